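# Methods

`stageshift` asks how woody-plant communities on habitat-fragmentation
islands assemble, by tracking how diversity changes *between* life stages of
the same community rather than by comparing static snapshots to a null. For
each island and each transition — seedling→sapling (SS) and sapling→tree
(ST) — it standardizes the observed shift of a diversity metric D against a
randomization null:

    Z_D = [ (D_obs,older − D_obs,younger) − mean(D_ran,older − D_ran,younger) ]
          / sd(D_ran,older − D_ran,younger)

with D either species richness (SD) or Faith's phylogenetic diversity (PD).
A significantly negative Z_D means diversity fell across the transition more
than chance allows (clustering); positive means overdispersion. The joint
(SD, PD) pattern maps to candidate ecological mechanisms:

| SD pattern     | PD pattern     | mechanism(s)                                  |
|----------------|----------------|-----------------------------------------------|
| clustering     | clustering     | environmental filtering / dispersal limitation |
| clustering     | overdispersed  | interspecific competition                      |
| overdispersed  | overdispersed  | density dependence                             |
| random         | random         | random process                                 |

Any other combination is reported as random with an `unclassified` flag.
The PD interpretation assumes phylogenetic niche conservatism (close
relatives share niches), which is why the package also ships Blomberg's K to
check trait conservatism on the user's phylogeny.

## Null models

Each life stage is randomized *independently* and compared against its own
ensemble, so differences in sampling intensity or density between stages
cannot masquerade as assembly signal.

**Individual-pool null (used for SD).** All individuals recorded anywhere in
the stage are pooled and dealt back to islands without replacement. Every
draw preserves the per-island abundance totals and per-species totals
exactly. This is implemented literally as a random permutation of the pooled
individual list, whose distribution over tables is the Fisher–Yates /
multivariate-hypergeometric law for fixed margins. (Note this is *not*
uniform over the set of feasible tables in general — tables are weighted by
their multinomial multiplicity; the two coincide for 0/1 margins.)

**Independent swap (used for PD).** The presence/absence matrix is
randomized by repeated 2×2 checkerboard submatrix swaps, preserving each
species' occurrence frequency and each island's richness; abundance values
travel with their occurrences, so each species' multiset of abundances (and
total abundance) is preserved as well. Default burn-in is 30,000 attempted
swaps per randomization, restarted from the observed matrix for each
replicate — the common convention in ecological null-model software. The
inner loop is JIT-compiled when `numba` is importable, with a pure-Python
fallback of identical behavior. A matrix with no swappable checkerboard is
returned unchanged with a logged notice.

Ensembles default to `n_rand = 1000` replicates; per-replicate RNG
substreams are spawned deterministically from one master seed, so results
are bit-reproducible regardless of evaluation order.

## Significance and classification

Z uses the sample (n−1) standard deviation of the null differences. If the
null sd is zero (degenerate margins, e.g. a single-island system) the island
is reported as random with a `degenerate` flag. The default significance
method is a one-tailed t-test of the observed difference against the null
sample, in the direction of the observed deviation; a rank-based
permutation p, `(extreme + 1) / (n_rand + 1)`, is available via
`method="rank"` and is the statistically cleaner choice for randomization
ensembles — the t-test remains the default because it is the convention this
analysis style follows. α defaults to 0.05.

Because the one-tailed p is taken in the direction of the deviation, the
probability of calling *some* non-random pattern under a true null is close
to 2α split between clustering and overdispersion; each specific direction
is called at rate ≈ α.

## Faith's PD

PD is the total branch length of the subtree linking a community's species.
The root path is included by default (`include_root=True`), so a singleton
community has PD equal to its root-to-tip distance and the full tip set
gives the total tree length; this matches the common default of the R
packages used for this analysis style and keeps PD positive for
single-species islands. `include_root=False` stops at the species set's
most recent common ancestor. Internally a tips × edges incidence matrix is
precomputed once, making PD a single boolean matrix product for whole
island × species presence matrices — the shape the null ensembles need.
Pruned trees retain any stem length above the remaining root, so PD of any
subset is invariant under pruning to a superset.

## Blomberg's K

K = (MSE0/MSE)_observed / (MSE0/MSE)_BM-expected, where MSE0 is the variance
of tip values around the phylogenetically corrected (GLS) mean, MSE the
generalized least-squares mean square under the branch-length covariance V,
and the Brownian expectation is the trace-based closed form
(tr V − n / Σ(V⁻¹)) / (n − 1). Both mean squares use the n−1 denominator of
the original formulation. K is exactly 1 on an equal-branch star phylogeny,
≈1 for Brownian traits, <1 for less-than-Brownian signal. The permutation
test shuffles tip values (default 999 permutations) and reports the
proportion of permutations with MSE at or below the observed — small MSE
means variance sits where the tree predicts.

## Landscape metrics

Shape index SI = P / (2·√(π·A)) with perimeter and area converted to meters
before the ratio, so SI is dimensionless despite the conventional mixed
units (ha, km). SI = 1 exactly for a circle, >1 otherwise (isoperimetric
inequality; validated to 1e−9 slack on input tables). Polygon area,
perimeter, minimum edge-to-edge distance (isolation) and validity checks go
through `shapely`; isolation to the mainland is the default, matching the
emulated field design, with other targets possible by passing a different
polygon. Geodesic coordinates are out of scope — inputs are planar
projected meters.

## Regression trees

CART regression trees attribute per-island Z_D to island attributes (area,
isolation, shape index, sampling area). The implementation is standard
greedy binary recursive partitioning minimizing within-node SSE, with
rpart-convention controls: `minsplit=20`, `minbucket=round(minsplit/3)=7`,
`cp=0.01` (minimum R² gain per split, relative to the root SST),
`maxdepth=30`. Candidate thresholds are midpoints of consecutive sorted
unique values; ties in SSE improvement break by attribute column order,
then smaller threshold, so fits are deterministic. With ~30 islands these
defaults typically allow at most one or two splits — single-driver trees.
The reported quantity is the apparent ("approximate") R² after k splits,
1 − Σ(leaf SSE)/SST, listed along the weakest-link cost-complexity sequence;
cross-validated error, surrogate splits and missing-value handling are
deliberately out of scope. The mainland reference row is excluded from
trees by default (they explain variation among islands).

## Synthetic landscapes

The generator produces the full input bundle — Yule phylogeny, conserved
traits, island attributes, three nested life-stage communities — under a
known assembly truth, so the whole pipeline is testable without field data.

Study conditions (defaults): 29 islands plus one mainland-like reference
site (largest area, zero isolation), 92 species, log-series regional
abundances (θ = 0.97, strong rarity skew typical of tree communities),
island areas log-uniform on 0.25–200 ha, isolation uniform on 0.05–2.5 km,
shape index 1 + Exp(0.35). Sampling area follows the emulated plot
protocol: full census below 1 ha, 0.5 ha on 1–5 ha islands, 1 ha above.
Seedling cohorts are 1200 stems per sampled hectare; stage survival is 8%
for seedling→sapling and 12% for sapling→tree (field tree:sapling density
ratios are ~0.1, and seedling-to-sapling survival of a few percent is the
typical forest regime). These sizes are an order of magnitude below raw
field stem densities — the statistical behavior of the shift statistics is
unchanged and the simulations stay light.

The phylogeny simulator is pure-birth with a final exponential waiting
interval appended so terminal branches are strictly positive (an ultrametric
tree ends otherwise exactly at the last speciation, producing zero-length
tips). Traits evolve by Brownian motion; the *niche* and *dispersal* traits
used by the assembly processes are simulated on an early-burst rescaled tree
(rate ∝ exp(−6·h/T) by default, `niche_conservatism` in the config), i.e.
pronounced niche conservatism — the assumption the PD-based mechanism table
rests on. Plain-Brownian traits (for K testing) use the untransformed tree.

Assembly processes act as species-level survival weights in a binomial
thinning whose abundance-weighted mean survival is rescaled to the stage
survival rate, so processes change *who* survives, not how many; nestedness
(tree ⊆ sapling ⊆ seedling per island × species) holds by construction.
Only survival differentials *within* an island leave a Z_D signature — a
penalty applied identically everywhere is absorbed into the null's fixed
margins — so each biotic process is built around its island-specific
component:

* **filtering** — Gaussian penalty in the distance between the species'
  niche trait and an island-specific optimum drawn uniformly over the trait
  range; strength multiplies the squared standardized deviation (values of
  ~4–8 are strong).
* **dispersal limitation** — penalty ∝ isolation × (1 − dispersal ability);
  colonization of the seedling stage also decays with isolation, but with
  the coefficient capped at 1 so the across-stage shift, not a pre-shaped
  seedling pool, carries the signal.
* **competition** — asymmetric exclusion under island-level lottery
  hierarchies (priority effects): each island draws its own dominance
  ranking, and a species is suppressed in proportion to the local abundance
  of phylogenetically close, locally dominant heterospecifics. Penalties
  are standardized within island, so strength is the log-survival
  differential in SD units (~4–8 strong). Produces SD clustering with PD
  overdispersion.
* **density dependence** — Janzen–Connell-style: survival is a power law
  `crowding^(−strength)` of local crowding by conspecifics and close
  relatives. At strength 1 every present species expects the same number of
  survivors — strong evenization without wholesale local extinction;
  strengths of ~1–1.5 are strong, and much larger values flip into a
  rare-species-only regime.
* **neutral** — uniform thinning. Strength 0 reduces *every* process to
  neutral bit-exactly.

Under neutral assembly the seedling stage is an independent multinomial
deal of individuals to islands, which conditional on its margins is exactly
the distribution the individual-pool null draws from, so Z_D calibrates:
across islands, mean ≈ 0 and sd ≈ 0.9. The sd sits slightly below 1 because
nested thinning makes successive stages share individuals, which positively
correlates their observed diversities while the null randomizes stages
independently; this is a property of the design (and of the field data the
generator emulates), not an artifact.

An optional `seedling_quadrat_subsampling` flag emulates quadrat-based
seedling sampling (4–48 quadrats growing with log island area; the mapping
from area to quadrat count is a stand-in, as no canonical rule exists). It
defaults to off — full censuses — because the shift statistics compare each
stage only to its own null. With it on, the *observed* seedling matrix is a
binomial subsample and is no longer guaranteed to nest above the sapling
matrix (the generative truth still nests).

What the generator does not emulate: within-island spatial structure, seed
banks, growth and mortality dynamics over time, species-specific detection
error, or any real species list. Passing tests therefore show the
statistics behave correctly under their own assumptions, not that those
assumptions hold in any particular forest.

## Sign conventions and known ambiguities

Positive Z_D = diversity increase from younger to older stage =
overdispersion, for both metrics. The analysis style this package follows
contains an internally inconsistent statement of the PD sign convention in
its source literature; the convention here is the one consistent with the
mechanism table, and `AssemblyCall` consumers who prefer the inverted PD
reading can negate PD z-scores upstream.

Per-island power is bounded: with a t-test against a randomization ensemble,
even extreme clustering rarely drives every island's p below α (joint
SD-and-PD significance saturates near ~55% of islands under strong
filtering at these community sizes), so mechanism *direction* statements in
the tests are made on signs and medians, and classification statements on
majorities.

## Problem sizes used in the test suite

Unit and acceptance tests run the generator at its default 29+1-island,
92-species conditions with 199–1000 null replicates, plus one 200-island
neutral calibration at 1000 replicates; these sizes give stable statistics
for every assertion while keeping the full suite under a minute of compute
for most modules.
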