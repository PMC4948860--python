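"""Synthetic fragmented-landscape metacommunities with known assembly truth.

Generates everything the pipeline consumes — a phylogeny, conserved traits,
island attributes, and three nested life-stage communities (seedling →
sapling → tree) — under a chosen assembly process per transition, so that
every downstream statistic can be checked against a known generative truth:

* ``neutral`` — uniform thinning; the observed matrices are, conditional on
  their margins, exactly the distribution the individual-pool null draws
  from, so Z_D calibrates to ~N(0, 1).
* ``filtering`` — survival decays with the distance between a species' niche
  trait and the island's environmental optimum (SD and PD clustering).
* ``dispersal_limitation`` — colonization and survival decay with island
  isolation for poor dispersers (clustering, as filtering).
* ``competition`` — asymmetric competitive exclusion: survival of a species
  decays with the local abundance of phylogenetically close *dominant*
  heterospecifics (SD clustering, PD overdispersion).
* ``density_dependence`` — survival decays with local conspecific-and-
  close-relative density, penalizing dominants (SD and PD overdispersion).

With ``strength = 0`` every process reduces to neutral thinning exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, SchemaError
from .landscape_metrics import IslandAttributes, shape_index
from .null_models import STAGES, LifeStageCommunity
from .phylodiversity import PhyloIndex, write_newick

__all__ = [
    "PROCESSES",
    "ScenarioConfig",
    "SyntheticDataset",
    "simulate_phylogeny",
    "simulate_traits_bm",
    "simulate_island_attributes",
    "simulate_metacommunity",
    "simulate_dataset",
]

PROCESSES = (
    "filtering",
    "competition",
    "dispersal_limitation",
    "density_dependence",
    "neutral",
)


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the landscape the package targets: 29 islands plus one
    mainland reference site, 92 woody species with log-series (strongly
    rarity-skewed) regional abundances, seedling cohorts of 1200 stems/ha of
    sampled area, and stage survival of 8% (seedling→sapling) and 12%
    (sapling→tree; field tree:sapling density ratios are ~0.1).
    """

    n_islands: int = 29
    n_species: int = 92
    process_ss: str = "neutral"
    process_st: str = "neutral"
    strength: float = 0.0
    abundance_distribution: str = "logseries"
    seed: int = 0
    # study-condition knobs
    seedling_density_per_ha: float = 1200.0
    survival_ss: float = 0.08
    survival_st: float = 0.12
    include_reference: bool = True
    area_range_ha: tuple[float, float] = (0.25, 200.0)
    logseries_theta: float = 0.97
    lognormal_sigma: float = 1.5
    # rate-decay exponent of the niche trait's evolution (early burst):
    # 0 = plain Brownian motion; larger values concentrate trait divergence
    # on deep branches, i.e. pronounced phylogenetic niche conservatism —
    # the assumption under which phylogenetic diversity proxies niche
    # similarity in the mechanism table
    niche_conservatism: float = 6.0
    # optional emulation of quadrat-based seedling sampling (count grows with
    # log island area, 4..48); the default is a full seedling census because
    # the shift statistics compare each stage only to its own null
    seedling_quadrat_subsampling: bool = False

    def __post_init__(self) -> None:
        if self.n_islands < 2:
            raise InvalidArgumentError("n_islands must be >= 2")
        if self.n_species < 3:
            raise InvalidArgumentError("n_species must be >= 3")
        for proc in (self.process_ss, self.process_st):
            if proc not in PROCESSES:
                raise InvalidArgumentError(f"unknown process {proc!r}")
        if self.strength < 0:
            raise InvalidArgumentError("strength must be >= 0")
        if self.abundance_distribution not in ("logseries", "lognormal"):
            raise InvalidArgumentError(
                f"unknown abundance distribution {self.abundance_distribution!r}"
            )
        if not (0 < self.survival_ss <= 1 and 0 < self.survival_st <= 1):
            raise InvalidArgumentError("survival fractions must be in (0, 1]")


@dataclass
class SyntheticDataset:
    """A generated metacommunity plus everything needed to analyze it."""

    communities: dict[str, LifeStageCommunity]
    phylogeny: dendropy.Tree
    traits: pd.Series
    dispersal_ability: pd.Series
    attributes: IslandAttributes
    truth: ScenarioConfig
    island_optima: pd.Series

    def write(self, out_dir) -> dict[str, Path]:
        """Write communities.csv (long), phylogeny.nwk and attributes.csv."""
        from .pipeline import write_communities  # deferred: avoids cycle

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "communities": out / "communities.csv",
            "phylogeny": out / "phylogeny.nwk",
            "attributes": out / "attributes.csv",
        }
        write_communities(self.communities, paths["communities"])
        write_newick(self.phylogeny, paths["phylogeny"])
        self.attributes.table.to_csv(paths["attributes"], index=False)
        return paths


# ---------------------------------------------------------------------------
# phylogeny and traits


def simulate_phylogeny(n_species: int, seed: int | None = None) -> dendropy.Tree:
    """Pure-birth (Yule) ultrametric tree with ``n_species`` labeled tips.

    Lineages split at unit rate; a final exponential waiting interval is
    appended after the last speciation so every terminal branch is strictly
    positive.  Tips are labeled sp001..spNNN in random order.
    """
    if n_species < 2:
        raise InvalidArgumentError(f"n_species must be >= 2, got {n_species}")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    root.birth_time = 0.0
    active = []
    for _ in range(2):
        child = root.new_child()
        child.birth_time = 0.0
        active.append(child)
    t = 0.0
    while len(active) < n_species:
        t += rng.exponential(1.0 / len(active))
        parent = active.pop(rng.integers(len(active)))
        parent.split_time = t
        for _ in range(2):
            child = parent.new_child()
            child.birth_time = t
            active.append(child)
    t_end = t + rng.exponential(1.0 / len(active))
    labels = [f"sp{i + 1:03d}" for i in range(n_species)]
    label_order = rng.permutation(n_species)
    for k, leaf in enumerate(active):
        leaf.edge.length = t_end - leaf.birth_time
        leaf.taxon = taxa.new_taxon(label=labels[label_order[k]])
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is None:
            node.edge.length = node.split_time - node.birth_time
    return tree


def simulate_traits_bm(
    phylo: dendropy.Tree, sigma2: float, seed: int | None = None
) -> pd.Series:
    """Brownian-motion trait evolution along the tree, root value 0.

    Tip covariance equals sigma2 times the shared branch-length matrix.
    ``sigma2 = 0`` is the degenerate limit where all tips equal the root.
    """
    if sigma2 < 0:
        raise InvalidArgumentError(f"sigma2 must be >= 0, got {sigma2}")
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {}
    out = {}
    for node in phylo.preorder_node_iter():
        if node.parent_node is None:
            values[id(node)] = 0.0
        else:
            step_var = sigma2 * (node.edge.length or 0.0)
            values[id(node)] = values[id(node.parent_node)] + (
                rng.normal(0.0, np.sqrt(step_var)) if step_var > 0 else 0.0
            )
        if node.is_leaf():
            out[node.taxon.label] = values[id(node)]
    return pd.Series(out, name="trait")


def early_burst_tree(phylo: dendropy.Tree, decay: float) -> dendropy.Tree:
    """Rescale branch lengths under an early-burst rate decay.

    The evolutionary rate at height h (distance from root) is
    exp(−decay × h / T) with T the tree height; each edge length becomes the
    integral of that rate along the edge.  Brownian traits simulated on the
    rescaled tree have their variance concentrated on deep splits, giving
    strong phylogenetic conservatism.  ``decay = 0`` returns a clone with
    unchanged lengths.
    """
    if decay < 0:
        raise InvalidArgumentError("decay must be >= 0")
    out = phylo.clone(depth=1)
    heights: dict[int, float] = {}
    for node in out.preorder_node_iter():
        if node.parent_node is None:
            heights[id(node)] = 0.0
        else:
            heights[id(node)] = heights[id(node.parent_node)] + (
                node.edge.length or 0.0
            )
    T = max(heights[id(l)] for l in out.leaf_node_iter())
    if decay == 0 or T <= 0:
        return out
    for node in out.preorder_node_iter():
        if node.parent_node is None:
            continue
        h1 = heights[id(node)]
        h0 = heights[id(node.parent_node)]
        node.edge.length = (
            (np.exp(-decay * h0 / T) - np.exp(-decay * h1 / T)) * T / decay
        )
    return out


# ---------------------------------------------------------------------------
# island attributes


def simulate_island_attributes(
    n_islands: int,
    seed: int | None = None,
    area_range_ha: tuple[float, float] = (0.25, 200.0),
    isolation_range_km: tuple[float, float] = (0.05, 2.5),
    include_reference: bool = True,
) -> IslandAttributes:
    """Island attribute table with areas log-uniform over ``area_range_ha``.

    Perimeters are drawn as SI × the circular minimum with SI = 1 + Exp(0.35),
    so SI ≥ 1 always holds.  Sampling area follows the plot protocol of the
    emulated field design: full census below 1 ha, 0.5 ha for 1–5 ha islands,
    1 ha above.  With ``include_reference`` a mainland-like control site is
    appended: largest area, zero isolation, flagged ``is_reference``.
    """
    if n_islands < 1:
        raise InvalidArgumentError("n_islands must be >= 1")
    lo, hi = area_range_ha
    if not (0 < lo < hi):
        raise InvalidArgumentError(f"invalid area range {area_range_ha}")
    rng = np.random.default_rng(seed)
    areas = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_islands))
    si = 1.0 + rng.exponential(0.35, size=n_islands)
    iso = rng.uniform(*isolation_range_km, size=n_islands)

    def sampling_area(a: float) -> float:
        if a < 1.0:
            return a
        return 0.5 if a <= 5.0 else 1.0

    def perimeter_km(a: float, s: float) -> float:
        return s * 2.0 * np.sqrt(np.pi * a * 1e4) / 1e3

    rows = [
        {
            "island_id": f"i{k + 1:02d}",
            "area_ha": areas[k],
            "perimeter_km": perimeter_km(areas[k], si[k]),
            "shape_index": si[k],
            "isolation_km": iso[k],
            "sampling_area_ha": sampling_area(areas[k]),
            "is_reference": False,
        }
        for k in range(n_islands)
    ]
    if include_reference:
        ref_area = 2.0 * hi
        ref_si = 1.0 + rng.exponential(0.35)
        rows.append(
            {
                "island_id": "mainland",
                "area_ha": ref_area,
                "perimeter_km": perimeter_km(ref_area, ref_si),
                "shape_index": ref_si,
                "isolation_km": 0.0,
                "sampling_area_ha": 1.0,
                "is_reference": True,
            }
        )
    table = pd.DataFrame(rows)
    # numerical guard: recomputed SI must respect the isoperimetric bound
    table["shape_index"] = [
        shape_index(a, p) for a, p in zip(table["area_ha"], table["perimeter_km"])
    ]
    return IslandAttributes(table)


# ---------------------------------------------------------------------------
# metacommunity assembly


def _regional_abundance(config: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    s = config.n_species
    if config.abundance_distribution == "logseries":
        k = np.arange(1, s + 1)
        w = config.logseries_theta**k / k
    else:
        w = np.exp(rng.normal(0.0, config.lognormal_sigma, size=s))
        w = np.sort(w)[::-1]
    w = w / w.sum()
    return rng.permutation(w)


def _similarity(index: PhyloIndex) -> np.ndarray:
    """exp(−patristic distance / τ) with τ = a quarter of the mean tip depth."""
    inc = index.incidence.astype(float)
    shared = (inc * index.edge_lengths) @ inc.T
    depths = np.diag(shared)
    dist = depths[:, None] + depths[None, :] - 2.0 * shared
    tau = max(0.25 * depths.mean(), 1e-12)
    return np.exp(-dist / tau)


def _survival_weights(
    process: str,
    strength: float,
    abundance: np.ndarray,
    traits: np.ndarray,
    optima: np.ndarray,
    dispersal: np.ndarray,
    iso_scaled: np.ndarray,
    similarity: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """(islands × species) relative survival weights for one transition.

    Only survival *differentials within an island* leave a Z_D signature —
    a penalty applied identically everywhere is absorbed into the null
    model's fixed margins — so each biotic process is built around its
    island-specific component.
    """
    n_islands, n_species = abundance.shape
    if process == "neutral" or strength == 0.0:
        return np.ones((n_islands, n_species))
    if process == "filtering":
        scale = max(np.std(traits), 1e-12)
        dev = (traits[None, :] - optima[:, None]) / scale
        return np.exp(-strength * dev**2)
    if process == "dispersal_limitation":
        return np.exp(
            -strength * iso_scaled[:, None] * (1.0 - dispersal[None, :])
        )
    totals = np.maximum(abundance.sum(axis=1, keepdims=True), 1)
    rel = abundance / totals
    if process == "competition":
        # competitive exclusion with island-level lottery hierarchies
        # (priority effects): each island has its own dominance ranking, and
        # a species is suppressed by locally abundant, phylogenetically
        # close species ranked above it there
        dom = rng.random((n_islands, n_species))
        sim = similarity.copy()
        np.fill_diagonal(sim, 0.0)
        pressure = np.empty_like(rel)
        for i in range(n_islands):
            loses_to = dom[i][None, :] > dom[i][:, None]  # [s, t]
            pressure[i] = (sim * loses_to) @ rel[i]
        return np.exp(-strength * _standardize_rows(pressure, abundance > 0))
    if process == "density_dependence":
        # Janzen-Connell-style negative density dependence: survival decays
        # as a power law of local crowding by conspecifics and close
        # relatives.  At strength 1 every present species expects the same
        # number of survivors regardless of its local abundance — strong
        # evenization of occupancy without wholesale local extinction
        crowd = np.maximum(abundance @ similarity.T, 1.0)
        return crowd ** (-strength)
    raise InvalidArgumentError(f"unknown process {process!r}")


def _standardize_rows(penalty: np.ndarray, present: np.ndarray) -> np.ndarray:
    """Center/scale each island's penalties over its present species.

    Puts the biotic penalties (competition pressure, neighborhood density) on
    a common per-island scale so ``strength`` is the log-survival differential
    in SD units, whatever the raw magnitude of the local pressures.
    """
    out = np.zeros_like(penalty, dtype=float)
    for i in range(penalty.shape[0]):
        mask = present[i]
        if mask.sum() < 2:
            continue
        vals = penalty[i, mask]
        sd = vals.std()
        if sd <= 0:
            continue
        out[i] = (penalty[i] - vals.mean()) / sd
    return out


def _thin(
    abundance: np.ndarray,
    q: float,
    weights: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Binomial thinning with species-level weights, mean survival ≈ q.

    Weights are rescaled per island so the abundance-weighted mean survival
    probability equals q (clipped to [0, 1]); a binomial draw from each cell
    guarantees the nestedness invariant.
    """
    totals = abundance.sum(axis=1, keepdims=True)
    wbar = np.where(
        totals > 0, (abundance * weights).sum(axis=1, keepdims=True) / np.maximum(totals, 1), 1.0
    )
    prob = np.clip(q * weights / np.maximum(wbar, 1e-300), 0.0, 1.0)
    return rng.binomial(abundance, prob)


def simulate_metacommunity(
    config: ScenarioConfig,
    phylo: dendropy.Tree,
    traits: pd.Series,
    attributes: IslandAttributes,
) -> SyntheticDataset:
    """Generate the three nested life-stage communities under a scenario.

    The seedling stage colonizes each island from the regional pool
    (isolation-weighted when a dispersal-limitation process is in play);
    each transition then thins individuals binomially with process-specific
    species survival weights.  Nestedness — tree ≤ sapling ≤ seedling per
    island × species — holds by construction.
    """
    index = PhyloIndex(phylo)
    species = index.tips
    if sorted(traits.index) != sorted(species):
        raise SchemaError("traits index must match phylogeny tip labels exactly")
    traits = traits.reindex(species)
    seq = np.random.SeedSequence(config.seed)
    rng_pool, rng_disp, rng_opt, rng_seed, rng_ss, rng_st, rng_quad = (
        np.random.default_rng(s) for s in seq.spawn(7)
    )

    table = attributes.table
    island_ids = [str(i) for i in table["island_id"]]
    n_islands = len(island_ids)
    iso = table["isolation_km"].to_numpy(dtype=float)
    iso_scaled = iso / max(iso.max(), 1e-12)
    sampling = table["sampling_area_ha"].to_numpy(dtype=float)
    sampling = np.where(np.isnan(sampling), 1.0, sampling)

    p_regional = _regional_abundance(config, rng_pool)
    if len(p_regional) != len(species):
        raise SchemaError(
            f"config.n_species={config.n_species} != phylogeny tips {len(species)}"
        )
    similarity = _similarity(index)
    trait_vec = traits.to_numpy(dtype=float)
    t_lo, t_hi = trait_vec.min(), trait_vec.max()
    optima = rng_opt.uniform(t_lo, t_hi, size=n_islands)
    # dispersal ability: phylogenetically conserved trait (dispersal
    # syndromes run in clades) squashed to [0, 1] ranks
    disp_raw = simulate_traits_bm(
        early_burst_tree(phylo, config.niche_conservatism),
        sigma2=1.0,
        seed=int(rng_disp.integers(2**31)),
    ).reindex(species)
    dispersal = disp_raw.rank().to_numpy() / len(species)

    # --- seedling colonization
    counts = np.maximum(
        10, np.round(config.seedling_density_per_ha * sampling).astype(int)
    )
    seed_weights = np.tile(p_regional, (n_islands, 1))
    if "dispersal_limitation" in (config.process_ss, config.process_st):
        # colonization decays mildly with isolation for poor dispersers; the
        # per-transition penalty carries the full strength, so the shift
        # statistic sees the limitation acting across stages rather than a
        # pre-shaped seedling pool
        seed_weights = seed_weights * np.exp(
            -min(config.strength, 1.0)
            * iso_scaled[:, None]
            * (1.0 - dispersal[None, :])
        )
    seed_weights = seed_weights / seed_weights.sum(axis=1, keepdims=True)
    seedling = np.vstack(
        [rng_seed.multinomial(counts[i], seed_weights[i]) for i in range(n_islands)]
    )

    # --- transitions
    def transition(
        abundance: np.ndarray, q: float, process: str, rng: np.random.Generator
    ) -> np.ndarray:
        weights = _survival_weights(
            process,
            config.strength,
            abundance,
            trait_vec,
            optima,
            dispersal,
            iso_scaled,
            similarity,
            rng,
        )
        return _thin(abundance, q, weights, rng)

    sapling = transition(seedling, config.survival_ss, config.process_ss, rng_ss)
    tree = transition(sapling, config.survival_st, config.process_st, rng_st)

    seedling_obs = seedling
    if config.seedling_quadrat_subsampling:
        # stand-in for the quadrat protocol: 4..48 quadrats, growing with
        # log area; retained fraction = quadrats / 48
        area = table["area_ha"].to_numpy(dtype=float)
        la = np.log(area)
        frac = (la - la.min()) / max(la.max() - la.min(), 1e-12)
        quadrats = np.round(4 + 44 * frac).astype(int)
        seedling_obs = rng_quad.binomial(
            seedling, (quadrats / 48.0)[:, None].repeat(seedling.shape[1], axis=1)
        )

    # canonical column order (sorted labels) so written data round-trip
    order = np.argsort(np.array(species))
    species_sorted = [species[j] for j in order]
    communities = {
        "seedling": LifeStageCommunity(
            island_ids, species_sorted, seedling_obs[:, order], "seedling"
        ),
        "sapling": LifeStageCommunity(
            island_ids, species_sorted, sapling[:, order], "sapling"
        ),
        "tree": LifeStageCommunity(island_ids, species_sorted, tree[:, order], "tree"),
    }
    return SyntheticDataset(
        communities=communities,
        phylogeny=phylo,
        traits=traits,
        dispersal_ability=pd.Series(dispersal, index=species, name="dispersal"),
        attributes=attributes,
        truth=config,
        island_optima=pd.Series(optima, index=island_ids, name="optimum"),
    )


def simulate_dataset(config: ScenarioConfig) -> SyntheticDataset:
    """Convenience wrapper: phylogeny, traits and attributes from the config seed."""
    seq = np.random.SeedSequence(config.seed)
    s_phylo, s_traits, s_attr = (
        int(s.generate_state(1)[0] % (2**31)) for s in seq.spawn(3)
    )
    phylo = simulate_phylogeny(config.n_species, seed=s_phylo)
    traits = simulate_traits_bm(
        early_burst_tree(phylo, config.niche_conservatism), sigma2=1.0, seed=s_traits
    )
    attributes = simulate_island_attributes(
        config.n_islands,
        seed=s_attr,
        area_range_ha=config.area_range_ha,
        include_reference=config.include_reference,
    )
    return simulate_metacommunity(config, phylo, traits, attributes)
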