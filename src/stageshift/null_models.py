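"""Community randomization null models for diversity-shift tests.

Two schemes, one per diversity metric:

* **individual-pool null** (species richness): all recorded individuals are
  pooled and dealt back to islands without replacement, so every draw keeps
  the observed per-island abundance totals and per-species totals exactly
  (the Fisher–Yates distribution over fixed-margin contingency tables).
* **independent swap** (phylogenetic diversity): the presence/absence matrix
  is randomized by 2×2 checkerboard swaps, preserving each species' number
  of occupied islands and each island's species richness; abundances travel
  with their occurrences so each species' abundance multiset (hence total)
  is also preserved.

Shift tests randomize the two life stages independently — each stage is
compared to its own randomized ensemble, so differing sampling intensity
between stages cannot masquerade as an assembly signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InvalidArgumentError
from .phylodiversity import PhyloIndex

__all__ = [
    "STAGES",
    "LifeStageCommunity",
    "NullEnsemble",
    "individual_pool_null",
    "independent_swap",
    "null_diff_ensemble",
    "DEFAULT_SWAP_ITERATIONS",
]

logger = logging.getLogger(__name__)

STAGES = ("seedling", "sapling", "tree")

#: attempted checkerboard swaps per randomization (burn-in from the observed
#: matrix); the common default in the ecological null-model literature
DEFAULT_SWAP_ITERATIONS = 30_000


@dataclass
class LifeStageCommunity:
    """Island × species abundance matrix for one life stage."""

    islands: list[str]
    species: list[str]
    abundance: np.ndarray
    stage: str

    def __post_init__(self) -> None:
        self.islands = [str(i) for i in self.islands]
        self.species = [str(s) for s in self.species]
        self.abundance = np.asarray(self.abundance)
        if self.stage not in STAGES:
            raise InvalidArgumentError(
                f"stage must be one of {STAGES}, got {self.stage!r}"
            )
        if self.abundance.shape != (len(self.islands), len(self.species)):
            raise InvalidArgumentError(
                f"abundance shape {self.abundance.shape} != "
                f"({len(self.islands)}, {len(self.species)})"
            )
        if not np.issubdtype(self.abundance.dtype, np.integer):
            as_int = self.abundance.astype(np.int64)
            if not np.array_equal(as_int, self.abundance):
                raise InvalidArgumentError("abundances must be integers")
            self.abundance = as_int
        if (self.abundance < 0).any():
            raise InvalidArgumentError("abundances must be non-negative")
        if len(set(self.islands)) != len(self.islands):
            raise InvalidArgumentError("duplicate island labels")
        if len(set(self.species)) != len(self.species):
            raise InvalidArgumentError("duplicate species labels")
        if self.abundance.sum() == 0:
            raise InvalidArgumentError("community matrix is all zero")

    @property
    def n_islands(self) -> int:
        return len(self.islands)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def presence(self) -> np.ndarray:
        return self.abundance > 0

    def richness(self) -> np.ndarray:
        return self.presence().sum(axis=1)

    def replace_abundance(self, abundance: np.ndarray) -> "LifeStageCommunity":
        return LifeStageCommunity(
            islands=list(self.islands),
            species=list(self.species),
            abundance=abundance,
            stage=self.stage,
        )


@dataclass
class NullEnsemble:
    """Per-island null distribution of (older − younger) diversity diffs."""

    metric: str  # "SD" or "PD"
    stage_pair: str  # e.g. "SS", "ST"
    n_rand: int
    islands: list[str]
    diffs: np.ndarray = field(repr=False)  # (n_islands, n_rand)

    def __post_init__(self) -> None:
        if self.n_rand < 2:
            raise InvalidArgumentError("n_rand must be >= 2")
        self.diffs = np.asarray(self.diffs, dtype=float)
        if self.diffs.shape != (len(self.islands), self.n_rand):
            raise InvalidArgumentError("diffs shape mismatch")
        if not np.isfinite(self.diffs).all():
            raise InvalidArgumentError("non-finite null differences")


# ---------------------------------------------------------------------------
# individual-pool null (fixed margins)


def _pooled_individuals(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flatten a count matrix into per-individual (island, species) labels."""
    n_islands, n_species = matrix.shape
    flat = matrix.ravel()
    cell_island = np.repeat(np.arange(n_islands), n_species)
    cell_species = np.tile(np.arange(n_species), n_islands)
    return np.repeat(cell_island, flat), np.repeat(cell_species, flat)


def _deal_pool(
    isl: np.ndarray, sp: np.ndarray, shape: tuple[int, int], rng: np.random.Generator
) -> np.ndarray:
    """Randomly re-deal pooled individuals into islands, fixing both margins."""
    n_islands, n_species = shape
    perm_sp = rng.permutation(sp)
    keys = isl * n_species + perm_sp
    return np.bincount(keys, minlength=n_islands * n_species).reshape(shape)


def individual_pool_null(
    comm: LifeStageCommunity, seed: int | np.random.Generator | None = None
) -> LifeStageCommunity:
    """One draw of the individual-pool randomization.

    All individuals across islands are pooled and dealt back without
    replacement: the returned matrix has exactly the observed row sums
    (abundance per island) and column sums (total abundance per species).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    isl, sp = _pooled_individuals(comm.abundance)
    randomized = _deal_pool(isl, sp, comm.abundance.shape, rng)
    return comm.replace_abundance(randomized)


# ---------------------------------------------------------------------------
# independent swap


def _swap_kernel_py(inc, ab, rows1, rows2, cols1, cols2):
    n_swaps = 0
    for k in range(rows1.shape[0]):
        a = rows1[k]
        b = rows2[k]
        c = cols1[k]
        d = cols2[k]
        if inc[a, c] == 1 and inc[b, d] == 1 and inc[a, d] == 0 and inc[b, c] == 0:
            ab[b, c] = ab[a, c]
            ab[a, c] = 0
            ab[a, d] = ab[b, d]
            ab[b, d] = 0
            inc[a, c] = 0
            inc[b, d] = 0
            inc[a, d] = 1
            inc[b, c] = 1
            n_swaps += 1
        elif inc[a, d] == 1 and inc[b, c] == 1 and inc[a, c] == 0 and inc[b, d] == 0:
            ab[a, c] = ab[b, c]
            ab[b, c] = 0
            ab[b, d] = ab[a, d]
            ab[a, d] = 0
            inc[a, d] = 0
            inc[b, c] = 0
            inc[a, c] = 1
            inc[b, d] = 1
            n_swaps += 1
    return n_swaps


try:  # optional JIT; the pure-Python kernel is the reference behavior
    from numba import njit as _njit

    _swap_kernel = _njit(cache=True)(_swap_kernel_py)
except Exception:  # pragma: no cover - numba present in the supported env
    _swap_kernel = _swap_kernel_py


def _has_checkerboard(presence: np.ndarray) -> bool:
    """True iff some 2×2 checkerboard submatrix exists (a swap is possible)."""
    X = presence.astype(np.int64)
    notX = 1 - X
    m = X.T @ notX  # m[c, d] = number of islands with species c but not d
    return bool(((m > 0) & (m.T > 0)).any())


def _swap_proposals(shape: tuple[int, int], n_iterations: int, rng: np.random.Generator):
    n_islands, n_species = shape
    rows = rng.integers(0, n_islands, size=(2, n_iterations))
    cols = rng.integers(0, n_species, size=(2, n_iterations))
    return rows[0], rows[1], cols[0], cols[1]


def independent_swap(
    comm: LifeStageCommunity,
    n_iterations: int = DEFAULT_SWAP_ITERATIONS,
    seed: int | np.random.Generator | None = None,
) -> LifeStageCommunity:
    """One independent-swap randomization (attempted checkerboard swaps).

    Preserves per-species occurrence frequency, per-island richness and each
    species' multiset of abundance values.  A matrix with no swappable
    checkerboard is returned unchanged with a logged notice.
    """
    if n_iterations < 1:
        raise InvalidArgumentError("n_iterations must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    inc = comm.presence().astype(np.int8)
    ab = comm.abundance.astype(np.int64).copy()
    r1, r2, c1, c2 = _swap_proposals(comm.abundance.shape, n_iterations, rng)
    n_swaps = _swap_kernel(inc, ab, r1, r2, c1, c2)
    if n_swaps == 0 and not _has_checkerboard(comm.presence()):
        logger.info(
            "independent_swap: no swappable checkerboard in %s matrix; "
            "returning input unchanged",
            comm.stage,
        )
        return comm.replace_abundance(comm.abundance.copy())
    return comm.replace_abundance(ab)


# ---------------------------------------------------------------------------
# ensembles of null (older − younger) diversity differences

_TRANSITION_NAMES = {("sapling", "seedling"): "SS", ("tree", "sapling"): "ST"}


def transition_name(older_stage: str, younger_stage: str) -> str:
    return _TRANSITION_NAMES.get(
        (older_stage, younger_stage), f"{older_stage}-{younger_stage}"
    )


def _check_aligned(older: LifeStageCommunity, younger: LifeStageCommunity) -> None:
    if older.islands != younger.islands or older.species != younger.species:
        raise InvalidArgumentError(
            "older/younger communities must share island and species universes"
        )


def _null_richness(
    comm: LifeStageCommunity, n_rand: int, rng_streams: list[np.random.Generator]
) -> np.ndarray:
    """(n_islands, n_rand) richness under the individual-pool null."""
    isl, sp = _pooled_individuals(comm.abundance)
    shape = comm.abundance.shape
    out = np.empty((shape[0], n_rand), dtype=np.int64)
    for r in range(n_rand):
        table = _deal_pool(isl, sp, shape, rng_streams[r])
        out[:, r] = (table > 0).sum(axis=1)
    return out


def _null_pd(
    comm: LifeStageCommunity,
    index: PhyloIndex,
    tip_cols: np.ndarray,
    n_rand: int,
    n_iterations: int,
    rng_streams: list[np.random.Generator],
) -> np.ndarray:
    """(n_islands, n_rand) Faith PD under the independent-swap null."""
    base_inc = comm.presence().astype(np.int8)
    dummy_ab = comm.abundance.astype(np.int64)
    out = np.empty((comm.n_islands, n_rand), dtype=float)
    n_tips = index.n_tips
    for r in range(n_rand):
        rng = rng_streams[r]
        inc = base_inc.copy()
        ab = dummy_ab.copy()
        r1, r2, c1, c2 = _swap_proposals(inc.shape, n_iterations, rng)
        _swap_kernel(inc, ab, r1, r2, c1, c2)
        tips_presence = np.zeros((comm.n_islands, n_tips), dtype=bool)
        tips_presence[:, tip_cols] = inc.astype(bool)
        out[:, r] = index.pd_from_presence(tips_presence)
    return out


def _species_tip_columns(comm: LifeStageCommunity, index: PhyloIndex) -> np.ndarray:
    missing = [s for s in comm.species if s not in index.tip_index]
    if missing:
        raise ConfigurationError(f"community species not in phylogeny: {missing}")
    return np.array([index.tip_index[s] for s in comm.species])


def null_diff_ensemble(
    older: LifeStageCommunity,
    younger: LifeStageCommunity,
    metric: str,
    phylo=None,
    n_rand: int = 1000,
    seed: int | None = None,
    swap_iterations: int = DEFAULT_SWAP_ITERATIONS,
) -> NullEnsemble:
    """Null distribution of per-island (older − younger) diversity shifts.

    Each of ``n_rand`` replicates randomizes the two stages independently —
    individual-pool resampling for SD, independent swap for PD — and records
    the per-island difference in the stage diversities.  Per-replicate RNG
    substreams are spawned from the master seed, so the ensemble is
    reproducible regardless of evaluation order.
    """
    _check_aligned(older, younger)
    if metric not in ("SD", "PD"):
        raise ConfigurationError(f"metric must be 'SD' or 'PD', got {metric!r}")
    if metric == "PD" and phylo is None:
        raise ConfigurationError("metric='PD' requires a phylogeny")
    if n_rand < 2:
        raise InvalidArgumentError("n_rand must be >= 2")
    seq = np.random.SeedSequence(seed)
    older_streams = [np.random.default_rng(s) for s in seq.spawn(n_rand)]
    younger_streams = [np.random.default_rng(s) for s in seq.spawn(n_rand)]
    if metric == "SD":
        div_older = _null_richness(older, n_rand, older_streams)
        div_younger = _null_richness(younger, n_rand, younger_streams)
    else:
        index = phylo if isinstance(phylo, PhyloIndex) else PhyloIndex(phylo)
        tip_cols = _species_tip_columns(older, index)
        div_older = _null_pd(
            older, index, tip_cols, n_rand, swap_iterations, older_streams
        )
        div_younger = _null_pd(
            younger, index, tip_cols, n_rand, swap_iterations, younger_streams
        )
    diffs = (div_older - div_younger).astype(float)
    return NullEnsemble(
        metric=metric,
        stage_pair=transition_name(older.stage, younger.stage),
        n_rand=n_rand,
        islands=list(older.islands),
        diffs=diffs,
    )
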