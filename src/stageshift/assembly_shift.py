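"""Standardized diversity-shift statistics and assembly-process calls.

For each island and life-stage transition (seedling→sapling, SS; and
sapling→tree, ST) the shift in a diversity metric D (species richness, SD;
or Faith's PD) is standardized against its randomization null:

    Z_D = [ (D_obs,older − D_obs,younger) − mean(D_ran,older − D_ran,younger) ]
          / sd(D_ran,older − D_ran,younger)

Negative Z_D means diversity dropped across the transition more than chance
allows — a clustering assembly process; positive Z_D means overdispersion.
The same sign convention is applied to both metrics; a significantly
negative/positive pair (SD, PD) is mapped to candidate ecological mechanisms:

    (clustering,    clustering)    → environmental filtering or dispersal limitation
    (clustering,    overdispersed) → interspecific competition
    (overdispersed, overdispersed) → density dependence
    (random,        random)        → random process
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ConfigurationError, InvalidArgumentError
from .null_models import (
    LifeStageCommunity,
    NullEnsemble,
    null_diff_ensemble,
    transition_name,
    DEFAULT_SWAP_ITERATIONS,
)
from .phylodiversity import PhyloIndex

__all__ = [
    "ShiftResult",
    "AssemblyCall",
    "diversity_by_island",
    "z_score",
    "shift_significance",
    "classify_assembly",
    "transition_table",
    "MECHANISM_TABLE",
]

logger = logging.getLogger(__name__)

#: (pattern_sd, pattern_pd) → candidate mechanisms
MECHANISM_TABLE: dict[tuple[str, str], frozenset[str]] = {
    ("clustering", "clustering"): frozenset(
        {"environmental_filtering", "dispersal_limitation"}
    ),
    ("clustering", "overdispersed"): frozenset({"interspecific_competition"}),
    ("overdispersed", "overdispersed"): frozenset({"density_dependence"}),
    ("random", "random"): frozenset({"random_process"}),
}


@dataclass(frozen=True)
class ShiftResult:
    """Standardized diversity shift for one island × transition × metric."""

    island_id: str
    transition: str  # "SS" or "ST"
    metric: str  # "SD" or "PD"
    d_obs_older: float
    d_obs_younger: float
    obs_diff: float
    null_mean: float
    null_sd: float
    z: float
    p: float
    degenerate: bool = False  # null sd was zero


@dataclass(frozen=True)
class AssemblyCall:
    """Mechanism classification for one island × transition."""

    island_id: str
    transition: str
    pattern_sd: str
    pattern_pd: str
    mechanisms: frozenset[str]
    unclassified: bool = False


def diversity_by_island(
    comm: LifeStageCommunity, metric: str, phylo=None
) -> np.ndarray:
    """Per-island diversity: SD = species richness, PD = Faith's PD.

    Islands with no individuals get diversity 0 (with a logged warning).
    """
    if metric == "SD":
        if phylo is not None:
            raise ConfigurationError("phylo must be omitted for metric='SD'")
        values = comm.richness().astype(float)
    elif metric == "PD":
        if phylo is None:
            raise ConfigurationError("metric='PD' requires a phylogeny")
        index = phylo if isinstance(phylo, PhyloIndex) else PhyloIndex(phylo)
        missing = [s for s in comm.species if s not in index.tip_index]
        if missing:
            raise ConfigurationError(f"community species not in phylogeny: {missing}")
        tip_cols = np.array([index.tip_index[s] for s in comm.species])
        presence = np.zeros((comm.n_islands, index.n_tips), dtype=bool)
        presence[:, tip_cols] = comm.presence()
        values = index.pd_from_presence(presence)
    else:
        raise ConfigurationError(f"metric must be 'SD' or 'PD', got {metric!r}")
    empty = comm.abundance.sum(axis=1) == 0
    if empty.any():
        logger.warning(
            "%d island(s) with zero individuals in %s stage; diversity set to 0",
            int(empty.sum()),
            comm.stage,
        )
    return values


def z_score(obs_diff: float, null_diffs: np.ndarray) -> tuple[float, float, float]:
    """Standardize an observed shift against its null sample.

    Returns ``(z, null_mean, null_sd)`` with the sample (n−1) standard
    deviation.  A degenerate null (sd = 0) yields z = 0 when the observation
    equals the null mean, otherwise signed infinity.
    """
    null_diffs = np.asarray(null_diffs, dtype=float)
    if null_diffs.size < 2:
        raise InvalidArgumentError("need at least 2 null values")
    mean = float(null_diffs.mean())
    sd = float(null_diffs.std(ddof=1))
    if sd == 0.0:
        z = 0.0 if obs_diff == mean else float(np.sign(obs_diff - mean)) * np.inf
    else:
        z = (obs_diff - mean) / sd
    return z, mean, sd


def shift_significance(
    obs_diff: float, null_diffs: np.ndarray, method: str = "t_test"
) -> float:
    """One-tailed significance of an observed shift against its null sample.

    ``t_test`` (default): one-tailed t probability of the observed value
    against the null sample, in the direction of the observed deviation.
    ``rank``: (number of null values as-or-more extreme in that direction
    + 1) / (n + 1).
    """
    null_diffs = np.asarray(null_diffs, dtype=float)
    if null_diffs.size < 2:
        raise InvalidArgumentError("need at least 2 null values")
    if method == "t_test":
        z, _, sd = z_score(obs_diff, null_diffs)
        if sd == 0.0:
            return 1.0 if np.isfinite(z) else 0.0
        return float(stats.t.sf(abs(z), df=null_diffs.size - 1))
    if method == "rank":
        n = null_diffs.size
        mean = null_diffs.mean()
        if obs_diff >= mean:
            extreme = int((null_diffs >= obs_diff).sum())
        else:
            extreme = int((null_diffs <= obs_diff).sum())
        return (extreme + 1) / (n + 1)
    raise ConfigurationError(f"unknown significance method {method!r}")


def _pattern(z: float, p: float, alpha: float) -> str:
    if p <= alpha and z < 0:
        return "clustering"
    if p <= alpha and z > 0:
        return "overdispersed"
    return "random"


def classify_assembly(
    z_sd: float,
    p_sd: float,
    z_pd: float,
    p_pd: float,
    alpha: float = 0.05,
    island_id: str = "",
    transition: str = "",
    invert_pd: bool = False,
) -> AssemblyCall:
    """Map (Z_SD, Z_PD) significance patterns to candidate mechanisms.

    Combinations outside the four predicted rows (e.g. one metric clustered,
    the other random) are mapped to random_process with ``unclassified=True``.
    ``invert_pd`` flips the sign reading of the PD statistic (positive =
    clustering) for users following the opposite convention.
    """
    if not (0.0 < alpha < 1.0):
        raise InvalidArgumentError(f"alpha must be in (0, 1), got {alpha}")
    if invert_pd:
        z_pd = -z_pd
    for name, v in (("z_sd", z_sd), ("p_sd", p_sd), ("z_pd", z_pd), ("p_pd", p_pd)):
        if not np.isfinite(v):
            raise InvalidArgumentError(f"{name} must be finite, got {v}")
    pattern_sd = _pattern(z_sd, p_sd, alpha)
    pattern_pd = _pattern(z_pd, p_pd, alpha)
    mechanisms = MECHANISM_TABLE.get((pattern_sd, pattern_pd))
    unclassified = mechanisms is None
    if unclassified:
        mechanisms = frozenset({"random_process"})
    return AssemblyCall(
        island_id=island_id,
        transition=transition,
        pattern_sd=pattern_sd,
        pattern_pd=pattern_pd,
        mechanisms=mechanisms,
        unclassified=unclassified,
    )


def _shift_results_for(
    older: LifeStageCommunity,
    younger: LifeStageCommunity,
    metric: str,
    ensemble: NullEnsemble,
    phylo,
    method: str,
) -> list[ShiftResult]:
    kwargs = {} if metric == "SD" else {"phylo": phylo}
    div_older = diversity_by_island(older, metric, **kwargs)
    div_younger = diversity_by_island(younger, metric, **kwargs)
    results = []
    for i, island in enumerate(ensemble.islands):
        obs_diff = float(div_older[i] - div_younger[i])
        nulls = ensemble.diffs[i]
        z, mean, sd = z_score(obs_diff, nulls)
        degenerate = sd == 0.0
        if degenerate:
            p = 1.0
            z_out = 0.0
            logger.warning(
                "degenerate null (sd=0) for island %s, %s %s; reported as random",
                island,
                ensemble.stage_pair,
                metric,
            )
        else:
            p = shift_significance(obs_diff, nulls, method=method)
            z_out = z
        results.append(
            ShiftResult(
                island_id=island,
                transition=ensemble.stage_pair,
                metric=metric,
                d_obs_older=float(div_older[i]),
                d_obs_younger=float(div_younger[i]),
                obs_diff=obs_diff,
                null_mean=mean,
                null_sd=sd,
                z=z_out,
                p=p,
                degenerate=degenerate,
            )
        )
    return results


def transition_table(
    communities: dict[str, LifeStageCommunity],
    phylo,
    n_rand: int = 1000,
    seed: int | None = None,
    method: str = "t_test",
    alpha: float = 0.05,
    swap_iterations: int = DEFAULT_SWAP_ITERATIONS,
) -> tuple[list[ShiftResult], list[AssemblyCall]]:
    """Z_D for both metrics and both transitions, plus mechanism calls.

    ``communities`` maps stage name → community for all of seedling, sapling
    and tree (aligned island and species labels).  SS compares sapling −
    seedling, ST compares tree − sapling.  Deterministic under a fixed seed.
    """
    for stage in ("seedling", "sapling", "tree"):
        if stage not in communities:
            raise InvalidArgumentError(f"missing {stage} community")
    ref = communities["seedling"]
    for stage, comm in communities.items():
        if comm.islands != ref.islands or comm.species != ref.species:
            raise InvalidArgumentError(
                f"label misalignment between seedling and {stage} communities"
            )
    index = phylo if isinstance(phylo, PhyloIndex) else PhyloIndex(phylo)
    seq = np.random.SeedSequence(seed)
    subseeds = [int(s.generate_state(1)[0] % (2**31)) for s in seq.spawn(4)]
    pairs = [
        (communities["sapling"], communities["seedling"]),
        (communities["tree"], communities["sapling"]),
    ]
    shift_results: list[ShiftResult] = []
    by_key: dict[tuple[str, str, str], ShiftResult] = {}
    k = 0
    for older, younger in pairs:
        for metric in ("SD", "PD"):
            ensemble = null_diff_ensemble(
                older,
                younger,
                metric=metric,
                phylo=index if metric == "PD" else None,
                n_rand=n_rand,
                seed=subseeds[k],
                swap_iterations=swap_iterations,
            )
            k += 1
            rows = _shift_results_for(
                older, younger, metric, ensemble, index, method
            )
            shift_results.extend(rows)
            for row in rows:
                by_key[(row.island_id, row.transition, row.metric)] = row
    calls = []
    for older, younger in pairs:
        trans = transition_name(older.stage, younger.stage)
        for island in ref.islands:
            sd_row = by_key[(island, trans, "SD")]
            pd_row = by_key[(island, trans, "PD")]
            calls.append(
                classify_assembly(
                    z_sd=sd_row.z,
                    p_sd=sd_row.p,
                    z_pd=pd_row.z,
                    p_pd=pd_row.p,
                    alpha=alpha,
                    island_id=island,
                    transition=trans,
                )
            )
    return shift_results, calls
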