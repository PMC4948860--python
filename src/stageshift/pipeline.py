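"""End-to-end orchestration: read inputs, run shifts, classify, fit trees.

Inputs are a long-format community CSV (island_id, species, life_stage,
abundance), a Newick phylogeny and an island attribute CSV.  Output is a
report bundle: a shift TSV (one row per island × transition × metric), an
assembly-call TSV, a JSON summary with per-transition sign counts and the
stage-wise Spearman correlation between species and phylogenetic diversity,
regression trees per transition × metric, and a run log.  Everything is
bit-for-bit reproducible under a fixed seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

import dendropy

from . import __version__
from .assembly_shift import AssemblyCall, ShiftResult, diversity_by_island, transition_table
from .errors import ConfigurationError, SchemaError
from .landscape_metrics import IslandAttributes, read_attributes
from .null_models import DEFAULT_SWAP_ITERATIONS, STAGES, LifeStageCommunity
from .phylodiversity import PhyloIndex, read_newick
from .regression_tree import RegressionTreeModel, TreeParams, fit_tree

__all__ = [
    "RunConfig",
    "ReportBundle",
    "read_communities",
    "write_communities",
    "run_analysis",
    "ingest_supplement",
]

logger = logging.getLogger(__name__)

COMMUNITY_COLUMNS = ["island_id", "species", "life_stage", "abundance"]
TREE_FEATURES = ["area_ha", "isolation_km", "shape_index", "sampling_area_ha"]


@dataclass
class RunConfig:
    """All tunables of a pipeline run."""

    communities: str
    phylogeny: str
    attributes: str
    out_dir: str
    n_rand: int = 1000
    seed: int = 0
    method: str = "t_test"  # or "rank"
    alpha: float = 0.05
    swap_iterations: int = DEFAULT_SWAP_ITERATIONS
    include_reference_in_trees: bool = False
    tree_minsplit: int = 20
    tree_cp: float = 0.01
    tree_maxdepth: int = 30

    def __post_init__(self) -> None:
        if self.n_rand < 2:
            raise ConfigurationError("n_rand must be >= 2")
        if self.method not in ("t_test", "rank"):
            raise ConfigurationError(f"unknown method {self.method!r}")


@dataclass
class ReportBundle:
    shifts: pd.DataFrame
    calls: pd.DataFrame
    summary: dict
    trees: dict[tuple[str, str], RegressionTreeModel]
    paths: dict[str, Path] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# community I/O


def read_communities(path) -> dict[str, LifeStageCommunity]:
    """Read three aligned life-stage communities from a long-format CSV.

    Absent (island, species, stage) combinations are zeros.  Schema errors
    (unknown stage, negative abundance, duplicate rows) name the offending
    CSV line numbers (1-based, counting the header as line 1).
    """
    df = pd.read_csv(path)
    missing = [c for c in COMMUNITY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"community CSV missing columns: {missing}")
    lines = df.index + 2  # header is line 1
    bad_stage = ~df["life_stage"].isin(STAGES)
    if bad_stage.any():
        raise SchemaError(
            f"unknown life_stage values at lines {lines[bad_stage].tolist()}: "
            f"{sorted(df.loc[bad_stage, 'life_stage'].unique())}"
        )
    if (df["abundance"] < 0).any():
        raise SchemaError(
            f"negative abundance at lines {lines[df['abundance'] < 0].tolist()}"
        )
    dup = df.duplicated(subset=["island_id", "species", "life_stage"], keep=False)
    if dup.any():
        raise SchemaError(f"duplicate (island, species, stage) rows at lines "
                          f"{lines[dup].tolist()}")
    islands = sorted(df["island_id"].astype(str).unique())
    species = sorted(df["species"].astype(str).unique())
    i_idx = {v: k for k, v in enumerate(islands)}
    s_idx = {v: k for k, v in enumerate(species)}
    out = {}
    for stage in STAGES:
        sub = df[df["life_stage"] == stage]
        mat = np.zeros((len(islands), len(species)), dtype=np.int64)
        rows = sub["island_id"].astype(str).map(i_idx).to_numpy()
        cols = sub["species"].astype(str).map(s_idx).to_numpy()
        mat[rows, cols] = sub["abundance"].to_numpy()
        out[stage] = LifeStageCommunity(islands, species, mat, stage)
    return out


def write_communities(communities: dict[str, LifeStageCommunity], path) -> None:
    """Write communities as long CSV.

    Zero cells are omitted, except that every island and species is anchored
    by at least one (possibly zero-abundance) row so the island × species
    universe round-trips exactly.
    """
    rows = []
    seen_islands: set[str] = set()
    seen_species: set[str] = set()
    for stage in STAGES:
        comm = communities[stage]
        nz = np.argwhere(comm.abundance > 0)
        for i, s in nz:
            rows.append(
                {
                    "island_id": comm.islands[i],
                    "species": comm.species[s],
                    "life_stage": stage,
                    "abundance": int(comm.abundance[i, s]),
                }
            )
            seen_islands.add(comm.islands[i])
            seen_species.add(comm.species[s])
    ref = communities[STAGES[0]]
    for island in ref.islands:
        if island not in seen_islands:
            rows.append(
                {
                    "island_id": island,
                    "species": ref.species[0],
                    "life_stage": STAGES[0],
                    "abundance": 0,
                }
            )
    for species in ref.species:
        if species not in seen_species:
            rows.append(
                {
                    "island_id": ref.islands[0],
                    "species": species,
                    "life_stage": STAGES[0],
                    "abundance": 0,
                }
            )
    pd.DataFrame(rows, columns=COMMUNITY_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# analysis


def _shifts_frame(results: list[ShiftResult]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in results])


def _calls_frame(calls: list[AssemblyCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        d = asdict(c)
        d["mechanisms"] = "|".join(sorted(c.mechanisms))
        rows.append(d)
    return pd.DataFrame(rows)


def _sign_counts(shifts: pd.DataFrame) -> dict:
    out = {}
    for (trans, metric), grp in shifts.groupby(["transition", "metric"]):
        out[f"{metric}_{trans}"] = {
            "n_islands": int(len(grp)),
            "n_increasing": int((grp["z"] > 0).sum()),
            "n_decreasing": int((grp["z"] < 0).sum()),
            "n_zero": int((grp["z"] == 0).sum()),
        }
    return out


def _opposing_counts(shifts: pd.DataFrame) -> dict:
    """Islands whose Z_D changes sign between the SS and ST transitions."""
    out = {}
    for metric, grp in shifts.groupby("metric"):
        wide = grp.pivot(index="island_id", columns="transition", values="z")
        if {"SS", "ST"} <= set(wide.columns):
            out[metric] = int(((wide["SS"] * wide["ST"]) < 0).sum())
    return out


def _spearman_sd_pd(
    communities: dict[str, LifeStageCommunity], index: PhyloIndex
) -> dict:
    out = {}
    for stage, comm in communities.items():
        sd = diversity_by_island(comm, "SD")
        pd_vals = diversity_by_island(comm, "PD", phylo=index)
        if np.unique(sd).size < 2 or np.unique(pd_vals).size < 2:
            out[stage] = {"rho": None, "p": None}  # correlation undefined
            continue
        rho, p = stats.spearmanr(sd, pd_vals)
        out[stage] = {"rho": float(rho), "p": float(p)}
    return out


def fit_attribute_trees(
    shifts: pd.DataFrame,
    attributes: IslandAttributes,
    include_reference: bool = False,
    params: TreeParams | None = None,
) -> dict[tuple[str, str], RegressionTreeModel]:
    """One regression tree of Z_D on island attributes per transition × metric.

    The mainland reference row is excluded by default — the trees explain
    variation among islands.
    """
    attr = attributes.table.set_index(attributes.table["island_id"].astype(str))
    trees = {}
    for (trans, metric), grp in shifts.groupby(["transition", "metric"]):
        grp = grp.set_index("island_id")
        ids = [i for i in grp.index if i in attr.index]
        if len(ids) != len(grp):
            missing = sorted(set(grp.index) - set(ids))
            raise SchemaError(f"islands missing from attribute table: {missing}")
        if not include_reference:
            ids = [i for i in ids if not attr.loc[i, "is_reference"]]
        X = attr.loc[ids, TREE_FEATURES].astype(float)
        if X["sampling_area_ha"].isna().any():
            X = X.drop(columns=["sampling_area_ha"])
        y = grp.loc[ids, "z"].to_numpy()
        trees[(trans, metric)] = fit_tree(X, y, params)
    return trees


def run_analysis(
    config: RunConfig,
    communities: dict[str, LifeStageCommunity] | None = None,
    phylo: dendropy.Tree | None = None,
    attributes: IslandAttributes | None = None,
) -> ReportBundle:
    """Execute the whole pipeline and write the report bundle.

    Data objects may be passed in directly (e.g. a fresh synthetic dataset);
    otherwise they are read from the paths in ``config``.
    """
    t0 = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if communities is None:
        communities = read_communities(config.communities)
    if phylo is None:
        phylo = read_newick(config.phylogeny)
    if attributes is None:
        attributes = read_attributes(config.attributes)
    index = PhyloIndex(phylo)
    log_lines = []

    def log(stage: str, **info) -> None:
        line = f"[{time.time() - t0:8.2f}s] {stage}: " + " ".join(
            f"{k}={v}" for k, v in info.items()
        )
        logger.info(line)
        log_lines.append(line)

    log("inputs", islands=communities["seedling"].n_islands,
        species=communities["seedling"].n_species, seed=config.seed,
        n_rand=config.n_rand)

    results, calls = transition_table(
        communities,
        index,
        n_rand=config.n_rand,
        seed=config.seed,
        method=config.method,
        alpha=config.alpha,
        swap_iterations=config.swap_iterations,
    )
    log("shifts", rows=len(results))
    shifts = _shifts_frame(results)
    calls_df = _calls_frame(calls)

    tree_params = TreeParams(
        minsplit=config.tree_minsplit, cp=config.tree_cp, maxdepth=config.tree_maxdepth
    )
    trees = fit_attribute_trees(
        shifts, attributes, config.include_reference_in_trees, tree_params
    )
    log("trees", fitted=len(trees))

    summary = {
        "seed": config.seed,
        "n_rand": config.n_rand,
        "method": config.method,
        "alpha": config.alpha,
        "stageshift_version": __version__,
        "sign_counts": _sign_counts(shifts),
        "opposing_trend_counts": _opposing_counts(shifts),
        "spearman_sd_pd": _spearman_sd_pd(communities, index),
        "tree_summary": {
            f"{metric}_{trans}": {
                "primary_driver": model.root.split_variable,
                "n_splits": model.n_splits,
                "approx_r2_final": float(model.cp_table["approx_r2"].iloc[-1]),
            }
            for (trans, metric), model in trees.items()
        },
    }
    log("summary", transitions=len(summary["sign_counts"]))

    paths = {
        "shifts": out_dir / "shifts.tsv",
        "calls": out_dir / "assembly_calls.tsv",
        "summary": out_dir / "summary.json",
        "log": out_dir / "run.log",
    }
    shifts.to_csv(paths["shifts"], sep="\t", index=False)
    calls_df.to_csv(paths["calls"], sep="\t", index=False)
    for (trans, metric), model in trees.items():
        jp = out_dir / f"tree_{metric}_{trans}.json"
        cp = out_dir / f"cp_{metric}_{trans}.tsv"
        model.to_json(jp)
        model.cp_table.to_csv(cp, sep="\t", index=False)
        paths[f"tree_{metric}_{trans}"] = jp
        paths[f"cp_{metric}_{trans}"] = cp
    with open(paths["summary"], "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    with open(paths["log"], "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return ReportBundle(
        shifts=shifts, calls=calls_df, summary=summary, trees=trees, paths=paths
    )


# ---------------------------------------------------------------------------
# supplementary-table ingestion

S3_REQUIRED = ["island_id", "z_sd_ss", "z_pd_ss", "z_sd_st", "z_pd_st",
               "area_ha", "isolation_km"]


def ingest_supplement(path, kind: str):
    """Validate a user-supplied supplementary-table export (CSV).

    ``kind="s3"``: per-island standardized differences plus island attributes;
    returns ``(long_shift_frame, attributes)`` ready for sign counting and
    regression trees.  ``kind="s2"``: a species list; returns the frame (the
    distinct species count is its length).  ``kind="s1"``: long-format
    species composition; returns the three life-stage communities.
    """
    if kind == "s1":
        return read_communities(path)
    if kind == "s2":
        df = pd.read_csv(path)
        if "species" not in df.columns:
            raise SchemaError("s2 table must have a 'species' column")
        return df.drop_duplicates(subset="species").reset_index(drop=True)
    if kind == "s3":
        df = pd.read_csv(path)
        missing = [c for c in S3_REQUIRED if c not in df.columns]
        if missing:
            raise SchemaError(
                f"s3 table missing columns {missing}; expected {S3_REQUIRED} "
                "plus optional shape_index, sampling_area_ha, perimeter_km, "
                "is_reference"
            )
        long_rows = []
        for _, row in df.iterrows():
            for trans in ("SS", "ST"):
                for metric in ("SD", "PD"):
                    long_rows.append(
                        {
                            "island_id": str(row["island_id"]),
                            "transition": trans,
                            "metric": metric,
                            "z": float(row[f"z_{metric.lower()}_{trans.lower()}"]),
                        }
                    )
        shifts = pd.DataFrame(long_rows)
        attr = df[[c for c in df.columns if not c.startswith("z_")]].copy()
        if "perimeter_km" not in attr.columns:
            # perimeter not part of the supplement layout; reconstruct from SI
            si = attr["shape_index"] if "shape_index" in attr.columns else 1.0
            attr["perimeter_km"] = (
                si * 2.0 * np.sqrt(np.pi * attr["area_ha"] * 1e4) / 1e3
            )
        attributes = IslandAttributes(attr)
        return shifts, attributes
    raise ConfigurationError(f"unknown supplement kind {kind!r}")


def summarize_s3(shifts: pd.DataFrame, attributes: IslandAttributes,
                 include_reference: bool = False,
                 params: TreeParams | None = None) -> dict:
    """Sign counts, opposing-trend counts and attribute trees for an s3 table."""
    trees = fit_attribute_trees(shifts, attributes, include_reference, params)
    return {
        "sign_counts": _sign_counts(shifts),
        "opposing_trend_counts": _opposing_counts(shifts),
        "tree_approx_r2": {
            f"{metric}_{trans}": float(model.cp_table["approx_r2"].iloc[-1])
            for (trans, metric), model in trees.items()
        },
        "tree_primary_driver": {
            f"{metric}_{trans}": model.root.split_variable
            for (trans, metric), model in trees.items()
        },
    }
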