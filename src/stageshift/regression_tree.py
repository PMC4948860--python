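"""CART regression trees for attributing Z_D shifts to island attributes.

Greedy binary recursive partitioning minimizing within-node sum of squared
errors, with rpart-style control parameters (minsplit, minbucket, cp,
maxdepth) and the apparent ("approximate") r-square report: after k splits,
R² = 1 − (sum of leaf SSE) / SST.  No cross-validation, surrogate splits or
missing-value handling — inputs are validated complete upstream, and the
reported quantity is the apparent R².
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

__all__ = [
    "TreeNode",
    "RegressionTreeModel",
    "TreeParams",
    "fit_tree",
    "approx_r_squared",
    "primary_driver",
]


@dataclass
class TreeParams:
    """rpart-convention control parameters.

    minsplit : smallest node that may be split (default 20).
    minbucket : smallest allowed child node (default round(minsplit / 3)).
    cp : complexity parameter; a split must improve R² by at least cp.
    maxdepth : maximum depth below the root.
    """

    minsplit: int = 20
    minbucket: int | None = None
    cp: float = 0.01
    maxdepth: int = 30

    def __post_init__(self) -> None:
        if self.minbucket is None:
            self.minbucket = int(round(self.minsplit / 3))
        if self.minsplit < 2 or self.minbucket < 1 or self.maxdepth < 1:
            raise InvalidArgumentError("invalid tree control parameters")
        if self.cp < 0:
            raise InvalidArgumentError("cp must be >= 0")


@dataclass
class TreeNode:
    n: int
    mean: float
    sse: float
    split_variable: str | None = None
    threshold: float | None = None
    improvement: float = 0.0  # SSE reduction achieved by this node's split
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.split_variable is None

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()

    def internal_nodes(self) -> list["TreeNode"]:
        if self.is_leaf:
            return []
        return [self] + self.left.internal_nodes() + self.right.internal_nodes()


@dataclass
class RegressionTreeModel:
    root: TreeNode
    feature_names: list[str]
    sst: float
    n: int
    params: TreeParams
    cp_table: pd.DataFrame = field(repr=False)

    @property
    def n_splits(self) -> int:
        return len(self.root.internal_nodes())

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        out = np.empty(len(X))
        for i, (_, row) in enumerate(X.iterrows()):
            node = self.root
            while not node.is_leaf:
                node = (
                    node.left
                    if row[node.split_variable] < node.threshold
                    else node.right
                )
            out[i] = node.mean
        return out

    def render(self) -> str:
        lines: list[str] = []

        def walk(node: TreeNode, prefix: str, label: str) -> None:
            if node.is_leaf:
                lines.append(f"{prefix}{label}leaf: mean={node.mean:.4f} n={node.n}")
            else:
                lines.append(
                    f"{prefix}{label}{node.split_variable} < {node.threshold:.6g} "
                    f"(mean={node.mean:.4f}, n={node.n})"
                )
                walk(node.left, prefix + "  ", "yes: ")
                walk(node.right, prefix + "  ", "no:  ")

        walk(self.root, "", "")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        def node_dict(node: TreeNode) -> dict:
            d = {"n": node.n, "mean": node.mean, "sse": node.sse}
            if not node.is_leaf:
                d.update(
                    split_variable=node.split_variable,
                    threshold=node.threshold,
                    improvement=node.improvement,
                    left=node_dict(node.left),
                    right=node_dict(node.right),
                )
            return d

        return {
            "n": self.n,
            "sst": self.sst,
            "n_splits": self.n_splits,
            "tree": node_dict(self.root),
            "cp_table": self.cp_table.to_dict(orient="records"),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _node_stats(y: np.ndarray) -> tuple[int, float, float]:
    n = y.size
    mean = float(y.mean())
    sse = float(((y - mean) ** 2).sum())
    return n, mean, sse


def best_split(
    X: np.ndarray, y: np.ndarray, feature_names: list[str], minbucket: int
) -> tuple[int, float, float] | None:
    """Exhaustive best (feature, threshold) by SSE reduction.

    Candidate thresholds are midpoints of consecutive sorted unique values.
    Ties are broken by feature column order, then by smaller threshold (the
    scan order), via strict improvement comparison.  Returns
    ``(feature_index, threshold, improvement)`` or None if no admissible
    split exists.
    """
    n = y.size
    best: tuple[int, float, float] | None = None
    total = y.sum()
    for j in range(X.shape[1]):
        v = X[:, j]
        order = np.argsort(v, kind="stable")
        vs, ys = v[order], y[order]
        csum = np.cumsum(ys)
        ks = np.arange(1, n)
        valid = vs[1:] > vs[:-1]
        valid &= (ks >= minbucket) & (n - ks >= minbucket)
        if not valid.any():
            continue
        left_sum = csum[:-1]
        improvement = (
            left_sum**2 / ks + (total - left_sum) ** 2 / (n - ks) - total**2 / n
        )
        improvement = np.where(valid, improvement, -np.inf)
        k = int(np.argmax(improvement))
        imp = float(improvement[k])
        thr = float((vs[k] + vs[k + 1]) / 2.0)
        if best is None or imp > best[2]:
            best = (j, thr, imp)
    return best


def _grow(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str],
    params: TreeParams,
    sst_root: float,
    depth: int,
) -> TreeNode:
    n, mean, sse = _node_stats(y)
    node = TreeNode(n=n, mean=mean, sse=sse)
    if n < params.minsplit or depth >= params.maxdepth or sse <= 0:
        return node
    found = best_split(X, y, feature_names, params.minbucket)
    if found is None:
        return node
    j, thr, imp = found
    if sst_root <= 0 or imp < params.cp * sst_root:
        return node
    mask = X[:, j] < thr
    node.split_variable = feature_names[j]
    node.threshold = thr
    node.improvement = imp
    node.left = _grow(X[mask], y[mask], feature_names, params, sst_root, depth + 1)
    node.right = _grow(X[~mask], y[~mask], feature_names, params, sst_root, depth + 1)
    return node


def _leaf_sse(node: TreeNode) -> float:
    return sum(leaf.sse for leaf in node.leaves())


def _weakest_link_table(root: TreeNode, sst: float, cp_min: float) -> pd.DataFrame:
    """Cost-complexity (weakest-link) pruning sequence, rpart printcp style.

    Rows run from the root-only tree (0 splits) to the full grown tree; the
    ``complexity`` column is the per-split normalized improvement at which
    each tree size becomes optimal; ``relative_error`` is leaf SSE / SST.
    """
    import copy

    tree = copy.deepcopy(root)
    rows = [
        {
            "n_splits": len(tree.internal_nodes()),
            "relative_error": _leaf_sse(tree) / sst if sst > 0 else 1.0,
            "complexity": cp_min,
        }
    ]
    while not tree.is_leaf:
        # weakest link: internal node whose subtree gives least per-split gain
        candidates = []
        for node in tree.internal_nodes():
            n_sub = len(node.internal_nodes())
            g = (node.sse - _leaf_sse(node)) / n_sub
            candidates.append((g, node))
        g_min, weakest = min(candidates, key=lambda t: t[0])
        weakest.split_variable = None
        weakest.threshold = None
        weakest.left = None
        weakest.right = None
        rows.append(
            {
                "n_splits": len(tree.internal_nodes()),
                "relative_error": _leaf_sse(tree) / sst if sst > 0 else 1.0,
                "complexity": g_min / sst if sst > 0 else 0.0,
            }
        )
    table = pd.DataFrame(rows).sort_values("n_splits").reset_index(drop=True)
    table["approx_r2"] = 1.0 - table["relative_error"]
    return table[["n_splits", "complexity", "relative_error", "approx_r2"]]


def fit_tree(
    X: pd.DataFrame, y, params: TreeParams | None = None
) -> RegressionTreeModel:
    """Fit a CART regression tree of y on the attribute columns of X.

    Splits are accepted greedily while the node has at least ``minsplit``
    rows, both children would keep ``minbucket``, depth stays within
    ``maxdepth``, and the split improves R² by at least ``cp``.  A constant
    response yields a root-only tree.  The fit is fully deterministic.
    """
    if params is None:
        params = TreeParams()
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(X)
    if X.shape[1] == 0 or len(X) == 0:
        raise InvalidArgumentError("X must have at least one row and one column")
    y = np.asarray(y, dtype=float)
    if y.shape != (len(X),):
        raise InvalidArgumentError(f"y length {y.size} != X rows {len(X)}")
    if np.isnan(y).any() or X.isna().any().any():
        raise InvalidArgumentError("missing values are not supported")
    feature_names = [str(c) for c in X.columns]
    Xv = X.to_numpy(dtype=float)
    _, _, sst = _node_stats(y)
    root = _grow(Xv, y, feature_names, params, sst, depth=0)
    cp_table = _weakest_link_table(root, sst, params.cp)
    return RegressionTreeModel(
        root=root,
        feature_names=feature_names,
        sst=sst,
        n=y.size,
        params=params,
        cp_table=cp_table,
    )


def approx_r_squared(model: RegressionTreeModel) -> np.ndarray:
    """Apparent R² after k = 0 … n_splits splits (non-decreasing, in [0, 1])."""
    return model.cp_table["approx_r2"].to_numpy()


def primary_driver(model: RegressionTreeModel) -> str | None:
    """The attribute split at the root, or None for a root-only tree."""
    return model.root.split_variable
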