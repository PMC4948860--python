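"""Phylogeny I/O, Faith's phylogenetic diversity and Blomberg's K.

The tree container is a :class:`dendropy.Tree` (rooted, branch lengths in any
consistent unit).  Faith's PD is the total branch length of the subtree
linking a species set; by this package's default convention the path to the
root is included, so the PD of a single species equals its root-to-tip
distance and PD of the full tip set equals the total tree length.  Blomberg's
K measures phylogenetic signal in a continuous trait: the ratio of observed
to Brownian-motion-expected (MSE0/MSE), which is ~1 under Brownian evolution,
<1 for less signal than Brownian, >1 for more.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, NewickParseError

__all__ = [
    "parse_newick",
    "read_newick",
    "write_newick",
    "PhyloIndex",
    "faith_pd",
    "prune_to_species",
    "blomberg_k",
    "PhyloSignalResult",
    "total_tree_length",
    "tip_labels",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Newick I/O


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string into a rooted tree.

    Branch lengths are expected; any that are missing are set to 0 with a
    logged warning (megatree exports often drop internal edge lengths).
    Duplicate tip labels and malformed syntax raise :class:`NewickParseError`
    naming the offending token.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except (dendropy.utility.error.DataParseError, ValueError) as exc:
        raise NewickParseError(str(exc)) from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if any(lbl is None or lbl == "" for lbl in labels):
        raise NewickParseError("tree contains unlabeled tips")
    n_missing = 0
    for node in tree:
        if node.parent_node is not None and node.edge.length is None:
            node.edge.length = 0.0
            n_missing += 1
        if node.edge.length is not None and node.edge.length < 0:
            raise NewickParseError(
                f"negative branch length {node.edge.length} on edge to "
                f"{node.taxon.label if node.taxon else 'internal node'}"
            )
    if n_missing:
        logger.warning("%d missing branch lengths set to 0", n_missing)
    return tree


def read_newick(path) -> dendropy.Tree:
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick(tree: dendropy.Tree, path=None) -> str:
    """Serialize a tree to Newick; write to ``path`` if given."""
    text = tree.as_string(schema="newick", suppress_rooting=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def total_tree_length(tree: dendropy.Tree) -> float:
    """Sum of all branch lengths, including any root (stem) edge."""
    internal = sum(
        node.edge.length or 0.0 for node in tree if node.parent_node is not None
    )
    return internal + (tree.seed_node.edge.length or 0.0)


# ---------------------------------------------------------------------------
# Faith's PD


class PhyloIndex:
    """Edge-incidence index of a rooted tree for fast repeated PD queries.

    Rows are tips, columns are tree edges (one per non-root node); entry
    (t, e) is True when edge e lies on the path from the root to tip t.  The
    PD of a species set is then the length-weighted cover of the union of its
    tips' rows, which vectorizes over whole island × species presence
    matrices — the shape the null-model ensembles need.
    """

    def __init__(self, tree: dendropy.Tree):
        tips = [leaf for leaf in tree.leaf_node_iter()]
        self.tips = [leaf.taxon.label for leaf in tips]
        if len(set(self.tips)) != len(self.tips):
            raise InvalidArgumentError("duplicate tip labels in tree")
        self.tip_index = {lbl: i for i, lbl in enumerate(self.tips)}
        edge_nodes = [n for n in tree.preorder_node_iter() if n.parent_node is not None]
        node_to_edge = {id(n): j for j, n in enumerate(edge_nodes)}
        lengths = [n.edge.length or 0.0 for n in edge_nodes]
        inc = np.zeros((len(tips), len(edge_nodes) + 1), dtype=bool)
        for i, leaf in enumerate(tips):
            node = leaf
            while node.parent_node is not None:
                inc[i, node_to_edge[id(node)]] = True
                node = node.parent_node
        # a root (stem) edge — e.g. left by pruning — is shared by every tip
        lengths.append(tree.seed_node.edge.length or 0.0)
        inc[:, -1] = True
        self.edge_lengths = np.array(lengths, dtype=float)
        self.incidence = inc
        # root-ward depth of each edge's child node, for MRCA-depth queries
        self._tip_depths = inc @ self.edge_lengths

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    def presence_matrix(self, species_lists: Iterable[Iterable[str]]) -> np.ndarray:
        """Stack species sets into a (n_sets, n_tips) boolean matrix."""
        rows = []
        for species in species_lists:
            row = np.zeros(self.n_tips, dtype=bool)
            for s in species:
                row[self.tip_index[s]] = True
            rows.append(row)
        return np.array(rows)

    def pd_from_presence(self, presence: np.ndarray) -> np.ndarray:
        """Faith PD (root included) for each row of a presence matrix.

        Rows with no species present get PD 0.
        """
        presence = np.atleast_2d(np.asarray(presence, dtype=bool))
        cover = presence @ self.incidence.astype(np.int64) > 0
        return cover @ self.edge_lengths

    def mrca_depth(self, species: Iterable[str]) -> float:
        """Root-to-MRCA distance of a species set (0 for the root itself)."""
        idx = [self.tip_index[s] for s in species]
        shared = self.incidence[idx].all(axis=0)
        return float(self.edge_lengths[shared].sum())


def faith_pd(
    tree: dendropy.Tree | PhyloIndex,
    species: Iterable[str],
    include_root: bool = True,
    on_missing: str = "error",
) -> float:
    """Faith's phylogenetic diversity of a species set.

    Sum of the branch lengths of the minimal subtree linking the species;
    with ``include_root=True`` (default) the path up to the root is part of
    that subtree, so a singleton community has PD equal to its root-to-tip
    distance.  With ``include_root=False`` edges above the set's MRCA are
    excluded (classical minimal spanning subtree).

    ``on_missing`` is ``"error"`` (default: raise listing unknown labels) or
    ``"drop"`` (ignore them with a logged warning).
    """
    index = tree if isinstance(tree, PhyloIndex) else PhyloIndex(tree)
    species = list(dict.fromkeys(species))
    missing = [s for s in species if s not in index.tip_index]
    if missing:
        if on_missing == "drop":
            logger.warning("dropping %d species not in tree: %s", len(missing), missing)
            species = [s for s in species if s in index.tip_index]
        else:
            raise InvalidArgumentError(f"species not in tree: {missing}")
    if not species:
        raise InvalidArgumentError("species set is empty")
    presence = index.presence_matrix([species])
    pd_root = float(index.pd_from_presence(presence)[0])
    if include_root:
        return pd_root
    return pd_root - index.mrca_depth(species)


def prune_to_species(tree: dendropy.Tree, species: Iterable[str]) -> dendropy.Tree:
    """Prune a tree to a species subset, collapsing unary nodes.

    Collapsed chains have their branch lengths summed, so root-to-tip
    distances of retained tips are preserved, and so is any PD computed over
    subsets of the retained species.
    """
    species = list(dict.fromkeys(species))
    if not species:
        raise InvalidArgumentError("cannot prune to an empty species set")
    tips = set(tip_labels(tree))
    missing = [s for s in species if s not in tips]
    if missing:
        raise InvalidArgumentError(f"species not in tree: {missing}")
    pruned = tree.extract_tree_with_taxa_labels(species)
    return pruned


# ---------------------------------------------------------------------------
# Blomberg's K


@dataclass(frozen=True)
class PhyloSignalResult:
    """Blomberg's K with its permutation significance."""

    K: float
    p_value: float
    n_permutations: int


def _vcv_from_index(index: PhyloIndex) -> np.ndarray:
    """Branch-length covariance matrix: V[i, j] = depth of MRCA(i, j)."""
    inc = index.incidence.astype(float)
    return (inc * index.edge_lengths) @ inc.T


def blomberg_k(
    tree: dendropy.Tree,
    traits: Mapping[str, float] | pd.Series,
    n_permutations: int = 999,
    seed: int | None = None,
) -> PhyloSignalResult:
    """Blomberg's K statistic of phylogenetic signal with a permutation test.

    K is the ratio of the observed MSE0/MSE to its expectation under Brownian
    motion, where MSE0 is the variance of tip values about the phylogenetically
    corrected mean and MSE is the generalized least-squares error under the
    branch-length covariance V:

        observed = MSE0 / MSE
        expected = (tr V - n / sum(V^-1)) / (n - 1)
        K = observed / expected

    Both mean squares use the n−1 denominator of the original formulation.
    The p-value is the proportion of tip-label permutations whose MSE is as
    small or smaller than observed (small MSE = trait variance concentrated
    where the tree expects it), with the +1 continuity correction.
    """
    index = PhyloIndex(tree)
    n = index.n_tips
    if n < 4:
        raise InvalidArgumentError(f"Blomberg's K needs >= 4 tips, got {n}")
    x = np.array([float(traits[t]) for t in index.tips])
    if np.isnan(x).any():
        raise InvalidArgumentError("traits contain NaN")
    V = _vcv_from_index(index)
    try:
        Vinv = np.linalg.inv(V)
    except np.linalg.LinAlgError as exc:
        raise InvalidArgumentError(
            "singular phylogenetic covariance matrix (zero-length branches "
            "producing identical tips?); collapse duplicate tips or add "
            "minimal branch lengths"
        ) from exc
    ones = np.ones(n)
    denom = ones @ Vinv @ ones
    expected = (np.trace(V) - n / denom) / (n - 1)

    def mse_pair(vals: np.ndarray) -> tuple[float, float]:
        ahat = (ones @ Vinv @ vals) / denom
        dev = vals - ahat
        mse0 = float(dev @ dev) / (n - 1)
        mse = float(dev @ Vinv @ dev) / (n - 1)
        return mse0, mse

    mse0_obs, mse_obs = mse_pair(x)
    if mse_obs <= 0:
        raise InvalidArgumentError("degenerate traits: zero GLS mean square")
    K = (mse0_obs / mse_obs) / expected

    if n_permutations <= 0:
        return PhyloSignalResult(K=K, p_value=1.0, n_permutations=0)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        _, mse_perm = mse_pair(rng.permutation(x))
        if mse_perm <= mse_obs:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return PhyloSignalResult(K=K, p_value=p, n_permutations=n_permutations)
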