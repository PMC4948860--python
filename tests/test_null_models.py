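from collections import Counter

import numpy as np
import pytest
from scipy import stats

import stageshift as ss
from stageshift.errors import ConfigurationError, InvalidArgumentError
from stageshift.null_models import (
    _has_checkerboard,
    _swap_kernel,
    _swap_kernel_py,
    independent_swap,
    individual_pool_null,
    null_diff_ensemble,
)


def random_community(rng, n_islands=4, n_species=6, stage="sapling"):
    mat = rng.integers(0, 6, size=(n_islands, n_species))
    if mat.sum() == 0:
        mat[0, 0] = 1
    return ss.LifeStageCommunity(
        [f"i{k}" for k in range(n_islands)],
        [f"s{k}" for k in range(n_species)],
        mat,
        stage,
    )


class TestCommunityValidation:
    def test_negative_abundance_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ss.LifeStageCommunity(["a"], ["x", "y"], np.array([[1, -1]]), "tree")

    def test_duplicate_labels_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ss.LifeStageCommunity(["a", "a"], ["x"], np.array([[1], [2]]), "tree")

    def test_unknown_stage_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ss.LifeStageCommunity(["a"], ["x"], np.array([[1]]), "adult")


class TestIndividualPoolNull:
    def test_margins_conserved_exactly(self):
        rng = np.random.default_rng(0)
        for t in range(50):
            comm = random_community(rng)
            draw = individual_pool_null(comm, seed=rng)
            assert (draw.abundance.sum(0) == comm.abundance.sum(0)).all()
            assert (draw.abundance.sum(1) == comm.abundance.sum(1)).all()

    def test_single_island_forced_identity(self):
        comm = ss.LifeStageCommunity(
            ["only"], ["x", "y", "z"], np.array([[3, 1, 2]]), "seedling"
        )
        draw = individual_pool_null(comm, seed=1)
        assert (draw.abundance == comm.abundance).all()

    def test_two_state_margins_equidistributed(self):
        comm = ss.LifeStageCommunity(
            ["a", "b"], ["x", "y"], np.array([[1, 0], [0, 1]]), "seedling"
        )
        rng = np.random.default_rng(3)
        hits = sum(
            individual_pool_null(comm, seed=rng).abundance[0, 0] for _ in range(2000)
        )
        assert abs(hits / 2000 - 0.5) < 0.05

    def test_nonequal_weights_follow_pool_permutation_law(self):
        # margins (2,1) x (2,1): table [[2,0],[0,1]] has probability 1/3 and
        # [[1,1],[1,0]] probability 2/3 under dealing the pooled individuals
        # (multivariate hypergeometric), not 1/2 each
        comm = ss.LifeStageCommunity(
            ["a", "b"], ["x", "y"], np.array([[2, 0], [0, 1]]), "seedling"
        )
        rng = np.random.default_rng(4)
        n = 3000
        hits = sum(
            individual_pool_null(comm, seed=rng).abundance[0, 0] == 2
            for _ in range(n)
        )
        assert abs(hits / n - 1 / 3) < 0.03


class TestIndependentSwap:
    def test_constraints_conserved(self):
        rng = np.random.default_rng(1)
        for t in range(30):
            comm = random_community(rng)
            draw = independent_swap(comm, 2000, seed=rng)
            assert ((draw.abundance > 0).sum(0) == (comm.abundance > 0).sum(0)).all()
            assert (draw.richness() == comm.richness()).all()
            assert (draw.abundance.sum(0) == comm.abundance.sum(0)).all()
            for col in range(comm.n_species):
                assert Counter(draw.abundance[:, col]) == Counter(
                    comm.abundance[:, col]
                )

    def test_no_checkerboard_returns_unchanged(self):
        comm = ss.LifeStageCommunity(
            ["a", "b"], ["x", "y"], np.array([[2, 3], [4, 0]]), "tree"
        )
        assert not _has_checkerboard(comm.presence())
        draw = independent_swap(comm, 500, seed=0)
        assert (draw.abundance == comm.abundance).all()

    def test_two_state_chain_equidistributed(self):
        comm = ss.LifeStageCommunity(
            ["a", "b"], ["x", "y"], np.array([[1, 0], [0, 1]]), "tree"
        )
        rng = np.random.default_rng(5)
        hits = sum(
            independent_swap(comm, 51, seed=rng).abundance[0, 0] for _ in range(2000)
        )
        assert abs(hits / 2000 - 0.5) < 0.05

    def test_jit_kernel_matches_pure_python(self):
        rng = np.random.default_rng(9)
        comm = random_community(rng, 5, 7)
        inc1 = comm.presence().astype(np.int8)
        ab1 = comm.abundance.astype(np.int64).copy()
        inc2, ab2 = inc1.copy(), ab1.copy()
        r1 = rng.integers(0, 5, 400)
        r2 = rng.integers(0, 5, 400)
        c1 = rng.integers(0, 7, 400)
        c2 = rng.integers(0, 7, 400)
        n1 = _swap_kernel(inc1, ab1, r1, r2, c1, c2)
        n2 = _swap_kernel_py(inc2, ab2, r1, r2, c1, c2)
        assert n1 == n2
        assert (inc1 == inc2).all() and (ab1 == ab2).all()


class TestNullDiffEnsemble:
    def make_pair(self, seed=0):
        rng = np.random.default_rng(seed)
        older = random_community(rng, 5, 8, "sapling")
        younger = random_community(rng, 5, 8, "seedling")
        return older, younger

    def test_shape_contract(self):
        older, younger = self.make_pair()
        ens = null_diff_ensemble(older, younger, "SD", n_rand=2, seed=0)
        assert ens.diffs.shape == (5, 2)
        assert ens.stage_pair == "SS"

    def test_identical_stages_center_on_zero(self):
        rng = np.random.default_rng(2)
        comm = random_community(rng, 6, 10, "sapling")
        younger = ss.LifeStageCommunity(
            comm.islands, comm.species, comm.abundance.copy(), "seedling"
        )
        ens = null_diff_ensemble(comm, younger, "SD", n_rand=400, seed=1)
        se = ens.diffs.std(axis=1, ddof=1) / np.sqrt(400)
        assert (np.abs(ens.diffs.mean(axis=1)) <= 2 * np.maximum(se, 1e-9) + 1e-9).all()

    def test_deterministic_under_seed(self):
        older, younger = self.make_pair()
        a = null_diff_ensemble(older, younger, "SD", n_rand=50, seed=7)
        b = null_diff_ensemble(older, younger, "SD", n_rand=50, seed=7)
        assert (a.diffs == b.diffs).all()

    def test_pd_requires_phylogeny(self):
        older, younger = self.make_pair()
        with pytest.raises(ConfigurationError):
            null_diff_ensemble(older, younger, "PD", n_rand=10, seed=0)

    def test_pd_ensemble_runs_with_tree(self):
        older, younger = self.make_pair()
        tree = ss.simulate_phylogeny(8, seed=4)
        relabel = {
            old: new
            for old, new in zip(
                older.species, [l.taxon.label for l in tree.leaf_node_iter()]
            )
        }
        older = ss.LifeStageCommunity(
            older.islands, [relabel[s] for s in older.species],
            older.abundance, "sapling",
        )
        younger = ss.LifeStageCommunity(
            younger.islands, [relabel[s] for s in younger.species],
            younger.abundance, "seedling",
        )
        ens = null_diff_ensemble(
            older, younger, "PD", phylo=tree, n_rand=20, seed=3, swap_iterations=500
        )
        assert ens.diffs.shape == (5, 20)
        assert np.isfinite(ens.diffs).all()
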