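import numpy as np
import pytest
from scipy import stats

import stageshift as ss
from stageshift.errors import InvalidArgumentError, NewickParseError
from stageshift.phylodiversity import PhyloIndex, total_tree_length, tip_labels

from conftest import brute_force_pd


class TestNewickIO:
    def test_parse_counts_and_total_length(self, small_tree):
        assert sorted(tip_labels(small_tree)) == ["A", "B", "C"]
        internal = [
            n for n in small_tree.preorder_node_iter() if not n.is_leaf()
        ]
        assert len(internal) == 2
        assert total_tree_length(small_tree) == pytest.approx(5.0)

    def test_round_trip_preserves_topology_and_lengths(self):
        tree = ss.simulate_phylogeny(15, seed=3)
        text = ss.write_newick(tree)
        again = ss.parse_newick(text)
        assert ss.write_newick(again) == text

    def test_duplicate_tips_rejected(self):
        with pytest.raises(NewickParseError, match="A"):
            ss.parse_newick("(A:1,A:2);")

    def test_unbalanced_parentheses_rejected(self):
        with pytest.raises(NewickParseError):
            ss.parse_newick("((A:1,B:1;")

    def test_missing_lengths_become_zero_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            tree = ss.parse_newick("((A,B):1,C:2);")
        assert total_tree_length(tree) == pytest.approx(3.0)
        assert any("missing branch lengths" in r.message for r in caplog.records)


class TestFaithPD:
    def test_full_set_equals_total_length(self, small_tree):
        assert ss.faith_pd(small_tree, ["A", "B", "C"]) == pytest.approx(5.0)

    def test_pair_includes_stem(self, small_tree):
        assert ss.faith_pd(small_tree, ["A", "B"]) == pytest.approx(3.0)

    def test_singleton_is_root_to_tip_distance(self, small_tree):
        assert ss.faith_pd(small_tree, ["C"]) == pytest.approx(2.0)

    def test_root_exclusion_stops_at_mrca(self, small_tree):
        assert ss.faith_pd(small_tree, ["A", "B"], include_root=False) == (
            pytest.approx(2.0)
        )

    def test_unknown_species_raise_unless_dropped(self, small_tree):
        with pytest.raises(InvalidArgumentError, match="ghost"):
            ss.faith_pd(small_tree, ["A", "ghost"])
        assert ss.faith_pd(small_tree, ["A", "ghost"], on_missing="drop") == (
            pytest.approx(2.0)
        )

    def test_matches_scikit_bio_reference(self):
        from io import StringIO

        from skbio import TreeNode
        from skbio.diversity.alpha import faith_pd as skbio_faith_pd

        rng = np.random.default_rng(3)
        tree = ss.simulate_phylogeny(15, seed=21)
        newick = ss.write_newick(tree)
        sk_tree = TreeNode.read(StringIO(newick))
        tips = tip_labels(tree)
        for _ in range(10):
            k = int(rng.integers(1, 16))
            subset = set(rng.choice(tips, size=k, replace=False))
            counts = np.array([int(t in subset) for t in tips])
            ref = skbio_faith_pd(counts, taxa=tips, tree=sk_tree)
            assert ss.faith_pd(tree, subset) == pytest.approx(ref, abs=1e-9)

    def test_matches_bruteforce_on_random_trees(self):
        rng = np.random.default_rng(42)
        for t in range(20):
            tree = ss.simulate_phylogeny(20, seed=1000 + t)
            index = PhyloIndex(tree)
            tips = index.tips
            for _ in range(5):
                k = rng.integers(1, 21)
                subset = list(rng.choice(tips, size=k, replace=False))
                assert ss.faith_pd(index, subset) == pytest.approx(
                    brute_force_pd(tree, subset), abs=1e-9
                )

    def test_monotone_in_species_set(self):
        rng = np.random.default_rng(7)
        tree = ss.simulate_phylogeny(25, seed=11)
        tips = tip_labels(tree)
        for _ in range(20):
            k1 = rng.integers(1, 20)
            s1 = list(rng.choice(tips, size=k1, replace=False))
            extra = [t for t in tips if t not in s1]
            s2 = s1 + list(rng.choice(extra, size=rng.integers(1, len(extra) + 1),
                                      replace=False))
            assert ss.faith_pd(tree, s1) <= ss.faith_pd(tree, s2) + 1e-12


class TestPrune:
    def test_prune_to_all_tips_is_identity(self, small_tree):
        pruned = ss.prune_to_species(small_tree, ["A", "B", "C"])
        assert total_tree_length(pruned) == pytest.approx(5.0)
        assert sorted(tip_labels(pruned)) == ["A", "B", "C"]

    def test_root_to_tip_distances_preserved(self, small_tree):
        pruned = ss.prune_to_species(small_tree, ["A", "C"])
        dists = {
            l.taxon.label: l.distance_from_root() for l in pruned.leaf_node_iter()
        }
        assert dists["A"] == pytest.approx(2.0)
        assert dists["C"] == pytest.approx(2.0)

    def test_pd_preserved_for_subsets_of_pruned_species(self):
        rng = np.random.default_rng(5)
        tree = ss.simulate_phylogeny(20, seed=9)
        tips = tip_labels(tree)
        for _ in range(25):
            k = rng.integers(2, 13)
            kept = list(rng.choice(tips, size=k, replace=False))
            pruned = ss.prune_to_species(tree, kept)
            sub = list(rng.choice(kept, size=rng.integers(1, k + 1), replace=False))
            assert ss.faith_pd(pruned, sub) == pytest.approx(
                ss.faith_pd(tree, sub), abs=1e-9
            )

    def test_empty_set_rejected(self, small_tree):
        with pytest.raises(InvalidArgumentError):
            ss.prune_to_species(small_tree, [])


class TestBlombergK:
    def test_star_tree_gives_exactly_one(self):
        star = ss.parse_newick("(A:1,B:1,C:1,D:1,E:1);")
        traits = {"A": 0.3, "B": -1.2, "C": 0.5, "D": 2.0, "E": 0.1}
        res = ss.blomberg_k(star, traits, n_permutations=0)
        assert res.K == pytest.approx(1.0, abs=1e-9)

    def test_brownian_traits_center_on_one(self):
        tree = ss.simulate_phylogeny(64, seed=5)
        ks = [
            ss.blomberg_k(
                tree, ss.simulate_traits_bm(tree, 1.0, seed=r), n_permutations=0
            ).K
            for r in range(200)
        ]
        assert 0.8 <= np.mean(ks) <= 1.2

    def test_noise_traits_show_no_signal(self):
        tree = ss.simulate_phylogeny(64, seed=5)
        tips = tip_labels(tree)
        rng = np.random.default_rng(0)
        ks, ps = [], []
        for r in range(25):
            traits = dict(zip(tips, rng.normal(size=len(tips))))
            res = ss.blomberg_k(tree, traits, n_permutations=199, seed=r)
            ks.append(res.K)
            ps.append(res.p_value)
        assert np.median(ks) < 1.0
        assert np.median(ps) > 0.05

    def test_permutation_p_uniform_under_exchangeable_noise(self):
        tree = ss.simulate_phylogeny(32, seed=8)
        tips = tip_labels(tree)
        rng = np.random.default_rng(1)
        ps = [
            ss.blomberg_k(
                tree,
                dict(zip(tips, rng.normal(size=len(tips)))),
                n_permutations=199,
                seed=r,
            ).p_value
            for r in range(300)
        ]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_small_trees_rejected(self, small_tree):
        with pytest.raises(InvalidArgumentError):
            ss.blomberg_k(small_tree, {"A": 1, "B": 2, "C": 3})
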