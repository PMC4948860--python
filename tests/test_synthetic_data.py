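import numpy as np
import pandas as pd
import pytest

import stageshift as ss
from stageshift.errors import InvalidArgumentError, SchemaError
from stageshift.phylodiversity import PhyloIndex, tip_labels, write_newick
from stageshift.synthetic_data import early_burst_tree


class TestSimulatePhylogeny:
    def test_smallest_binary_tree(self):
        tree = ss.simulate_phylogeny(2, seed=0)
        leaves = list(tree.leaf_node_iter())
        internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
        assert len(leaves) == 2 and len(internal) == 1

    def test_deterministic_newick_under_seed(self):
        a = write_newick(ss.simulate_phylogeny(92, seed=5))
        b = write_newick(ss.simulate_phylogeny(92, seed=5))
        assert a == b

    def test_ultrametric(self):
        tree = ss.simulate_phylogeny(50, seed=3)
        depths = [l.distance_from_root() for l in tree.leaf_node_iter()]
        assert max(depths) - min(depths) < 1e-9

    def test_strictly_positive_branch_lengths(self):
        tree = ss.simulate_phylogeny(40, seed=11)
        for node in tree.preorder_node_iter():
            if node.parent_node is not None:
                assert node.edge.length > 0

    def test_too_few_species_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ss.simulate_phylogeny(1, seed=0)


class TestSimulateTraitsBM:
    def test_zero_variance_limit(self):
        tree = ss.simulate_phylogeny(10, seed=1)
        traits = ss.simulate_traits_bm(tree, 0.0, seed=0)
        assert (traits == 0.0).all()

    def test_negative_rate_rejected(self):
        tree = ss.simulate_phylogeny(5, seed=1)
        with pytest.raises(InvalidArgumentError):
            ss.simulate_traits_bm(tree, -1.0)

    def test_tip_covariance_matches_shared_branch_lengths(self):
        tree = ss.simulate_phylogeny(32, seed=2)
        index = PhyloIndex(tree)
        inc = index.incidence.astype(float)
        V = (inc * index.edge_lengths) @ inc.T
        sims = np.array(
            [
                ss.simulate_traits_bm(tree, 1.0, seed=r).reindex(index.tips)
                for r in range(1500)
            ]
        )
        emp = (sims.T @ sims) / len(sims)  # known zero root value
        rel = np.linalg.norm(emp - V) / np.linalg.norm(V)
        assert rel < 0.10


class TestEarlyBurst:
    def test_zero_decay_is_identity(self):
        tree = ss.simulate_phylogeny(12, seed=4)
        assert write_newick(early_burst_tree(tree, 0.0)) == write_newick(tree)

    def test_depth_concentrated_variance(self):
        tree = ss.simulate_phylogeny(12, seed=4)
        eb = early_burst_tree(tree, 6.0)
        # terminal branches shrink relative to the deepest ones
        def terminal_fraction(t):
            total = sum(n.edge.length for n in t if n.parent_node is not None)
            term = sum(l.edge.length for l in t.leaf_node_iter())
            return term / total

        assert terminal_fraction(eb) < terminal_fraction(tree)


class TestSimulateIslandAttributes:
    def test_shape_index_bound_and_area_range(self):
        attrs = ss.simulate_island_attributes(29, seed=0)
        islands = attrs.table[~attrs.table["is_reference"]]
        assert (attrs.table["shape_index"] >= 1.0 - 1e-9).all()
        assert islands["area_ha"].min() >= 0.25
        assert islands["area_ha"].max() <= 200.0
        assert (attrs.table["isolation_km"] >= 0).all()

    def test_deterministic(self):
        a = ss.simulate_island_attributes(10, seed=1).table
        b = ss.simulate_island_attributes(10, seed=1).table
        pd.testing.assert_frame_equal(a, b)

    def test_reference_site_is_largest_and_touching(self):
        attrs = ss.simulate_island_attributes(15, seed=2).table
        ref = attrs[attrs["is_reference"]]
        assert len(ref) == 1
        assert ref["area_ha"].iloc[0] == attrs["area_ha"].max()
        assert ref["isolation_km"].iloc[0] == 0.0


class TestScenarioConfig:
    def test_invalid_values_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ss.ScenarioConfig(n_islands=1)
        with pytest.raises(InvalidArgumentError):
            ss.ScenarioConfig(n_species=2)
        with pytest.raises(InvalidArgumentError):
            ss.ScenarioConfig(process_ss="predation")
        with pytest.raises(InvalidArgumentError):
            ss.ScenarioConfig(strength=-0.5)


@pytest.fixture(scope="module")
def meta_dataset():
    return ss.simulate_dataset(ss.ScenarioConfig(seed=3))


class TestSimulateMetacommunity:
    def test_nested_thinning(self, meta_dataset):
        see = meta_dataset.communities["seedling"].abundance
        sap = meta_dataset.communities["sapling"].abundance
        tre = meta_dataset.communities["tree"].abundance
        assert (tre <= sap).all() and (sap <= see).all()

    def test_species_are_phylogeny_tips(self, meta_dataset):
        tips = set(tip_labels(meta_dataset.phylogeny))
        for comm in meta_dataset.communities.values():
            assert set(comm.species) <= tips

    def test_reference_row_present(self, meta_dataset):
        assert "mainland" in meta_dataset.communities["seedling"].islands

    def test_trait_tip_mismatch_rejected(self):
        cfg = ss.ScenarioConfig(n_islands=5, n_species=10, seed=0)
        phylo = ss.simulate_phylogeny(10, seed=0)
        attrs = ss.simulate_island_attributes(5, seed=0)
        bad = pd.Series(np.zeros(10), index=[f"bad{i}" for i in range(10)])
        with pytest.raises(SchemaError):
            ss.simulate_metacommunity(cfg, phylo, bad, attrs)

    @pytest.mark.parametrize(
        "process", ["filtering", "competition", "dispersal_limitation",
                    "density_dependence"]
    )
    def test_zero_strength_reduces_to_neutral_exactly(self, process):
        base = ss.ScenarioConfig(n_islands=6, n_species=15, seed=5)
        proc = ss.ScenarioConfig(
            n_islands=6, n_species=15, seed=5, process_ss=process,
            process_st=process, strength=0.0,
        )
        a = ss.simulate_dataset(base)
        b = ss.simulate_dataset(proc)
        for stage in ("seedling", "sapling", "tree"):
            assert (
                a.communities[stage].abundance == b.communities[stage].abundance
            ).all()

    def test_quadrat_subsampling_keeps_valid_communities(self):
        cfg = ss.ScenarioConfig(
            n_islands=8, n_species=20, seed=6, seedling_quadrat_subsampling=True
        )
        ds = ss.simulate_dataset(cfg)
        assert ds.communities["seedling"].abundance.sum() > 0


class TestDirectionRecovery:
    """Each assembly process, simulated strongly, shifts Z_D with the
    predicted sign (median over islands, pooled over replicate landscapes)."""

    # process, transition, strong strength, expected sign of (SD, PD) medians
    CASES = [
        ("filtering", "SS", 8.0, (-1, -1)),
        ("dispersal_limitation", "SS", 8.0, (-1, -1)),
        ("density_dependence", "ST", 1.5, (+1, +1)),
        ("competition", "ST", 8.0, (-1, +1)),
    ]

    @pytest.mark.parametrize("process,trans,strength,signs", CASES)
    def test_predicted_sign_of_median_z(self, process, trans, strength, signs):
        from stageshift.assembly_shift import transition_table

        rows = []
        for seed in (11, 13):
            kwargs = {"process_ss": process} if trans == "SS" else {
                "process_st": process
            }
            ds = ss.simulate_dataset(
                ss.ScenarioConfig(strength=strength, seed=seed, **kwargs)
            )
            res, _ = transition_table(
                ds.communities, ds.phylogeny, n_rand=199, seed=200 + seed
            )
            rows.extend(r.__dict__ for r in res)
        df = pd.DataFrame(rows).query("transition == @trans")
        med_sd = df.query("metric == 'SD'")["z"].median()
        med_pd = df.query("metric == 'PD'")["z"].median()
        assert np.sign(med_sd) == signs[0], (med_sd, med_pd)
        assert np.sign(med_pd) == signs[1], (med_sd, med_pd)
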