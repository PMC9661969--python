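import numpy as np
import pytest

from ecoassembly.nullmodels import bray_curtis
from ecoassembly.phylo import cophenetic_distances
from ecoassembly.simulate import (
    ScenarioSpec,
    assemble_communities,
    evolve_trait,
    ground_truth_labels,
    simulate_scenario,
    simulate_tree,
)


class TestSimulateTree:
    def test_tip_count(self):
        for n in (2, 5, 20):
            tree = simulate_tree(n, seed=1)
            assert len(tree.leaf_nodes()) == n

    def test_depth_scaled_to_one_and_ultrametric(self):
        tree = simulate_tree(12, seed=3)
        depths = []
        for leaf in tree.leaf_node_iter():
            d, node = 0.0, leaf
            while node.parent_node is not None:
                d += node.edge.length
                node = node.parent_node
            depths.append(d)
        assert np.allclose(depths, 1.0)

    def test_two_taxa_is_a_cherry(self):
        tree = simulate_tree(2, seed=0)
        d = cophenetic_distances(tree)
        assert d.data.max() == pytest.approx(2.0)

    def test_different_seeds_differ(self):
        t1 = simulate_tree(30, seed=1)
        t2 = simulate_tree(30, seed=2)
        d1 = cophenetic_distances(t1).filter([f"t{i+1}" for i in range(30)]).data
        d2 = cophenetic_distances(t2).filter([f"t{i+1}" for i in range(30)]).data
        assert not np.allclose(d1, d2)

    def test_same_seed_reproducible(self):
        d1 = cophenetic_distances(simulate_tree(10, seed=5)).data
        d2 = cophenetic_distances(simulate_tree(10, seed=5)).data
        assert np.allclose(d1, d2)


class TestEvolveTrait:
    def test_zero_rate_gives_zero_traits(self):
        tree = simulate_tree(8, seed=1)
        traits = evolve_trait(tree, trait_sigma=0.0, seed=0)
        assert all(v == 0.0 for v in traits.values())

    def test_brownian_cherry_variance(self):
        """Under rate-constant Brownian motion the trait difference of a
        2-tip cherry with unit-depth branches has variance 2 sigma^2."""
        tree = simulate_tree(2, seed=0)
        diffs = [
            np.subtract(*evolve_trait(tree, 1.0, seed=s, signal_decay=0.0).values())
            for s in range(400)
        ]
        assert np.var(diffs) == pytest.approx(2.0, rel=0.25)

    def test_phylogenetic_signal(self):
        """Trait distance correlates positively with cophenetic distance."""
        corrs = []
        for seed in range(5):
            tree = simulate_tree(40, seed=seed)
            traits = evolve_trait(tree, 1.0, seed=seed)
            taxa = [l.taxon.label for l in tree.leaf_node_iter()]
            d = cophenetic_distances(tree).filter(taxa).data
            tr = np.array([traits[t] for t in taxa])
            td = np.abs(tr[:, None] - tr[None, :])
            iu = np.triu_indices(len(taxa), k=1)
            corrs.append(np.corrcoef(d[iu], td[iu])[0, 1])
        assert np.mean(corrs) > 0.2


class TestAssembleCommunities:
    @pytest.mark.parametrize(
        "regime",
        [
            "variable_selection",
            "homogeneous_selection",
            "dispersal_limitation",
            "homogenizing_dispersal",
            "neutral",
        ],
    )
    def test_row_sums_exact_and_counts_integer(self, regime):
        spec = ScenarioSpec(regime=regime, n_taxa=30, n_sites=5, reads_per_site=400, seed=2)
        sc = simulate_scenario(spec)
        assert (sc.table.counts.sum(axis=1) == 400).all()
        assert sc.table.counts.dtype.kind == "i"
        assert (sc.table.counts >= 0).all()

    def test_gradient_extremes_share_few_taxa(self):
        spec = ScenarioSpec(regime="variable_selection", n_taxa=60, n_sites=8,
                            reads_per_site=1000, seed=4)
        sc = simulate_scenario(spec)
        bc = bray_curtis(sc.table.counts[0], sc.table.counts[-1])
        assert bc > 0.8

    def test_mass_effects_sites_nearly_identical(self):
        spec = ScenarioSpec(regime="homogenizing_dispersal", n_taxa=60, n_sites=6,
                            reads_per_site=2000, seed=4)
        sc = simulate_scenario(spec)
        bc = bray_curtis(sc.table.counts[0], sc.table.counts[1])
        assert bc < 0.3

    def test_zero_filter_width_rejected_for_selection(self):
        spec = ScenarioSpec(regime="variable_selection", n_taxa=20, n_sites=4, seed=1)
        spec.filter_width = None
        tree = simulate_tree(20, seed=1)
        traits = {l.taxon.label: 0.0 for l in tree.leaf_node_iter()}
        # all traits equal -> realised sd 0 -> filter width collapses
        with pytest.raises(ValueError, match="filter_width"):
            assemble_communities(spec, tree, traits)

    def test_same_seed_fully_reproducible(self):
        spec = ScenarioSpec(regime="neutral", n_taxa=25, n_sites=4, seed=9)
        a = simulate_scenario(spec).table.counts
        b = simulate_scenario(spec).table.counts
        assert (a == b).all()


class TestGroundTruthLabels:
    def test_fixed_regimes_label_every_pair(self):
        for regime, label in [
            ("homogeneous_selection", "homogeneous_selection"),
            ("dispersal_limitation", "dispersal_limitation"),
            ("homogenizing_dispersal", "homogenizing_dispersal"),
            ("neutral", "no_dominant_process"),
        ]:
            spec = ScenarioSpec(regime=regime, n_sites=4, n_taxa=10, seed=0)
            truth = ground_truth_labels(spec, np.full(4, np.nan))
            assert len(truth) == 6
            assert set(truth.values()) == {label}

    def test_two_environment_clusters(self):
        spec = ScenarioSpec(
            regime="variable_selection", n_sites=4, n_taxa=10, filter_width=0.5, seed=0
        )
        envs = np.array([0.0, 0.1, 3.0, 3.1])
        truth = ground_truth_labels(spec, envs)
        assert truth[(0, 1)] == "homogeneous_selection"
        assert truth[(2, 3)] == "homogeneous_selection"
        assert truth[(0, 2)] == "variable_selection"
        assert truth[(1, 3)] == "variable_selection"
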