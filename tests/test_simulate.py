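"""GTR+Gamma+I simulator, scenarios, and network construction."""

import numpy as np
import pytest

from softwired.io import parse_enewick, write_enewick
from softwired.matrix import FormatError
from softwired.network import StructureError, enumerate_display_trees, validate
from softwired.simulate import (
    GTR_GAMMA_I,
    Locus,
    ScenarioSpec,
    SubstitutionModel,
    add_network_edge,
    bridge_network,
    build_rate_matrix,
    discrete_gamma_rates,
    scenario_spec,
    simulate_locus,
    simulate_scenario,
    TREE_A,
    TREE_B,
)


class TestRateMatrix:
    def test_jukes_cantor_symmetry(self):
        jc = SubstitutionModel()
        q = build_rate_matrix(jc)
        off = q[~np.eye(4, dtype=bool)]
        assert np.allclose(off, off[0])

    def test_rows_sum_to_zero(self):
        q = build_rate_matrix(GTR_GAMMA_I)
        assert np.allclose(q.sum(axis=1), 0.0, atol=1e-12)

    def test_stationary_distribution_is_left_null_vector(self):
        q = build_rate_matrix(GTR_GAMMA_I)
        pi = np.array(GTR_GAMMA_I.base_freqs)
        assert np.allclose(pi @ q, 0.0, atol=1e-12)

    def test_mean_rate_normalized_to_one(self):
        q = build_rate_matrix(GTR_GAMMA_I)
        pi = np.array(GTR_GAMMA_I.base_freqs)
        assert -(pi * np.diag(q)).sum() == pytest.approx(1.0)

    def test_bad_frequencies_rejected(self):
        with pytest.raises(FormatError, match="frequencies"):
            SubstitutionModel(base_freqs=(0.5, 0.5, 0.2, 0.2))


class TestDiscreteGamma:
    def test_four_categories_mean_one_increasing(self):
        r = discrete_gamma_rates(1.0, 4)
        assert r.mean() == pytest.approx(1.0)
        assert np.all(np.diff(r) > 0)

    def test_single_category_is_rate_one(self):
        assert discrete_gamma_rates(2.0, 1).tolist() == [1.0]

    def test_large_shape_collapses_to_uniform(self):
        r = discrete_gamma_rates(500.0, 4)
        assert np.allclose(r, 1.0, atol=0.1)


class TestSimulateLocus:
    def test_deterministic_under_fixed_seed(self):
        a = simulate_locus(TREE_A, GTR_GAMMA_I, 80, 7)
        b = simulate_locus(TREE_A, GTR_GAMMA_I, 80, 7)
        assert all(a.sequence(t) == b.sequence(t) for t in a.taxa)

    def test_near_zero_branches_leave_taxa_identical(self):
        tree = "((A:1e-12,B:1e-12):1e-12,(C:1e-12,D:1e-12):1e-12);"
        m = simulate_locus(tree, GTR_GAMMA_I, 200, 3)
        seqs = {m.sequence(t) for t in m.taxa}
        assert len(seqs) == 1

    def test_missing_branch_length_rejected(self):
        with pytest.raises(FormatError, match="branch length"):
            simulate_locus("((A,B),(C,D));", GTR_GAMMA_I, 10, 0)

    def test_longer_branch_never_less_divergent(self):
        """Doubling a branch length does not decrease observed differences."""
        diffs = []
        for t in (0.1, 0.2, 0.4, 0.8):
            m = simulate_locus(f"(A:{t},B:{t});", GTR_GAMMA_I, 10000, 11)
            a, b = m.sequence("A"), m.sequence("B")
            diffs.append(sum(x != y for x, y in zip(a, b)))
        assert all(d2 >= d1 for d1, d2 in zip(diffs, diffs[1:]))


class TestScenarios:
    def test_com_concatenates_identical_histories(self):
        spec = ScenarioSpec.com(TREE_A, 2, 100, seed=5)
        m, bounds = simulate_scenario(spec, GTR_GAMMA_I)
        assert m.n_characters == 200
        assert bounds == [(0, 100), (100, 200)]

    def test_ind_requires_distinct_topologies(self):
        with pytest.raises(FormatError, match="IND"):
            ScenarioSpec("IND", (Locus(TREE_A, 50), Locus(TREE_A, 50)), 0)

    def test_sep_requires_shared_topology(self):
        with pytest.raises(FormatError, match="SEP"):
            ScenarioSpec("SEP", (Locus(TREE_A, 50), Locus(TREE_B, 50)), 0)

    def test_same_spec_same_seed_identical(self):
        spec = scenario_spec("IND", 2, 60, seed=9)
        m1, _ = simulate_scenario(spec, GTR_GAMMA_I)
        m2, _ = simulate_scenario(spec, GTR_GAMMA_I)
        assert all(m1.sequence(t) == m2.sequence(t) for t in m1.taxa)

    def test_json_roundtrip(self):
        spec = scenario_spec("COM", 2, 40, seed=3)
        import json

        text = json.dumps(
            {
                "scenario": spec.scenario,
                "seed": spec.seed,
                "loci": [{"tree": l.tree, "length": l.length} for l in spec.loci],
            }
        )
        assert ScenarioSpec.from_json(text) == spec


class TestAddNetworkEdge:
    def test_toy_reconstruction(self):
        net = add_network_edge("((A,B),(C,D));", frozenset("C"), frozenset("B"))
        assert validate(net).ok
        newicks = {t.to_newick() for t in enumerate_display_trees(net)}
        assert newicks == {"((A,B),(C,D));", "(((B,C),D),A);"}

    def test_original_tree_always_displayed(self, rng):
        from softwired.simulate import random_binary_tree

        tree = random_binary_tree(list("ABCDEF"), rng)
        base_clusters = enumerate_display_trees(tree)[0].clusters
        net = None
        for a in "ABCDEF":
            for b in "ABCDEF":
                if a == b:
                    continue
                try:
                    net = add_network_edge(tree, frozenset(a), frozenset(b))
                    break
                except StructureError:
                    continue
            if net is not None:
                break
        assert net is not None
        displayed = {t.clusters for t in enumerate_display_trees(net)}
        assert base_clusters in displayed

    def test_ancestral_source_refused_as_time_inconsistent(self):
        # source edge above {A,B} is ancestral to the target edge above {B}:
        # the hybrid's two parents would be ancestor and descendant
        with pytest.raises(StructureError, match="time"):
            add_network_edge("((A,B),(C,D));", frozenset("AB"), frozenset("B"))

    def test_upward_edge_refused_as_cycle(self):
        with pytest.raises(StructureError, match="cycle"):
            add_network_edge("((A,B),(C,D));", frozenset("A"), frozenset("AB"))

    def test_bridge_network_displays_both_study_trees(self):
        net = bridge_network()
        assert validate(net).ok
        displayed = {t.clusters for t in enumerate_display_trees(net)}
        for nwk in (TREE_A, TREE_B):
            t = parse_enewick(nwk)
            (dt,) = enumerate_display_trees(t)
            assert dt.clusters in displayed
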