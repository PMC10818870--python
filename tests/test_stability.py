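import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from micronet.io import AbundanceTable
from micronet.stability import (RobustnessParams, cohesion, compare_stability,
                                connectedness, robustness_random,
                                robustness_targeted)
from micronet.topology import detect_modules, zipi


def exhaustive_robustness(graph: nx.Graph, n_remove: int) -> float:
    """Brute-force mean robustness over every removal set (degree-zero
    cascade): survivors are nodes keeping at least one link."""
    nodes = list(graph.nodes)
    n = len(nodes)
    values = []
    for removal in itertools.combinations(nodes, n_remove):
        remnant = graph.subgraph(v for v in nodes if v not in removal)
        survivors = sum(1 for v in remnant if remnant.degree(v) > 0)
        values.append(survivors / n)
    return float(np.mean(values))


class TestRobustnessRandom:
    def test_complete_graph_has_no_cascade(self):
        res = robustness_random(
            nx.complete_graph(10),
            RobustnessParams(removal_fraction=0.5, replicates=20, seed=0))
        assert np.all(res.values == 0.5)

    def test_cascade_off_equals_one_minus_fraction(self):
        for g in (nx.path_graph(10), nx.star_graph(9),
                  nx.gnm_random_graph(20, 30, seed=0)):
            res = robustness_random(
                g, RobustnessParams(removal_fraction=0.5, replicates=10,
                                    cascade_rule="none", seed=1))
            assert np.all(res.values == 0.5)

    def test_cascade_only_removes(self):
        g = nx.gnm_random_graph(20, 25, seed=3)
        on = robustness_random(g, RobustnessParams(replicates=50, seed=5))
        off = robustness_random(g, RobustnessParams(
            replicates=50, cascade_rule="none", seed=5))
        assert np.all(on.values <= off.values + 1e-12)

    def test_path_graph_matches_enumeration_oracle(self):
        g = nx.path_graph(6)
        oracle = exhaustive_robustness(g, 3)
        res = robustness_random(
            g, RobustnessParams(removal_fraction=0.5, replicates=2000, seed=2))
        mc_se = res.sd / np.sqrt(len(res.values))
        assert abs(res.mean - oracle) < 4 * mc_se + 1e-9

    def test_deterministic_under_seed(self):
        g = nx.gnm_random_graph(15, 25, seed=4)
        a = robustness_random(g, RobustnessParams(replicates=10, seed=9))
        b = robustness_random(g, RobustnessParams(replicates=10, seed=9))
        np.testing.assert_array_equal(a.values, b.values)

    def test_empty_removal_rejected(self):
        with pytest.raises(ValueError):
            robustness_random(nx.path_graph(3),
                              RobustnessParams(removal_fraction=0.2))


class TestRobustnessTargeted:
    def _zipi_for(self, g):
        partition, _ = detect_modules(g)
        return zipi(g, partition)

    def test_cut_node_removal_spares_cliques(self):
        # two 4-cliques bridged through one cut node
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        g.add_node(8)
        g.add_edge(0, 8)
        g.add_edge(4, 8)
        table = self._zipi_for(g)
        res = robustness_targeted(
            g, table, RobustnessParams(n_hubs_removed=1))
        assert res.mean == pytest.approx(8 / 9)

    def test_star_hub_removal_cascades_everything(self):
        g = nx.star_graph(9)
        table = pd.DataFrame(
            {"module": 0, "Zi": [5.0] + [0.0] * 9, "Pi": 0.0,
             "role": ["module_hub"] + ["peripheral"] * 9},
            index=list(g.nodes))
        res = robustness_targeted(g, table,
                                  RobustnessParams(n_hubs_removed=1))
        assert res.mean == 0.0

    def test_no_cascade_when_hubs_redundant(self):
        g = nx.complete_graph(8)
        table = self._zipi_for(g)
        res = robustness_targeted(g, table, RobustnessParams(n_hubs_removed=3))
        assert res.mean == pytest.approx(5 / 8)
        assert res.fallback_used  # complete graph has no module hubs

    def test_removed_set_deterministic(self):
        g = nx.gnm_random_graph(20, 40, seed=6)
        table = self._zipi_for(g)
        r1 = robustness_targeted(g, table, RobustnessParams(n_hubs_removed=3))
        r2 = robustness_targeted(g, table, RobustnessParams(n_hubs_removed=3))
        assert r1.removed == r2.removed


def _rel_table(matrix, prefix="s"):
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    matrix = matrix / matrix.sum(axis=0)
    return AbundanceTable(pd.DataFrame(
        matrix, index=[f"t{i}" for i in range(matrix.shape[0])],
        columns=[f"{prefix}{j}" for j in range(matrix.shape[1])]),
        kind="relative")


class TestConnectedness:
    def test_perfect_pair_survives_null_correction(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(0.5, 2.0, size=30)
        x = np.vstack([base, base * 2.0] + [rng.uniform(0.5, 2, 30)
                                            for _ in range(4)])
        conn = connectedness(_rel_table(x), null_reps=100, seed=1)
        # relative-abundance closure perturbs the pair only slightly
        assert conn.corrected[0, 1] > 0.8

    def test_sign_constraints(self):
        rng = np.random.default_rng(2)
        conn = connectedness(_rel_table(rng.uniform(0.1, 1, (8, 20))),
                             null_reps=50, seed=3)
        assert (conn.c_plus >= 0).all()
        assert (conn.c_minus <= 0).all()

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            connectedness(_rel_table([[1, 1], [1, 2]]), null_reps=10, seed=0)


class TestCohesion:
    def test_constant_connectedness_gives_constant_cohesion(self):
        table = _rel_table(np.random.default_rng(4).uniform(1, 2, (5, 6)))
        conn = connectedness(table, null_reps=20, seed=5)
        conn.c_plus[:] = 0.3
        conn.c_minus[:] = -0.2
        out = cohesion(table, conn)
        np.testing.assert_allclose(out["positive"], 0.3)
        np.testing.assert_allclose(out["negative"], -0.2)

    def test_point_mass_sample_picks_single_taxon(self):
        table = _rel_table([[1, 0.5], [0, 0.5]])
        conn = connectedness(_rel_table(
            np.random.default_rng(6).uniform(1, 2, (2, 10))), null_reps=20,
            seed=7)
        conn.c_plus[:] = [0.4, 0.1]
        conn.taxon_ids = table.taxon_ids
        out = cohesion(table, conn)
        assert out.loc["s0", "positive"] == pytest.approx(0.4)

    def test_linearity_in_abundance(self):
        rng = np.random.default_rng(8)
        table = _rel_table(rng.uniform(0.1, 1, (6, 4)))
        conn = connectedness(table, null_reps=30, seed=9)
        out = cohesion(table, conn)
        a = table.data.iloc[:, 0].to_numpy()
        b = table.data.iloc[:, 1].to_numpy()
        mixed = 0.25 * a + 0.75 * b
        blended = AbundanceTable(
            pd.DataFrame({"mix": mixed}, index=table.taxon_ids),
            kind="relative")
        mixed_out = cohesion(blended, conn)
        expected = 0.25 * out.iloc[0]["positive"] + 0.75 * out.iloc[1]["positive"]
        assert mixed_out.loc["mix", "positive"] == pytest.approx(expected)

    @given(st.integers(0, 1000))
    def test_sign_contract_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        table = _rel_table(rng.uniform(0.01, 1, (5, 8)))
        conn = connectedness(table, null_reps=10, seed=seed)
        out = cohesion(table, conn)
        assert (out["positive"] >= 0).all()
        assert (out["negative"] <= 0).all()

    def test_mismatched_taxa_rejected(self):
        t1 = _rel_table(np.random.default_rng(1).uniform(1, 2, (4, 5)))
        t2 = _rel_table(np.random.default_rng(1).uniform(1, 2, (3, 5)))
        conn = connectedness(t2, null_reps=10, seed=0)
        with pytest.raises(ValueError):
            cohesion(t1, conn)


class TestCompareStability:
    def test_identical_groups(self):
        t, p = compare_stability([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert (t, p) == (0.0, 1.0)

    def test_worked_example(self):
        t, p = compare_stability([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert p == pytest.approx(0.0214, abs=1e-3)

    def test_swap_flips_sign_only(self):
        t1, p1 = compare_stability([1, 2, 3], [4, 5, 7])
        t2, p2 = compare_stability([4, 5, 7], [1, 2, 3])
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)
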