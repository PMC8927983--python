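import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest, norm
from sklearn.metrics import adjusted_rand_score
from statsmodels.stats.multitest import multipletests

from tissuenet.diffnet import (
    DifferentialNetwork,
    bh_adjust,
    build_network,
    detect_modules,
    diff_z,
    fisher_z,
    hub_scores,
    pairwise_diffcorr,
    permutation_null,
)


def random_matrix(n_genes, n_cols, seed, loc=0.0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.normal(loc, 1.0, size=(n_genes, n_cols)),
                        index=[f"g{i}" for i in range(n_genes)])


class TestFisherZ:
    def test_zero_maps_to_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_half_closed_form(self):
        assert fisher_z(0.5) == pytest.approx(0.5 * np.log(3), abs=1e-10)
        assert fisher_z(0.5) == pytest.approx(0.54931, abs=1e-5)

    def test_antisymmetry_sampled(self):
        rng = np.random.default_rng(0)
        rho = rng.uniform(-0.99, 0.99, size=1000)
        np.testing.assert_allclose(fisher_z(-rho), -fisher_z(rho), atol=1e-12)

    def test_clamping_at_unit_correlation(self, caplog):
        with caplog.at_level("WARNING"):
            z = fisher_z(1.0)
        assert np.isfinite(z)
        assert any("clamped" in rec.message for rec in caplog.records)


class TestDiffZ:
    def test_equal_z_gives_p_one(self):
        dz, p = diff_z(0.3, 30, 0.3, 50)
        assert dz == 0.0 and p == 1.0

    def test_closed_form_example(self):
        dz, p = diff_z(0.54931, 64, 0.0, 64)
        assert dz == pytest.approx(3.0337, abs=2e-4)
        assert p == pytest.approx(0.00242, abs=5e-5)

    def test_swap_negates_dz_keeps_p(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            z1, z2 = rng.normal(size=2)
            n1, n2 = rng.integers(5, 100, size=2)
            dz_a, p_a = diff_z(z1, n1, z2, n2)
            dz_b, p_b = diff_z(z2, n2, z1, n1)
            assert dz_a == pytest.approx(-dz_b, abs=1e-12)
            assert p_a == pytest.approx(p_b, abs=1e-12)

    @pytest.mark.parametrize("n1,n2,group", [(3, 64, "group 1"), (64, 2, "group 2")])
    def test_small_groups_named_in_error(self, n1, n2, group):
        with pytest.raises(ValueError, match=group):
            diff_z(0.1, n1, 0.2, n2)


class TestBhAdjust:
    def test_hand_evaluated_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.37]), [0.37])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=200))
    def test_matches_statsmodels_oracle(self, pvals):
        ours = bh_adjust(pvals)
        theirs = multipletests(pvals, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, theirs, atol=1e-12)

    def test_rank_order_preserved(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=500)
        adj = bh_adjust(p)
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-15).all()  # order-preserving in ranks
        assert (adj >= p - 1e-15).all()  # adjusted never below raw


class TestPairwiseDiffcorr:
    def test_identical_matrices_null(self):
        m = random_matrix(10, 20, seed=3)
        table = pairwise_diffcorr(m, m.copy())
        np.testing.assert_allclose(table.dz, 0.0, atol=1e-10)
        np.testing.assert_allclose(table.p, 1.0, atol=1e-10)

    def test_row_count_is_choose_two(self):
        m = random_matrix(12, 15, seed=4)
        table = pairwise_diffcorr(m, random_matrix(12, 18, seed=5))
        assert len(table) == 12 * 11 // 2
        assert table.attrs["n1"] == 15 and table.attrs["n2"] == 18

    def test_zero_variance_gene_is_error(self):
        m = random_matrix(5, 10, seed=6)
        m.iloc[2] = 7.0
        with pytest.raises(ValueError, match="zero-variance"):
            pairwise_diffcorr(m, random_matrix(5, 10, seed=7))

    def test_planted_pair_detected(self):
        rng = np.random.default_rng(8)
        t = random_matrix(20, 64, seed=9)
        t.iloc[1] = 0.9 * t.iloc[0] + 0.1 * rng.normal(size=64)
        c = random_matrix(20, 64, seed=10)
        table = pairwise_diffcorr(t, c)
        top = table.loc[table.dz.abs().idxmax()]
        assert {top.gene_a, top.gene_b} == {"g0", "g1"}


class TestPermutationNull:
    def test_fixed_seed_reproducible(self):
        t, c = random_matrix(8, 12, seed=11), random_matrix(8, 12, seed=12)
        p1 = permutation_null(t, c, n_perm=10, seed=5)
        p2 = permutation_null(t, c, n_perm=10, seed=5)
        pd.testing.assert_series_equal(p1, p2)

    def test_add_one_rule_floor(self):
        # the smallest achievable pooled empirical p is 1/(1 + n_perm * P)
        t, c = random_matrix(6, 10, seed=13), random_matrix(6, 10, seed=14)
        n_pairs = 6 * 5 // 2
        p = permutation_null(t, c, n_perm=20, seed=0)
        assert (p >= 1.0 / (1 + 20 * n_pairs) - 1e-15).all()

    def test_per_pair_mode(self):
        t, c = random_matrix(6, 10, seed=15), random_matrix(6, 10, seed=16)
        p = permutation_null(t, c, n_perm=10, seed=1, pooled=False)
        assert ((p >= 1 / 11) & (p <= 1.0)).all()

    def test_null_uniformity(self):
        # identical generative law in both groups -> empirical p ~ U(0,1)
        t = random_matrix(40, 30, seed=17)
        c = random_matrix(40, 30, seed=18)
        p = permutation_null(t, c, n_perm=60, seed=2)
        assert kstest(p, "uniform").pvalue > 0.01

    def test_invalid_n_perm(self):
        t, c = random_matrix(5, 10, seed=19), random_matrix(5, 10, seed=20)
        with pytest.raises(ValueError, match="n_perm"):
            permutation_null(t, c, n_perm=0)


class TestBuildNetworkAndHubs:
    def test_small_table_all_edges(self):
        m = random_matrix(5, 20, seed=21)
        table = pairwise_diffcorr(m, random_matrix(5, 20, seed=22))
        net = build_network(table, cap=1000)
        assert net.graph.number_of_edges() == len(table)

    def test_cap_one(self):
        m = random_matrix(6, 20, seed=23)
        table = pairwise_diffcorr(m, random_matrix(6, 20, seed=24))
        net = build_network(table, cap=1)
        assert net.graph.number_of_edges() == 1
        assert net.edges.iloc[0].p_adj == table.p_adj.min()

    def test_deterministic_under_ties(self):
        table = pd.DataFrame({
            "gene_a": ["a", "a", "b"],
            "gene_b": ["b", "c", "c"],
            "rho_tissue": [0.5, 0.5, 0.5],
            "rho_control": [0.0, 0.0, 0.0],
            "z1": [0.5, 0.5, 0.5], "z2": [0, 0, 0],
            "dz": [2.0, 2.0, -2.0], "p": [0.04, 0.04, 0.04],
            "p_adj": [0.04, 0.04, 0.04],
        })
        net = build_network(table, cap=2)
        assert net.edges[["gene_a", "gene_b"]].values.tolist() == [["a", "b"], ["a", "c"]]
        assert set(net.edges.sign) == {1, -1} or set(net.edges.sign) == {1}

    def test_hub_scores_zero_table(self):
        m = random_matrix(5, 20, seed=25)
        table = pairwise_diffcorr(m, m.copy())
        hubs = hub_scores(table)
        np.testing.assert_allclose(hubs.score, 0.0, atol=1e-10)

    def test_single_strong_gene_tops_ranking(self):
        rows = []
        genes = [f"g{i}" for i in range(10)]
        for a, b in itertools.combinations(genes, 2):
            dz = 2.0 if "g0" in (a, b) else 0.0
            rows.append({"gene_a": a, "gene_b": b, "dz": dz})
        hubs = hub_scores(pd.DataFrame(rows))
        assert hubs.iloc[0].gene_id == "g0"
        assert hubs.iloc[0].direction == "gain"


def modularity_oracle(graph):
    """Exhaustive best-modularity partition over all set partitions."""
    nodes = sorted(graph.nodes)

    def partitions(collection):
        if len(collection) == 1:
            yield [collection]
            return
        first, rest = collection[0], collection[1:]
        for smaller in partitions(rest):
            for i, subset in enumerate(smaller):
                yield smaller[:i] + [[first] + subset] + smaller[i + 1:]
            yield [[first]] + smaller

    best_q, best_parts = -np.inf, None
    for parts in partitions(nodes):
        q = nx.community.modularity(graph, [set(p) for p in parts])
        if q > best_q:
            best_q, best_parts = q, parts
    return best_q, [set(p) for p in best_parts]


class TestModules:
    def _network(self, graph):
        edges = pd.DataFrame({"gene_a": [u for u, _ in graph.edges],
                              "gene_b": [v for _, v in graph.edges]})
        return DifferentialNetwork(graph=graph, edges=edges)

    def test_two_cliques_vs_exhaustive_oracle(self):
        g = nx.Graph()
        for offset in (0, 5):
            g.add_edges_from((offset + i, offset + j)
                             for i, j in itertools.combinations(range(5), 2))
        g.add_edge(0, 5)
        modules = detect_modules(self._network(g))
        found = {}
        for node, m in modules.items():
            found.setdefault(m, set()).add(node)
        assert len(found) == 2
        _, oracle_parts = modularity_oracle(g)
        assert {frozenset(p) for p in found.values()} == \
               {frozenset(p) for p in oracle_parts}

    def test_disconnected_components_never_merge(self):
        g = nx.Graph()
        g.add_edges_from([(0, 1), (1, 2), (10, 11), (11, 12)])
        modules = detect_modules(self._network(g))
        assert modules[0] == modules[1] == modules[2]
        assert modules[10] == modules[11] == modules[12]
        assert modules[0] != modules[10]

    def test_edgeless_graph_singleton_modules(self, caplog):
        g = nx.Graph()
        g.add_nodes_from(["a", "b", "c"])
        with caplog.at_level("WARNING"):
            modules = detect_modules(self._network(g))
        assert len(set(modules.values())) == 3

    def test_planted_four_blocks_recovered(self):
        g = nx.planted_partition_graph(4, 25, p_in=0.4, p_out=0.02, seed=7)
        truth = [g.nodes[n]["block"] for n in g.nodes]
        modules = detect_modules(self._network(g))
        predicted = [modules[n] for n in g.nodes]
        assert adjusted_rand_score(truth, predicted) >= 0.8
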