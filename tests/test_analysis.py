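import numpy as np
import pytest
from scipy import stats as sps

from merlot.analysis import (
    build_correlation_network,
    cluster_network,
    de_kruskal_wallis,
    kruskal_wallis_h,
)
from merlot.score import nmi


class TestKruskalWallis:
    def test_matches_scipy_oracle_on_random_genes(self, rng):
        a = rng.normal(size=(12, 8))
        b = rng.normal(size=(9, 8)) + 0.5
        H, p = kruskal_wallis_h(a, b)
        for g in range(8):
            ref = sps.kruskal(a[:, g], b[:, g])
            assert H[g] == pytest.approx(ref.statistic)
            assert p[g] == pytest.approx(ref.pvalue)

    def test_perfect_separation_matches_rank_formula_oracle(self):
        # {1,2,3} vs {4,5,6}: compute H from the rank formula directly
        x, y = np.array([1.0, 2, 3]), np.array([4.0, 5, 6])
        n = 6
        ranks_x, ranks_y = [1, 2, 3], [4, 5, 6]
        oracle = 12 / (n * (n + 1)) * (
            3 * (np.mean(ranks_x) - (n + 1) / 2) ** 2
            + 3 * (np.mean(ranks_y) - (n + 1) / 2) ** 2
        )
        H, p = kruskal_wallis_h(x[:, None], y[:, None])
        assert H[0] == pytest.approx(oracle)
        assert p[0] == pytest.approx(sps.chi2.sf(oracle, 1))

    def test_identical_groups_give_h0_p1(self):
        x = np.array([[1.0], [2.0], [3.0]])
        H, p = kruskal_wallis_h(x, x)
        assert H[0] == pytest.approx(0.0, abs=1e-12)
        assert p[0] == pytest.approx(1.0)

    def test_constant_gene_gives_h0_p1(self):
        H, p = kruskal_wallis_h(np.full((4, 1), 2.0), np.full((5, 1), 2.0))
        assert H[0] == 0.0
        assert p[0] == 1.0

    def test_null_p_values_approximately_uniform(self):
        # i.i.d. NB genes, two random groups: fraction p < 0.05 near 0.05
        r = np.random.default_rng(77)
        counts = r.negative_binomial(5, 0.4, size=(80, 2000)).astype(float)
        groups = r.permutation(80)
        table = de_kruskal_wallis(counts, groups[:40], groups[40:])
        frac = float((table["p_value"] < 0.05).mean())
        assert 0.03 <= frac <= 0.07


class TestDETable:
    def test_e_value_is_p_times_g_and_order_matches(self, rng):
        counts = rng.poisson(5.0, size=(30, 50)).astype(float)
        counts[:15, :5] += 6.0
        table = de_kruskal_wallis(counts, np.arange(15))
        np.testing.assert_allclose(table["e_value"], table["p_value"] * 50)
        assert table["p_value"].is_monotonic_increasing
        assert len(table) == 50

    def test_against_rest_and_mean_diff_sign(self, rng):
        counts = rng.poisson(2.0, size=(20, 4)).astype(float)
        counts[:10, 0] += 10.0
        table = de_kruskal_wallis(counts, np.arange(10))
        row = table[table["gene"] == "gene_0"].iloc[0]
        assert row["mean_diff"] > 0
        assert row["p_value"] < 0.01

    def test_overlapping_groups_rejected(self, rng):
        counts = rng.poisson(2.0, size=(10, 3)).astype(float)
        with pytest.raises(ValueError, match="disjoint"):
            de_kruskal_wallis(counts, [0, 1, 2], [2, 3])


class TestCorrelationNetwork:
    def test_identical_and_negated_profiles(self):
        base = np.array([1.0, 2, 3, 4, 5])
        profiles = np.column_stack([base, base, -base])
        net = build_correlation_network(profiles, threshold=0.9)
        weights = {(a, b): w for a, b, w in net.edges}
        assert weights[(0, 1)] == pytest.approx(1.0)
        assert weights[(0, 2)] == pytest.approx(-1.0)

    def test_coregulated_module_yields_all_within_edges(self, rng):
        t = np.linspace(0, 1, 40)
        module = np.column_stack([t * s + rng.normal(0, 0.01, 40) for s in
                                  (1.0, 2.0, 0.5, 1.5, 3.0)])
        noise = rng.normal(size=(40, 4))
        profiles = np.column_stack([module, noise])
        net = build_correlation_network(profiles, threshold=0.9)
        module_edges = [e for e in net.edges if e[0] < 5 and e[1] < 5]
        assert len(module_edges) == 10  # all C(5,2) pairs
        # direct correlation oracle
        R = np.corrcoef(profiles.T)
        for a, b, w in net.edges:
            assert w == pytest.approx(R[a, b])
            assert abs(w) >= 0.9

    def test_zero_variance_genes_excluded_with_warning(self, rng):
        profiles = np.column_stack([rng.normal(size=10), np.full(10, 3.0)])
        profiles = np.column_stack([profiles, profiles[:, 0]])
        with pytest.warns(UserWarning, match="zero-variance"):
            net = build_correlation_network(profiles, threshold=0.9)
        assert net.excluded == ["gene_1"]

    def test_too_few_profiles_rejected(self):
        with pytest.raises(ValueError, match="3 profiles"):
            build_correlation_network(np.ones((2, 4)), threshold=0.5)


class TestClusterNetwork:
    @staticmethod
    def _clique_profiles(rng, sizes, n_obs=60):
        cols = []
        for s in sizes:
            latent = rng.normal(size=n_obs)
            for _ in range(s):
                cols.append(latent + rng.normal(0, 0.05, n_obs))
        return np.column_stack(cols)

    def test_two_disconnected_cliques_become_two_modules(self, rng):
        profiles = self._clique_profiles(rng, [5, 5])
        net = cluster_network(build_correlation_network(profiles, 0.9), min_size=3)
        assert len(net.modules) == 2
        assert sorted(map(len, net.modules)) == [5, 5]
        assert set(net.modules[0]) | set(net.modules[1]) == set(range(10))

    def test_modules_below_min_size_dissolved(self, rng):
        profiles = self._clique_profiles(rng, [2])
        net = cluster_network(build_correlation_network(profiles, 0.9), min_size=3)
        assert net.modules == []
        assert net.unclustered == [0, 1]

    def test_planted_partition_recovered(self, rng):
        import igraph as ig

        g = ig.Graph.SBM(
            60,
            pref_matrix=[[0.9, 0.05], [0.05, 0.9]],
            block_sizes=[30, 30],
        )
        from merlot.analysis import CorrelationNetwork

        net = CorrelationNetwork(
            genes=[f"g{i}" for i in range(60)],
            edges=[(e.source, e.target, 1.0) for e in g.es],
            threshold=0.5,
        )
        net = cluster_network(net, min_size=3)
        labels = np.zeros(60, int)
        for m, members in enumerate(net.modules):
            labels[members] = m + 1
        truth = np.repeat([0, 1], 30)
        assert nmi(truth, labels) > 0.9

    def test_empty_network(self):
        from merlot.analysis import CorrelationNetwork

        net = CorrelationNetwork(genes=["a", "b"], edges=[], threshold=0.9)
        net = cluster_network(net)
        assert net.modules == []
        assert net.unclustered == [0, 1]
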