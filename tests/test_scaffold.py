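import itertools

import networkx as nx
import numpy as np
import pytest

from merlot.scaffold import (
    ScaffoldTree,
    assign_branches,
    connect_endpoints,
    endpoint_gain,
    find_endpoints,
    shortest_path_cell_counts,
)
from merlot.score import nmi


def brute_force_paths(X):
    """Independent Floyd-Warshall oracle on squared distances, tracking
    the cell count of each shortest path."""
    n = X.shape[0]
    D = ((X[:, None, :] - X[None]) ** 2).sum(-1).astype(float)
    S = np.full((n, n), 2)
    np.fill_diagonal(S, 1)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                alt = D[i, k] + D[k, j]
                if alt < D[i, j] - 1e-15:
                    D[i, j] = alt
                    S[i, j] = S[i, k] + S[k, j] - 1
    return S, D


class TestShortestPathCellCounts:
    def test_collinear_points_route_through_middle(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        stats = shortest_path_cell_counts(X)
        assert stats.S[0, 2] == 3  # (2d)^2 > d^2 + d^2
        assert list(stats.path(0, 2)) == [0, 1, 2]

    def test_two_points(self):
        stats = shortest_path_cell_counts(np.array([[0.0, 0.0], [1.0, 1.0]]))
        np.testing.assert_array_equal(stats.S, [[1, 2], [2, 1]])

    def test_matches_brute_force_oracle_on_random_points(self, rng):
        X = rng.normal(size=(20, 2))
        stats = shortest_path_cell_counts(X)
        S_oracle, D_oracle = brute_force_paths(X)
        np.testing.assert_allclose(stats.D2, D_oracle, rtol=1e-10)
        np.testing.assert_array_equal(stats.S, S_oracle)

    def test_symmetry_and_diagonal(self, rng):
        X = rng.normal(size=(15, 3))
        stats = shortest_path_cell_counts(X)
        np.testing.assert_array_equal(stats.S, stats.S.T)
        np.testing.assert_array_equal(np.diag(stats.S), 1)
        assert np.all(stats.S[~np.eye(15, dtype=bool)] >= 2)

    def test_duplicate_points_allowed(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 0.0]])
        stats = shortest_path_cell_counts(X)
        assert np.isfinite(stats.D2).all()

    def test_nonfinite_coords_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            shortest_path_cell_counts(np.array([[0.0, np.inf], [1, 1], [2, 2]]))


class TestEndpointGain:
    def test_point_on_existing_path_gains_half(self):
        # collinear chain: candidate lies on the path between the only pair
        X = np.column_stack([np.arange(5.0), np.zeros(5)])
        stats = shortest_path_cell_counts(X)
        assert endpoint_gain(stats, [0, 4], 2) == pytest.approx(0.5)

    def test_new_arm_gain_close_to_arm_size(self, rng):
        # star: a new arm of m cells hangs off the middle of a chain
        chain = np.column_stack([np.linspace(0, 2, 41), np.zeros(41)])
        m = 12
        arm = np.column_stack([np.full(m, 1.0), np.linspace(0.05, 0.6, m)])
        X = np.vstack([chain, arm])
        stats = shortest_path_cell_counts(X)
        tip = 41 + m - 1
        gain = endpoint_gain(stats, [0, 40], tip)
        # brute-force evaluation of the gain formula
        S = stats.S
        oracle = 0.5 * min(
            S[k, tip] + S[tip, l] - S[k, l] for k, l in itertools.combinations([0, 40], 2)
        )
        assert gain == pytest.approx(oracle)
        assert gain == pytest.approx(m, abs=2)

    def test_symmetric_in_endpoint_relabeling(self, rng):
        X = rng.normal(size=(15, 2))
        stats = shortest_path_cell_counts(X)
        assert endpoint_gain(stats, [0, 5, 9], 3) == endpoint_gain(stats, [9, 0, 5], 3)

    def test_gain_essentially_nonnegative_on_tree_structured_data(self, y_cloud):
        # when the path inequality S_kn + S_nl >= S_kl + 1 holds the gain is
        # non-negative; on real path-count matrices it can be violated by at
        # most a cell or two where detouring via n sheds a path cell
        coords, _ = y_cloud
        stats = shortest_path_cell_counts(coords)
        E = [59, 119, 179]
        gains = [
            endpoint_gain(stats, E, n) for n in range(coords.n_cells) if n not in E
        ]
        gains = np.asarray(gains)
        assert np.mean(gains >= 0) > 0.95
        assert gains.min() >= -1.0

    def test_requires_two_endpoints(self, rng):
        stats = shortest_path_cell_counts(rng.normal(size=(5, 2)))
        with pytest.raises(ValueError):
            endpoint_gain(stats, [0], 2)


class TestFindEndpoints:
    def test_linear_chain_auto_finds_two_extremes(self):
        X = np.column_stack([np.linspace(0, 5, 50), np.zeros(50)])
        E, _ = find_endpoints(X, mode="auto")
        assert sorted(E) == [0, 49]

    def test_y_cloud_auto_finds_three_arm_tips(self, y_cloud):
        coords, labels = y_cloud
        E, stats = find_endpoints(coords, mode="auto")
        assert len(E) == 3
        assert sorted(labels[E]) == [0, 1, 2]
        # each endpoint near its arm tip (last sixth of the arm)
        for e in E:
            pos_in_arm = e % 60
            assert pos_in_arm > 40

    def test_fixed_mode_adds_endpoints_regardless_of_branch_size(self, y_cloud):
        coords, _ = y_cloud
        E, _ = find_endpoints(coords, mode="fixed", n_endpoints=4)
        assert len(E) == 4

    def test_fixed_mode_parameter_validation(self, y_cloud):
        coords, _ = y_cloud
        with pytest.raises(ValueError):
            find_endpoints(coords, mode="fixed", n_endpoints=None)
        with pytest.raises(ValueError, match="exceed"):
            find_endpoints(coords, mode="fixed", n_endpoints=10**6)


class TestConnectEndpoints:
    def test_two_endpoints_single_branch(self, rng):
        X = rng.normal(size=(10, 2))
        stats = shortest_path_cell_counts(X)
        nj = connect_endpoints(stats, [0, 9])
        assert nj.roles == ["endpoint", "endpoint"]
        assert nj.edges == [(0, 1)]

    def test_three_endpoints_one_branchpoint_three_branches(self, y_cloud):
        # single-bifurcation topology: endpoints A, C, D join through one
        # branchpoint B into branches AB, BC, BD
        coords, _ = y_cloud
        E, stats = find_endpoints(coords, mode="auto")
        nj = connect_endpoints(stats, E)
        assert nj.roles.count("branchpoint") == 1
        assert len(nj.edges) == 3
        bp = nj.roles.index("branchpoint")
        assert all(bp in e for e in nj.edges)

    def test_h_cloud_two_branchpoints_five_branches(self, h_cloud):
        E, stats = find_endpoints(h_cloud, mode="fixed", n_endpoints=4)
        nj = connect_endpoints(stats, E)
        assert nj.roles.count("branchpoint") == 2
        assert len(nj.edges) == 5

    def test_nj_pair_choice_matches_exhaustive_oracle(self, h_cloud):
        E, stats = find_endpoints(h_cloud, mode="fixed", n_endpoints=4)
        S = stats.S.astype(float)
        V = list(E)
        # exhaustive evaluation of the NJ criterion over all pairs
        best, best_pair = np.inf, None
        for k, l in itertools.combinations(V, 2):
            d = S[k, l] - sum(S[m, k] + S[m, l] for m in V) / (len(V) - 2)
            if d < best:
                best, best_pair = d, (min(k, l), max(k, l))
        # the branchpoint joining that pair per the exhaustive criterion
        rest = [v for v in V if v not in best_pair]
        k, l = best_pair
        crit = S[k] + S[l] + S[rest].sum(axis=0) / (len(V) - 2)
        crit[[k, l]] = np.inf
        m_oracle = int(np.argmin(crit))
        nj = connect_endpoints(stats, E)
        cells = np.asarray(nj.nodes)
        edge_cells = {tuple(sorted((cells[a], cells[b]))) for a, b in nj.edges}
        assert tuple(sorted((k, m_oracle))) in edge_cells
        assert tuple(sorted((l, m_oracle))) in edge_cells

    def test_tree_invariants_on_random_endpoint_sets(self, rng):
        X = rng.normal(size=(40, 3))
        stats = shortest_path_cell_counts(X)
        for n_e in (2, 3, 4, 5):
            E = list(rng.choice(40, size=n_e, replace=False))
            nj = connect_endpoints(stats, E)
            g = nx.Graph()
            g.add_nodes_from(range(len(nj.nodes)))
            g.add_edges_from(nj.edges)
            assert nx.is_tree(g)
            assert nj.roles.count("branchpoint") <= n_e - 2
            if n_e == 3:
                assert nj.roles.count("branchpoint") == 1


class TestAssignBranches:
    def test_cell_on_branch_path_gets_that_branch(self, y_cloud):
        coords, _ = y_cloud
        tree = ScaffoldTree().fit(coords)
        for b, path in enumerate(tree.branch_paths_):
            interior = [c for c in path if all(c not in p for p2, p in
                        enumerate(tree.branch_paths_) if p2 != b)]
            for c in interior[:3]:
                assert tree.labels_[c] == b

    def test_single_branch_single_label(self):
        X = np.column_stack([np.linspace(0, 3, 30), np.zeros(30)])
        tree = ScaffoldTree().fit(X)
        assert len(set(tree.labels_)) == 1

    def test_y_cloud_labels_recover_arms(self, y_cloud):
        coords, labels = y_cloud
        tree = ScaffoldTree().fit(coords)
        assert nmi(labels, tree.labels_) > 0.9


def test_scaffold_tree_invariants(y_cloud, h_cloud):
    for coords in (y_cloud[0], h_cloud):
        tree = ScaffoldTree().fit(coords)
        assert len(tree.edges_nodeidx_) == len(tree.nodes_) - 1
        g = nx.Graph()
        g.add_nodes_from(range(len(tree.nodes_)))
        g.add_edges_from(tree.edges_nodeidx_)
        assert nx.is_tree(g)
        for node, role in zip(range(len(tree.nodes_)), tree.node_roles_):
            if role == "endpoint":
                assert g.degree[node] == 1
            else:
                assert g.degree[node] >= 3
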