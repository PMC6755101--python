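import numpy as np
import pytest
from scipy.stats import spearmanr

from merlot.elastic import ElasticPrincipalTree
from merlot.embed import GeneSpaceEmbedding, embed_in_expression_space, init_pseudocells
from merlot.io import ExpressionMatrix
from merlot.pseudotime import assign_pseudotime, gene_profile, longest_trajectory
from merlot.scaffold import ScaffoldTree


def chain_tree(k, n_cells, rng, length=4.0):
    """Straight 1-D manifold with a fitted k-node chain tree."""
    X = np.column_stack([np.linspace(0, length, n_cells), np.zeros(n_cells)])
    X = X + rng.normal(0, 0.01, X.shape)
    scaffold = ScaffoldTree().fit(X)
    return X, ElasticPrincipalTree(n_nodes=k).fit(X, scaffold=scaffold)


class TestInitPseudocells:
    def test_single_cell_node_gets_that_profile(self, rng):
        X, tree = chain_tree(5, 40, rng)
        expr = rng.poisson(5.0, size=(40, 7)).astype(float)
        profiles = init_pseudocells(expr, tree)
        for j in range(5):
            members = np.flatnonzero(tree.cell2node_ == j)
            if len(members) == 1:
                np.testing.assert_allclose(profiles[j], expr[members[0]])

    def test_empty_node_gets_null_vector(self, rng):
        X, tree = chain_tree(5, 40, rng)
        tree.cell2node_ = np.zeros(40, dtype=int)  # leave nodes 1..4 empty
        profiles = init_pseudocells(rng.poisson(5.0, (40, 3)).astype(float), tree)
        assert np.all(profiles[1:] == 0)

    def test_mean_of_assigned_cells(self, rng):
        X, tree = chain_tree(3, 30, rng)
        expr = np.zeros((30, 1))
        members = np.flatnonzero(tree.cell2node_ == 1)[:2]
        tree.cell2node_ = np.full(30, 0)
        tree.cell2node_[members] = 1
        expr[members] = [[2.0], [4.0]]
        profiles = init_pseudocells(expr, tree)
        assert profiles[1, 0] == pytest.approx(3.0)

    def test_misaligned_inputs_rejected(self, rng):
        X, tree = chain_tree(4, 30, rng)
        with pytest.raises(ValueError, match="match"):
            init_pseudocells(np.ones((10, 3)), tree)


class TestGeneSpaceEmbedding:
    def test_linear_ramp_profile_is_monotone_along_chain(self, rng):
        n = 150
        X, tree = chain_tree(12, n, rng)
        t = X[:, 0] / X[:, 0].max()
        # smooth linear ramp plus mild noise
        expr = np.column_stack([10 * t, 5 * (1 - t), np.full(n, 3.0)])
        expr = np.clip(expr + rng.normal(0, 0.3, expr.shape), 0, None)
        emb = embed_in_expression_space(expr, tree)
        times = assign_pseudotime(emb, t0=int(tree.endpoint_nodes_[0]))
        path = longest_trajectory(emb)
        tt, ramp = gene_profile(emb, times, 0, path)
        rho = spearmanr(tt, ramp).statistic
        assert abs(rho) > 0.95  # monotone along the chain up to direction

    def test_constant_data_is_a_fixed_point(self, rng):
        X, tree = chain_tree(6, 40, rng)
        expr = np.full((40, 5), 7.0)
        emb = GeneSpaceEmbedding().fit(expr, tree=tree)
        np.testing.assert_allclose(emb.pseudocell_profiles_, 7.0, atol=1e-8)
        assert len(emb.energy_history_) <= 2

    def test_all_zero_matrix_warns_and_returns_zero_profiles(self, rng):
        X, tree = chain_tree(5, 30, rng)
        with pytest.warns(UserWarning, match="zero"):
            emb = GeneSpaceEmbedding().fit(np.zeros((30, 4)), tree=tree)
        assert np.all(emb.pseudocell_profiles_ == 0)

    def test_topology_copied_and_energy_monotone(self, y_cloud, rng):
        coords, _ = y_cloud
        tree = ElasticPrincipalTree(n_nodes=40).fit(coords)
        expr = rng.poisson(4.0, size=(coords.n_cells, 20)).astype(float)
        emb = GeneSpaceEmbedding().fit(expr, tree=tree)
        assert emb.edges_ == tree.edges_
        assert emb.node_roles_ == tree.node_roles_
        assert np.all(np.diff(emb.energy_history_) <= 1e-9)

    def test_zero_penalty_limit_equals_final_node_means(self, y_cloud, rng):
        coords, _ = y_cloud
        tree = ElasticPrincipalTree(n_nodes=25).fit(coords)
        expr = rng.poisson(6.0, size=(coords.n_cells, 10)).astype(float)
        emb = GeneSpaceEmbedding(mu=1e-12, lam=1e-12).fit(expr, tree=tree)
        for j in range(25):
            members = expr[emb.cell2node_ == j]
            if len(members):
                np.testing.assert_allclose(
                    emb.pseudocell_profiles_[j], members.mean(axis=0), atol=1e-6
                )


def test_imputation_reduces_noise_against_true_curve(rng):
    """Imputed profiles track a noisy ramp's true mean curve better than the
    raw per-node means, and have lower variance, over repeated simulations."""
    from merlot.simulate import draw_counts

    wins_rmse, wins_var = 0, 0
    n_seeds = 20
    k = 40  # sparse nodes (~3 cells each), where pooling across the tree pays
    for s in range(n_seeds):
        r = np.random.default_rng(1000 + s)
        n = 120
        X = np.column_stack([np.linspace(0, 4, n), np.zeros(n)])
        X = X + r.normal(0, 0.02, X.shape)
        scaffold = ScaffoldTree().fit(X)
        tree = ElasticPrincipalTree(n_nodes=k).fit(X, scaffold=scaffold)
        t = X[:, 0] / 4
        # a few dozen genes ramping up or down at random slopes, so that
        # expression-space distances carry the pseudotime signal
        slopes = r.uniform(-15, 15, size=30)
        true_mean = np.clip(10 + slopes[None, :] * (t[:, None] - 0.5), 0.5, None)
        counts = r.negative_binomial(3, 3 / (3 + true_mean)).astype(float)
        raw = init_pseudocells(counts, tree)
        emb = GeneSpaceEmbedding().fit(counts, tree=tree)
        node_truth = init_pseudocells(true_mean, tree)
        occupied = np.bincount(tree.cell2node_, minlength=k) > 0
        rmse_raw = np.sqrt(np.mean((raw[occupied] - node_truth[occupied]) ** 2))
        rmse_imp = np.sqrt(
            np.mean((emb.pseudocell_profiles_[occupied] - node_truth[occupied]) ** 2)
        )
        wins_rmse += rmse_imp < rmse_raw
        wins_var += emb.pseudocell_profiles_[occupied].var(axis=0).sum() <= \
            raw[occupied].var(axis=0).sum()
    assert wins_rmse >= 15
    assert wins_var >= 15
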