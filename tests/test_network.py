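import numpy as np
import pytest

from bridgenet import ebic_score, estimate_network, glasso_solve, lambda_path
from bridgenet.network import GlassoConvergenceError, precision_to_partial_corr

from conftest import corr_obj, random_corr


def kkt_residual(Theta: np.ndarray, S: np.ndarray, penalty: float) -> float:
    """Worst stationarity violation of the penalized likelihood optimum."""
    W = np.linalg.inv(Theta)
    p = S.shape[0]
    res = 0.0
    for i in range(p):
        for j in range(p):
            if i == j:
                res = max(res, abs(W[i, j] - S[i, j]))
            elif Theta[i, j] == 0:
                res = max(res, max(0.0, abs(W[i, j] - S[i, j]) - penalty))
            else:
                res = max(res, abs(W[i, j] - S[i, j] - penalty * np.sign(Theta[i, j])))
    return res


class TestGlassoSolve:
    def test_identity_input_gives_identity_precision(self):
        for penalty in (0.0, 0.1, 0.5):
            Theta = glasso_solve(np.eye(5), penalty)
            np.testing.assert_allclose(Theta, np.eye(5), atol=1e-10)

    def test_penalty_above_lambda_max_empties_network(self, rng):
        S = random_corr(8, rng)
        lam_max = np.abs(S[~np.eye(8, dtype=bool)]).max()
        Theta = glasso_solve(S, lam_max * 1.0001)
        off = Theta[~np.eye(8, dtype=bool)]
        assert np.all(off == 0)

    def test_zero_penalty_matches_three_variable_closed_form(self):
        # partial correlation r_AB|C = (r_AB − r_AC r_BC)/√((1−r_AC²)(1−r_BC²))
        r_ab, r_ac, r_bc = 0.5, 0.4, 0.3
        S = np.array([[1, r_ab, r_ac], [r_ab, 1, r_bc], [r_ac, r_bc, 1.0]])
        Theta = glasso_solve(S, 0.0)
        W = precision_to_partial_corr(Theta)
        expected = (r_ab - r_ac * r_bc) / np.sqrt((1 - r_ac**2) * (1 - r_bc**2))
        assert W[0, 1] == pytest.approx(expected, abs=1e-6)

    def test_kkt_conditions_on_random_problems(self, rng):
        for p in (5, 10, 15):
            S = random_corr(p, rng)
            for penalty in (0.05, 0.2, 0.5):
                Theta = glasso_solve(S, penalty)
                assert kkt_residual(Theta, S, penalty) <= 1e-4
                assert np.linalg.eigvalsh(Theta).min() > 0

    def test_agrees_with_independent_solver(self, rng):
        sklearn = pytest.importorskip("sklearn.covariance")
        S = random_corr(10, rng, n=500)
        for penalty in (0.05, 0.15):
            Theta = glasso_solve(S, penalty)
            _, prec = sklearn.graphical_lasso(S, alpha=penalty, tol=1e-8, max_iter=2000)
            np.testing.assert_allclose(Theta, prec, atol=5e-4)

    def test_zero_penalty_requires_positive_definite_input(self):
        S = np.ones((3, 3))
        with pytest.raises(ValueError, match="positive definite"):
            glasso_solve(S, 0.0)

    def test_nonconvergence_raises_with_diagnostics(self, rng):
        S = random_corr(12, rng)
        with pytest.raises(GlassoConvergenceError):
            glasso_solve(S, 0.01, max_iter=1)


class TestLambdaPath:
    def test_two_point_path(self):
        S = np.eye(3)
        S[0, 1] = S[1, 0] = 0.8
        np.testing.assert_allclose(lambda_path(S, 2, 0.5), [0.8, 0.4])

    def test_strictly_decreasing(self, rng):
        path = lambda_path(random_corr(7, rng), 25, 0.01)
        assert np.all(np.diff(path) < 0)

    def test_first_point_yields_empty_network(self, rng):
        S = random_corr(6, rng)
        path = lambda_path(S, 10, 0.1)
        Theta = glasso_solve(S, path[0])
        assert np.count_nonzero(Theta[~np.eye(6, dtype=bool)]) == 0

    def test_all_zero_offdiagonal_warns(self):
        with pytest.warns(UserWarning):
            path = lambda_path(np.eye(4), 10, 0.1)
        np.testing.assert_array_equal(path, [0.0])


class TestEbicScore:
    def test_hand_computed_value(self):
        Theta = np.array([[1.2, -0.3, 0.0], [-0.3, 1.1, 0.0], [0.0, 0.0, 0.9]])
        S = np.array([[1.0, 0.4, 0.1], [0.4, 1.0, 0.2], [0.1, 0.2, 1.0]])
        n, gamma = 100, 0.25
        # independent arithmetic: log det via cofactor expansion
        det = 0.9 * (1.2 * 1.1 - 0.09)
        trace_STheta = (
            1.2 + 1.1 + 0.9 + 2 * (0.4 * -0.3)
        )
        E = 1
        expected = -n * (np.log(det) - trace_STheta) + E * np.log(n) + 4 * E * gamma * np.log(3)
        assert ebic_score(Theta, S, n, gamma) == pytest.approx(expected, abs=1e-10)

    def test_edge_count_penalty_monotone(self):
        # equal likelihood term, different sparsity ⇒ sparser scores lower
        Theta_sparse = np.eye(4)
        Theta_dense = np.eye(4)
        S = np.eye(4)
        Theta_dense[0, 1] = Theta_dense[1, 0] = 1e-9
        d = Theta_dense.copy()
        base_sparse = ebic_score(Theta_sparse, S, 100, 0.25)
        base_dense = ebic_score(d, S, 100, 0.25)
        assert base_sparse < base_dense

    def test_gamma_zero_reduces_to_bic(self, rng):
        S = random_corr(5, rng)
        Theta = glasso_solve(S, 0.2)
        E = np.count_nonzero(Theta[np.triu_indices(5, 1)])
        bic = ebic_score(Theta, S, 80, 0.0)
        full = ebic_score(Theta, S, 80, 0.3)
        assert full - bic == pytest.approx(4 * E * 0.3 * np.log(5), abs=1e-10)

    def test_non_positive_definite_rejected(self):
        Theta = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError):
            ebic_score(Theta, np.eye(2), 50, 0.25)


class TestEstimateNetwork:
    def test_identity_correlations_give_empty_network(self):
        cm = corr_obj(np.eye(6), n=100)
        model = estimate_network(cm, n=100, n_points=5)
        assert model.edge_count == 0
        assert model.selected_lambda == 0.0  # degenerate single-point path

    def test_weight_and_precision_sign_relation(self, rng):
        cm = corr_obj(random_corr(10, rng, n=300), n=300)
        model = estimate_network(cm, n=300, n_points=15, min_ratio=0.05)
        iu = np.triu_indices(10, 1)
        assert np.all(np.sign(model.W[iu]) == np.sign(-model.Theta[iu]))
        assert np.all(np.abs(model.W) < 1)
        assert np.all(np.diag(model.W) == 0)
        # sparsity patterns of W and Theta agree off-diagonal
        assert np.array_equal(model.W[iu] != 0, model.Theta[iu] != 0)

    def test_increasing_gamma_never_adds_edges(self, small_dataset):
        from bridgenet import correlation_matrix

        _, m, _ = small_dataset
        S = correlation_matrix(m)
        counts = [
            estimate_network(S, n=m.n, gamma=g, n_points=20, min_ratio=0.05).edge_count
            for g in (0.0, 0.25, 0.5)
        ]
        assert counts[0] >= counts[1] >= counts[2]

    def test_recovery_improves_with_sample_size(self):
        from bridgenet import correlation_matrix, recovery_metrics
        from bridgenet.synthetic import SyntheticSpec, generate_dataset

        sens = {}
        for n in (100, 2000):
            vals = []
            for seed in range(3):
                spec = SyntheticSpec(
                    p_community_a=8, p_community_b=8, n=n, seed=seed,
                    n_redundant_pairs=0, missing_rate=0.0, n_reverse_coded=0,
                )
                m, gt = generate_dataset(spec)
                model = estimate_network(
                    correlation_matrix(m), n=n, n_points=20, min_ratio=0.05,
                    communities=m.communities,
                )
                vals.append(recovery_metrics(model, gt)["sensitivity"])
            sens[n] = np.mean(vals)
        assert sens[2000] >= sens[100]

    def test_fixed_lambda_mode(self, rng):
        cm = corr_obj(random_corr(8, rng), n=200)
        model = estimate_network(cm, n=200, fixed_lambda=0.3)
        assert model.selected_lambda == 0.3
        assert len(model.lambda_path) == 1

    def test_graphml_export_roundtrip(self, tmp_path, rng):
        import networkx as nx

        cm = corr_obj(random_corr(6, rng, n=400), n=400)
        model = estimate_network(cm, n=400, n_points=10, min_ratio=0.1,
                                 communities=["A"] * 3 + ["B"] * 3)
        path = tmp_path / "net.graphml"
        model.write_graphml(path)
        G = nx.read_graphml(path)
        assert set(G.nodes) == set(model.items)
        assert G.number_of_edges() == model.edge_count
        for _, _, d in G.edges(data=True):
            assert d["sign"] in (-1, 1)
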