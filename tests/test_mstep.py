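import numpy as np
import pytest
from scipy.optimize import minimize

from tmixnet import estep, mstep
from tmixnet.mstep import AdaptiveWeights, DegenerateComponentError
from tmixnet.simulate import sample_mvt


class TestUpdatePi:
    def test_hard_assignment(self):
        tau = np.zeros((10, 2))
        tau[:, 0] = 1.0
        with pytest.raises(DegenerateComponentError):
            mstep.update_pi(tau)

    def test_uniform(self):
        tau = np.full((12, 4), 0.25)
        np.testing.assert_allclose(mstep.update_pi(tau), 0.25)

    def test_column_means(self, rng):
        tau = rng.dirichlet(np.ones(3), size=50)
        np.testing.assert_allclose(mstep.update_pi(tau), tau.mean(axis=0), atol=1e-12)


class TestUpdateNu:
    def test_recovers_generating_dof(self):
        nu0, p, n = 10.0, 5, 10_000
        X = sample_mvt(n, np.zeros(p), np.eye(p), nu0, seed=2)
        _, delta = estep.component_pass(X, np.zeros(p), np.eye(p), nu0)
        uhat, loguhat = estep.gamma_scale_moments(delta[:, None], [nu0], p)
        est = mstep.update_nu(np.ones(n), uhat[:, 0], loguhat[:, 0], nu0, p)
        assert abs(est - nu0) / nu0 < 0.15

    def test_gaussian_consistent_moments_hit_upper_bound(self):
        n = 100
        est = mstep.update_nu(np.ones(n), np.ones(n), np.zeros(n), 200.0, 5,
                              bounds=(2.001, 200.0))
        assert est == 200.0

    def test_always_within_bounds(self, rng):
        n = 50
        uh = rng.uniform(0.2, 3.0, n)
        lu = np.log(uh) - rng.uniform(0.0, 1.0, n)
        est = mstep.update_nu(np.ones(n), uh, lu, 10.0, 3, bounds=(3.0, 30.0))
        assert 3.0 <= est <= 30.0

    def test_low_bound_must_exceed_two(self):
        with pytest.raises(ValueError):
            mstep.update_nu(np.ones(3), np.ones(3), np.zeros(3), 5.0, 2, bounds=(2.0, 50.0))


class TestAdaptiveWeights:
    def test_zero_estimate_default_epsilon(self):
        w = mstep.adaptive_weights(np.zeros((1, 2)), np.zeros((1, 2, 2)), 0.1)
        np.testing.assert_allclose(w.w_mu, 10.0)
        np.testing.assert_allclose(w.w_omega, 10.0)

    def test_point_nine_estimate(self):
        w = mstep.adaptive_weights(np.full((1, 1), 0.9), np.ones((1, 1, 1)), 0.1)
        assert w.w_mu[0, 0] == pytest.approx(1.0)

    def test_strictly_decreasing_in_magnitude(self, rng):
        vals = np.sort(rng.uniform(0.0, 3.0, 20))
        w = mstep.adaptive_weights(vals[None, :], np.ones((1, 20, 20)), 0.1)
        assert np.all(np.diff(w.w_mu[0]) < 0)

    def test_nonpositive_epsilon_rejected(self):
        with pytest.raises(ValueError):
            mstep.adaptive_weights(np.zeros((1, 1)), np.zeros((1, 1, 1)), 0.0)


def _penalized_mean_objective(mu, X, tu, omega, pen):
    Xc = X - mu
    quad = -0.5 * np.einsum("i,ij,jk,ik->", tu, Xc, omega, Xc)
    return quad - np.sum(pen * np.abs(mu))


class TestUpdateMu:
    def test_unpenalized_diagonal_weighted_mean(self, rng):
        X = rng.normal(size=(30, 4))
        tau = rng.uniform(0.2, 1.0, 30)
        uh = rng.uniform(0.5, 2.0, 30)
        omega = np.diag(rng.uniform(0.5, 2.0, 4))
        mu = mstep.update_mu(X, tau, uh, omega, np.ones(4), 0.0, np.zeros(4))
        tu = tau * uh
        np.testing.assert_allclose(mu, tu @ X / tu.sum(), atol=1e-8)

    def test_infinite_penalty_gives_zero(self, rng):
        X = rng.normal(size=(20, 3)) + 5.0
        mu = mstep.update_mu(X, np.ones(20), np.ones(20), np.eye(3),
                             np.ones(3), 1e9, np.full(3, 5.0))
        np.testing.assert_allclose(mu, 0.0)

    def test_matches_numeric_maximizer_p3(self, rng, random_pd):
        X = rng.normal(size=(25, 3)) + np.array([1.0, -0.5, 0.0])
        tau = rng.uniform(0.3, 1.0, 25)
        uh = rng.uniform(0.5, 1.5, 25)
        omega = np.linalg.inv(random_pd(3, seed=4))
        w = np.array([1.0, 2.0, 4.0])
        lam = 3.0
        mu = mstep.update_mu(X, tau, uh, omega, w, lam, np.zeros(3), tol=1e-10)
        tu = tau * uh
        pen = lam * w
        ours = _penalized_mean_objective(mu, X, tu, omega, pen)
        best = ours
        for s in range(8):
            x0 = mu + np.random.default_rng(s).normal(scale=0.3, size=3)
            res = minimize(lambda m: -_penalized_mean_objective(m, X, tu, omega, pen),
                           x0, method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
            best = max(best, -res.fun)
        assert ours >= best - 1e-5

    def test_subgradient_optimality(self, rng, random_pd):
        X = rng.normal(size=(40, 5))
        tau = rng.uniform(0.1, 1.0, 40)
        uh = rng.uniform(0.4, 2.5, 40)
        omega = np.linalg.inv(random_pd(5, seed=14))
        w = rng.uniform(0.5, 3.0, 5)
        lam = 2.0
        mu = mstep.update_mu(X, tau, uh, omega, w, lam, np.zeros(5), tol=1e-10)
        tu = tau * uh
        grad = omega @ (tu @ X - tu.sum() * mu)  # gradient of the smooth part
        for j in range(5):
            if mu[j] == 0:
                assert abs(grad[j]) <= lam * w[j] + 1e-6
            else:
                assert grad[j] - np.sign(mu[j]) * lam * w[j] == pytest.approx(0.0, abs=1e-6)


class TestWeightedScatter:
    def test_gaussian_reduction(self, rng):
        X = rng.normal(size=(50, 3))
        mu = X.mean(axis=0)
        S = mstep.weighted_scatter(X, np.ones(50), np.ones(50), mu)
        np.testing.assert_allclose(S, np.cov(X.T, bias=True), atol=1e-10)

    def test_single_sample_at_location_zero(self):
        X = np.array([[2.0, -1.0]])
        S = mstep.weighted_scatter(X, np.ones(1), np.ones(1), np.array([2.0, -1.0]))
        np.testing.assert_allclose(S, 0.0)

    def test_hand_case_n4_p2(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0], [0.0, -1.0]])
        tau = np.array([1.0, 0.5, 1.0, 0.5])
        uh = np.array([2.0, 1.0, 2.0, 1.0])
        mu = np.zeros(2)
        expected = sum(
            t * u * np.outer(x - mu, x - mu) for t, u, x in zip(tau, uh, X)
        ) / tau.sum()
        S = mstep.weighted_scatter(X, tau, uh, mu)
        np.testing.assert_allclose(S, expected, atol=1e-12)


class TestUpdatePrecision:
    def test_unpenalized_inverse(self, random_pd):
        S = random_pd(4, seed=6)
        omega = mstep.update_precision(S, np.ones((4, 4)), 0.0, 50.0)
        np.testing.assert_allclose(omega, np.linalg.inv(S), atol=1e-6)

    def test_huge_penalty_diagonal(self, random_pd):
        S = random_pd(4, seed=7)
        omega = mstep.update_precision(S, np.ones((4, 4)), 1e6, 10.0)
        np.testing.assert_allclose(omega, np.diag(1.0 / np.diag(S)), atol=1e-10)

    def test_diagonal_family(self, random_pd):
        S = random_pd(5, seed=8)
        omega = mstep.update_precision(S, np.ones((5, 5)), 2.0, 10.0, family="pmt-dc")
        np.testing.assert_allclose(omega, np.diag(1.0 / np.diag(S)))

    def test_matches_reference_solver(self, rng, random_pd):
        from tmixnet import wglasso
        S = random_pd(4, seed=10, strength=0.5)
        w = rng.uniform(0.5, 2.0, (4, 4))
        w = 0.5 * (w + w.T)
        lam2, n_eff = 3.0, 25.0
        omega = mstep.update_precision(S, w, lam2, n_eff, tol=1e-7)
        P = (lam2 / n_eff) * w
        np.fill_diagonal(P, 0.0)
        ref = wglasso.reference_solve(S, P, gap_tol=1e-7)
        assert np.abs(omega - ref).max() < 1e-4
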