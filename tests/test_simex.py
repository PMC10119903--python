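import numpy as np
import pytest

from simexsel import (
    ObservedSample,
    SimexGrid,
    extrapolate_trajectory,
    fit_extrapolant,
    fit_treatment_model,
    generate_pseudo_data,
    pseudo_errors,
    run_simex,
)

PSI5 = (0.0, 0.5, 1.0, 1.5, 2.0)


def _sample(rng, n=120, px=2, pz=1):
    X = rng.standard_normal((n, px))
    Z = rng.standard_normal((n, pz))
    eta = 0.2 + 0.9 * X[:, 0]
    T = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    return ObservedSample(T=T, Y=np.zeros(n), Xstar=X, Z=Z)


class TestGrid:
    def test_validation(self):
        with pytest.raises(ValueError, match="start at 0"):
            SimexGrid(sigma_e=np.eye(1), psi=(0.5, 1.0))
        with pytest.raises(ValueError, match="increasing"):
            SimexGrid(sigma_e=np.eye(1), psi=(0.0, 1.0, 1.0))
        with pytest.raises(ValueError, match="positive"):
            SimexGrid(sigma_e=np.eye(1), K=0)
        with pytest.raises(ValueError, match="semi-definite"):
            SimexGrid(sigma_e=np.array([[1.0, 2.0], [2.0, 1.0]]))
        with pytest.raises(ValueError, match="symmetric"):
            SimexGrid(sigma_e=np.array([[1.0, 0.5], [0.1, 1.0]]))

    def test_pseudo_errors_deterministic_in_seed(self):
        g = SimexGrid(sigma_e=0.3 * np.eye(2), K=4, seed=9)
        E1 = pseudo_errors(g, 50)
        E2 = pseudo_errors(g, 50)
        assert np.array_equal(E1, E2)
        g2 = SimexGrid(sigma_e=0.3 * np.eye(2), K=4, seed=10)
        assert not np.array_equal(E1, pseudo_errors(g2, 50))


class TestPseudoData:
    def test_psi_zero_returns_xstar(self, rng):
        s = _sample(rng)
        g = SimexGrid(sigma_e=0.5 * np.eye(2), psi=PSI5, K=3, seed=1)
        assert np.array_equal(generate_pseudo_data(s, g, 0, 0.0), s.Xstar)

    def test_zero_sigma_returns_xstar_all_psi(self, rng):
        s = _sample(rng)
        g = SimexGrid(sigma_e=np.zeros((2, 2)), psi=PSI5, K=3, seed=1)
        for psi in PSI5:
            assert np.array_equal(generate_pseudo_data(s, g, 1, psi), s.Xstar)

    def test_invalid_k_and_psi(self, rng):
        s = _sample(rng)
        g = SimexGrid(sigma_e=np.eye(2), psi=PSI5, K=3, seed=1)
        with pytest.raises(ValueError, match="replicate index"):
            generate_pseudo_data(s, g, 3, 0.5)
        with pytest.raises(ValueError, match="not on the grid"):
            generate_pseudo_data(s, g, 0, 0.3)

    def test_added_noise_has_covariance_psi_sigma(self, rng):
        """Monte-Carlo oracle: cov(X*(k,psi) - X*) = psi * Sigma_e."""
        sigma = np.array([[0.4, 0.1], [0.1, 0.2]])
        psi = 1.5
        g = SimexGrid(sigma_e=sigma, psi=(0.0, psi), K=2000, seed=7)
        s = _sample(np.random.default_rng(3), n=5)
        E = pseudo_errors(g, s.n)
        devs = np.concatenate(
            [generate_pseudo_data(s, g, k, psi, errors=E) - s.Xstar for k in range(g.K)]
        )
        emp = np.cov(devs, rowvar=False)
        assert np.allclose(emp, psi * sigma, atol=0.03)


class TestRunSimex:
    def test_zero_sigma_collapses_to_naive(self, rng):
        s = _sample(rng)
        g = SimexGrid(sigma_e=np.zeros((2, 2)), psi=PSI5, K=5, seed=2)
        traj = run_simex(s, "logistic", g)
        naive = fit_treatment_model("logistic", s)
        assert np.allclose(traj.gamma, naive[None, :], atol=1e-12)

    def test_single_point_grid_equals_naive(self, rng):
        s = _sample(rng)
        g = SimexGrid(sigma_e=0.3 * np.eye(2), psi=(0.0,), K=1, seed=2)
        traj = run_simex(s, "logistic", g)
        assert np.allclose(traj.gamma[0], fit_treatment_model("logistic", s), atol=1e-10)

    def test_attenuation_monotone_in_psi(self):
        """Added noise attenuates the slope of an error-prone covariate."""
        rng = np.random.default_rng(42)
        n = 4000
        X = rng.standard_normal((n, 1))
        T = (rng.random(n) < 1 / (1 + np.exp(-(0.3 + 1.2 * X[:, 0])))).astype(float)
        s = ObservedSample(T=T, Y=np.zeros(n), Xstar=X + 0.4 * rng.standard_normal((n, 1)),
                           Z=np.empty((n, 0)))
        g = SimexGrid(sigma_e=np.array([[0.16]]), psi=PSI5, K=30, seed=5)
        traj = run_simex(s, "logistic", g)
        slopes = np.abs(traj.gamma[:, 1])
        assert np.all(np.diff(slopes) < 0)

    def test_reproducible_and_k_order_invariant(self, rng):
        s = _sample(rng)
        g = SimexGrid(sigma_e=0.2 * np.eye(2), psi=(0.0, 1.0), K=8, seed=3)
        t1 = run_simex(s, "logistic", g)
        t2 = run_simex(s, "logistic", g)
        assert np.array_equal(t1.gamma, t2.gamma)

    def test_tidy_export(self, rng):
        s = _sample(rng)
        g = SimexGrid(sigma_e=0.2 * np.eye(2), psi=(0.0, 1.0), K=2, seed=3)
        df = run_simex(s, "logistic", g).to_frame()
        assert set(df.columns) == {"component", "psi", "estimate"}
        assert len(df) == 2 * (1 + s.p)


class TestExtrapolation:
    def test_linear_exact(self):
        psi = np.array([0.0, 0.5, 1.0, 2.0])
        fit = fit_extrapolant(psi, 2 + 3 * psi, "linear")
        assert fit.value_at_minus_one == pytest.approx(-1.0, abs=1e-10)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)

    def test_quadratic_exact(self):
        psi = np.array([0.0, 0.5, 1.0, 1.5, 2.0])
        fit = fit_extrapolant(psi, 1 + psi**2, "quadratic")
        assert fit.value_at_minus_one == pytest.approx(2.0, abs=1e-10)

    def test_rational_linear_recovers_synthetic(self):
        psi = np.linspace(0.0, 2.0, 9)
        a, b, c = 0.0, 1.0, 2.0
        fit = fit_extrapolant(psi, a + b / (c + psi), "rational_linear")
        assert fit.family == "rational_linear"
        assert fit.value_at_minus_one == pytest.approx(a + b / (c - 1.0), abs=1e-6)

    def test_rational_pole_falls_back_to_quadratic(self):
        psi = np.linspace(0.0, 2.0, 9)
        v = 1.0 + 1.0 / (0.5 + psi)  # pole at -0.5, inside [-1, 2]
        with pytest.warns(UserWarning, match="pole"):
            fit = fit_extrapolant(psi, v, "rational_linear")
        assert fit.family == "quadratic"

    def test_constant_trajectory_any_family(self):
        psi = np.linspace(0.0, 2.0, 9)
        for fam in ("linear", "quadratic", "rational_linear"):
            fit = fit_extrapolant(psi, np.full(9, 1.7), fam)
            assert fit.value_at_minus_one == pytest.approx(1.7, abs=1e-9)

    def test_insufficient_points_rejected(self):
        with pytest.raises(ValueError, match="distinct psi"):
            fit_extrapolant([0.0, 1.0], [1.0, 2.0], "quadratic")
        with pytest.raises(ValueError, match="unknown extrapolant"):
            fit_extrapolant([0.0, 1.0], [1.0, 2.0], "cubic")

    def test_families_differ_on_curved_trajectory(self):
        psi = np.linspace(0.0, 2.0, 9)
        v = np.exp(-psi)
        lin = fit_extrapolant(psi, v, "linear").value_at_minus_one
        quad = fit_extrapolant(psi, v, "quadratic").value_at_minus_one
        assert np.isfinite(lin) and np.isfinite(quad) and lin != quad

    def test_attenuation_curve_is_exactly_rational_linear(self):
        """For a linear model with additive error the attenuated slope is
        beta * sx2 / (sx2 + (1+psi) se2) — a rational-linear function whose
        extrapolation to psi = -1 is the error-free slope."""
        beta, sx2, se2 = 1.8, 1.0, 0.5
        psi = np.linspace(0.0, 2.0, 9)
        curve = beta * sx2 / (sx2 + (1 + psi) * se2)
        fit = fit_extrapolant(psi, curve, "rational_linear")
        assert fit.value_at_minus_one == pytest.approx(beta, abs=1e-8)


def test_extrapolate_trajectory_componentwise(rng):
    s = _sample(rng)
    g = SimexGrid(sigma_e=0.2 * np.eye(2), psi=PSI5, K=10, seed=4)
    traj = run_simex(s, "logistic", g)
    gt = extrapolate_trajectory(traj, "quadratic")
    assert gt.shape == (1 + s.p,)
    assert np.all(np.isfinite(gt))
    ref = np.array(
        [fit_extrapolant(traj.psi, traj.gamma[:, j], "quadratic").value_at_minus_one
         for j in range(1 + s.p)]
    )
    assert np.array_equal(gt, ref)
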