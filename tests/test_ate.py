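import numpy as np
import pytest
from sklearn.base import clone

from simexsel import (
    ObservedSample,
    PositivityWarning,
    SimexSelectAte,
    SimulationDesign,
    bootstrap_se,
    fit_treatment_model,
    generate_dataset,
    ipw_ate,
    link_prob,
)

TAME = dict(sigma_e=0.2, K=10, psi_grid=(0.0, 0.5, 1.0, 1.5, 2.0), random_state=77)


class TestIpw:
    def test_hand_example(self):
        t, y, pi = np.array([1.0, 0.0]), np.array([2.0, 1.0]), np.array([0.5, 0.5])
        assert ipw_ate(t, y, pi, stabilized=True) == pytest.approx(1.0)
        assert ipw_ate(t, y, pi, stabilized=False) == pytest.approx(1.0)

    def test_constant_propensity_equals_arm_means(self, rng):
        n = 200
        t = (rng.random(n) < 0.5).astype(float)
        y = rng.normal(size=n)
        pi = np.full(n, 0.37)
        diff = y[t == 1].mean() - y[t == 0].mean()
        assert ipw_ate(t, y, pi) == pytest.approx(diff, abs=1e-12)

    def test_degenerate_propensity_names_subject(self):
        with pytest.raises(ValueError, match="index 1"):
            ipw_ate([1.0, 0.0], [1.0, 2.0], [0.5, 1.0])

    def test_positivity_warning(self):
        with pytest.warns(PositivityWarning):
            ipw_ate([1.0, 0.0, 1.0], [1.0, 2.0, 0.5], [0.005, 0.5, 0.6])

    def test_randomized_design_recovers_ate(self):
        """With known constant pi = 0.5 and a unit treatment effect the IPW
        estimate recovers tau0 = 1 within 3 Monte-Carlo SEs."""
        rng = np.random.default_rng(314)
        reps, n = 20, 10_000
        taus = []
        for _ in range(reps):
            t = (rng.random(n) < 0.5).astype(float)
            x = rng.standard_normal(n)
            y = t + x + rng.standard_normal(n)
            taus.append(ipw_ate(t, y, np.full(n, 0.5), stabilized=False))
        taus = np.asarray(taus)
        assert abs(taus.mean() - 1.0) < 3 * taus.std(ddof=1) / np.sqrt(reps)


class TestPipeline:
    def test_zero_error_collapses_to_naive_plugin(self, tame_sample):
        """Sigma_e = 0: the five-step estimate equals selection + plug-in IPW
        on X* exactly."""
        est = SimexSelectAte(sigma_e=0.0, K=5, random_state=1).fit(tame_sample)
        naive_gamma = fit_treatment_model("logistic", tame_sample)
        assert np.allclose(est.gamma_tilde_, naive_gamma, atol=1e-9)
        act = est.active_
        D = np.hstack([np.ones((tame_sample.n, 1)), tame_sample.W()])
        pi = link_prob("logistic", D[:, act] @ est.gamma_hat_[act])
        plug_in = ipw_ate(tame_sample.T, tame_sample.Y, pi)
        assert est.tau_hat_ == pytest.approx(plug_in, abs=1e-12)
        assert np.all(est.result_.tau_curve == est.result_.tau_curve[0])

    def test_reproducible_under_seed(self, tame_sample):
        a = SimexSelectAte(**TAME).fit(tame_sample)
        b = SimexSelectAte(**TAME).fit(tame_sample)
        assert a.tau_hat_ == b.tau_hat_
        assert np.array_equal(a.trajectory_.gamma, b.trajectory_.gamma)

    def test_recovers_effect_on_tame_design(self, tame_sample):
        est = SimexSelectAte(**TAME).fit(tame_sample)
        assert 0.4 < est.tau_hat_ < 1.6  # true effect 1, single replicate
        assert est.active_[1]  # the strong treatment predictor X1 is kept

    def test_full_model_variant(self, tame_sample):
        est = SimexSelectAte(penalty=None, **TAME).fit(tame_sample)
        assert est.selection_ is None
        assert est.active_.all()

    def test_sklearn_params_roundtrip(self):
        est = SimexSelectAte(sigma_e=0.1, K=7, penalty="lasso")
        assert clone(est).get_params() == est.get_params()

    def test_refit_option_runs(self, tame_sample):
        est = SimexSelectAte(refit=True, **TAME).fit(tame_sample)
        assert np.isfinite(est.tau_hat_)

    def test_tau_curve_extrapolation_consistency(self, tame_sample):
        from simexsel import fit_extrapolant

        est = SimexSelectAte(**TAME).fit(tame_sample)
        r = est.result_
        fit = fit_extrapolant(r.psi, r.tau_curve, r.family)
        assert r.tau_hat == pytest.approx(fit.value_at_minus_one, abs=1e-12)


class TestForcedInclusion:
    def test_forcing_selected_covariate_is_noop(self, tame_sample):
        est = SimexSelectAte(**TAME).fit(tame_sample)
        name = [n for n, a in zip(tame_sample.names, est.active_[1:]) if a][0]
        res = est.forced_ate(tame_sample, [name])
        assert res.tau_hat == pytest.approx(est.tau_hat_, abs=1e-12)

    def test_forcing_adds_to_active_set(self, tame_sample):
        from simexsel import SelectionResult, SimexGrid
        from simexsel.ate import forced_inclusion_ate

        gamma_tilde = np.array([0.2, 0.9, 0.1, -0.4])
        gamma_hat = np.array([0.2, 0.9, 0.0, -0.4])
        sel = SelectionResult(
            gamma_hat=gamma_hat, active=np.array([True, True, False, True]),
            lambdas=np.array([0.1]), path=gamma_hat[None, :], df=np.array([3]),
            bic=np.array([0.0]), lambda_star=0.1,
        )
        grid = SimexGrid(sigma_e=0.2 * np.eye(2), psi=(0.0, 1.0, 2.0), K=4, seed=0)
        base = forced_inclusion_ate(tame_sample, sel, gamma_tilde, [], grid)
        forced = forced_inclusion_ate(tame_sample, sel, gamma_tilde, ["X2"], grid)
        # the shrunk-to-zero covariate re-enters with its pilot coefficient
        assert np.isfinite(forced.tau_hat) and forced.tau_hat != base.tau_hat

    def test_unknown_name_rejected(self, tame_sample):
        est = SimexSelectAte(**TAME).fit(tame_sample)
        with pytest.raises(ValueError, match="unknown"):
            est.forced_ate(tame_sample, ["XX9"])

    def test_forcing_null_covariate_close_to_tau(self):
        """Forcing a truly unimportant covariate barely moves the estimate."""
        d = SimulationDesign(
            n=500, px=2, pz=1, gamma_x=np.array([0.9, 0.0]), gamma_z=np.array([0.0]),
            beta_x=np.array([1.0, 0.0]), beta_z=np.array([0.0]), sigma_e2=0.2, seed=9,
        )
        sample, truth = generate_dataset(d)
        est = SimexSelectAte(sigma_e=0.2, K=20, random_state=9).fit(sample)
        if est.active_[2]:
            pytest.skip("null covariate selected on this draw")
        res = est.forced_ate(sample, ["X2"])
        assert abs(res.tau_hat - est.tau_hat_) < 0.2


class TestBootstrap:
    small = dict(sigma_e=0.2, K=4, psi_grid=(0.0, 1.0, 2.0), n_lambda=20)

    def _tiny_sample(self, seed=0, n=80, y=None):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, 1))
        T = (rng.random(n) < 1 / (1 + np.exp(-(0.2 + X[:, 0])))).astype(float)
        Y = (T + X[:, 0] + rng.standard_normal(n)) if y is None else np.full(n, y)
        return ObservedSample(T=T, Y=Y, Xstar=X + 0.3 * rng.standard_normal((n, 1)),
                              Z=np.empty((n, 0)))

    def test_constant_outcome_gives_zero_se(self):
        s = self._tiny_sample(y=3.0)
        se, ci, p = bootstrap_se(s, dict(self.small, random_state=4), B=50, random_state=4)
        assert se == pytest.approx(0.0, abs=1e-10)
        assert ci[0] == pytest.approx(ci[1], abs=1e-9)

    def test_minimum_replicates_enforced(self):
        with pytest.raises(ValueError, match="at least 50"):
            bootstrap_se(self._tiny_sample(), self.small, B=10)

    def test_bootstrap_size_stability(self):
        """B=50 and B=200 standard errors agree within Monte-Carlo slack."""
        s = self._tiny_sample(seed=5)
        se50, *_ = bootstrap_se(s, dict(self.small, random_state=1), B=50, random_state=1)
        se200, *_ = bootstrap_se(s, dict(self.small, random_state=2), B=200, random_state=2)
        assert se50 > 0 and se200 > 0
        assert 0.5 < se50 / se200 < 2.0

    def test_estimator_level_interface(self):
        s = self._tiny_sample(seed=6)
        est = SimexSelectAte(n_bootstrap=50, random_state=3, **self.small).fit(s)
        assert est.se_ > 0
        assert est.ci_[0] < est.tau_hat_ < est.ci_[1]
        assert 0 <= est.p_value_ <= 1

    def test_bootstrap_se_tracks_sampling_variability(self):
        """Bootstrap SE within a factor 1.5 of the empirical SE over
        independent replicates of the same tame design."""
        taus = []
        for seed in range(25):
            s = self._tiny_sample(seed=100 + seed, n=120)
            est = SimexSelectAte(random_state=seed, **self.small).fit(s)
            taus.append(est.tau_hat_)
        emp_se = np.std(taus, ddof=1)
        s = self._tiny_sample(seed=100, n=120)
        boot_se, *_ = bootstrap_se(s, dict(self.small, random_state=0), B=60, random_state=0)
        assert boot_se / emp_se < 1.5 and emp_se / boot_se < 1.5
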