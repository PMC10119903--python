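"""IPW estimation of the average treatment effect (pipeline step 5) and the
end-to-end estimator class.

The ATE is estimated by inverse probability weighting.  Writing pi_hat_i for
the fitted propensity score, the stabilized (ratio-of-weighted-sums) form

    tau_hat = sum(T Y / pi) / sum(T / pi)
              - sum((1-T) Y / (1-pi)) / sum((1-T) / (1-pi))

is the default; the unstabilized simple-mean form is available as well.

Measurement error is corrected at the tau level: for each pseudo-error
replicate k and noise level psi, propensity scores are computed from the
*selected* treatment model with the active error-prone covariates replaced by
the pseudo-data X*_I(k, psi) (reusing the same e_ik as step 1), the
stabilized IPW estimate tau_hat(k, psi) is K-averaged, and the curve
psi -> tau_hat(psi) is extrapolated to psi = -1.

Uncertainty is quantified by a nonparametric bootstrap over subjects (the
full five-step pipeline is re-run on each resample with fresh pseudo-errors).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .data import ObservedSample
from .selection import PenaltySpec, SelectionResult, select
from .simex import (
    DEFAULT_PSI,
    SimexGrid,
    SimexTrajectory,
    extrapolate_trajectory,
    fit_extrapolant,
    pseudo_errors,
    run_simex,
)
from .treatment import link_prob

__all__ = [
    "PositivityWarning",
    "AteResult",
    "ipw_ate",
    "simex_ate",
    "forced_inclusion_ate",
    "bootstrap_se",
    "SimexSelectAte",
]


class PositivityWarning(UserWarning):
    """Fitted propensity scores close to 0 or 1 (weights may be unstable)."""


def ipw_ate(T, Y, pi_hat, stabilized: bool = True) -> float:
    """Inverse-probability-weighted ATE estimate on fixed inputs.

    Raises if any propensity is exactly 0 or 1; propensities outside
    (0.01, 0.99) trigger a :class:`PositivityWarning` but are used as-is.
    """
    T = np.asarray(T, dtype=float).ravel()
    Y = np.asarray(Y, dtype=float).ravel()
    pi = np.asarray(pi_hat, dtype=float).ravel()
    bad = np.flatnonzero((pi <= 0.0) | (pi >= 1.0))
    if bad.size:
        raise ValueError(
            f"propensity score is 0 or 1 for subject index {bad[0]} "
            "(positivity violated)"
        )
    if np.any((pi < 0.01) | (pi > 0.99)):
        warnings.warn(
            "propensity scores outside (0.01, 0.99); IPW weights may be unstable",
            PositivityWarning,
            stacklevel=2,
        )
    w1 = T / pi
    w0 = (1.0 - T) / (1.0 - pi)
    if stabilized:
        return float(np.sum(w1 * Y) / np.sum(w1) - np.sum(w0 * Y) / np.sum(w0))
    n = T.shape[0]
    return float(np.sum(w1 * Y) / n - np.sum(w0 * Y) / n)


@dataclass
class AteResult:
    """Point estimate with its SIMEX curve and (optional) bootstrap inference."""

    tau_hat: float
    psi: np.ndarray
    tau_curve: np.ndarray  # tau_hat(psi), K-averaged
    family: str
    se: float | None = None
    ci: tuple | None = None
    p_value: float | None = None
    n_boot: int = 0
    flags: list[str] = field(default_factory=list)

    def curve_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"psi": self.psi, "tau_hat": self.tau_curve})


def _active_propensity(sample, grid, gamma, active, link, E, k, psi):
    """Fitted propensities from the selected model on pseudo-data X*_I(k, psi)."""
    px = sample.px
    x_active = np.flatnonzero(active[1 : 1 + px])
    z_active = np.flatnonzero(active[1 + px :])
    eta = np.full(sample.n, gamma[0])
    if x_active.size:
        Xk = sample.Xstar[:, x_active] + grid.scale(psi) * E[k][:, x_active]
        eta = eta + Xk @ gamma[1 + x_active]
    if z_active.size:
        eta = eta + sample.Z[:, z_active] @ gamma[1 + px + z_active]
    return link_prob(link, eta)


def simex_ate(
    sample: ObservedSample,
    gamma_hat: np.ndarray,
    active: np.ndarray,
    grid: SimexGrid,
    link: str = "logistic",
    family: str = "quadratic",
    stabilized: bool = True,
) -> AteResult:
    """Step 5: SIMEX-corrected IPW estimate under the selected model.

    The selected coefficients ``gamma_hat`` are held fixed (no refit); the
    pseudo-errors are regenerated from the grid seed and therefore identical
    to those used in steps 1-2.
    """
    gamma_hat = np.asarray(gamma_hat, dtype=float)
    active = np.asarray(active, dtype=bool)
    flags = []
    if not active[1:].any():
        warnings.warn(
            "selected treatment model is intercept-only; propensity is constant",
            stacklevel=2,
        )
        flags.append("intercept_only")

    x_active_any = active[1 : 1 + sample.px].any()
    if grid.is_error_free or not x_active_any:
        # No pseudo-noise reaches the propensities: the curve is flat and the
        # extrapolation collapses to the plug-in estimate.
        E = np.zeros((1, sample.n, sample.px))
        pi = _active_propensity(sample, grid, gamma_hat, active, link, E, 0, 0.0)
        tau = ipw_ate(sample.T, sample.Y, pi, stabilized=stabilized)
        curve = np.full(grid.M, tau)
        return AteResult(tau, np.asarray(grid.psi), curve, family, flags=flags)

    E = pseudo_errors(grid, sample.n)
    curve = np.zeros(grid.M)
    for m, psi in enumerate(grid.psi):
        tk = np.zeros(grid.K)
        for k in range(grid.K):
            pi = _active_propensity(sample, grid, gamma_hat, active, link, E, k, psi)
            tk[k] = ipw_ate(sample.T, sample.Y, pi, stabilized=stabilized)
        curve[m] = tk.mean()
    fit = fit_extrapolant(grid.psi, curve, family)
    return AteResult(fit.value_at_minus_one, np.asarray(grid.psi), curve, family, flags=flags)


def forced_inclusion_ate(
    sample: ObservedSample,
    selection: SelectionResult,
    gamma_tilde: np.ndarray,
    forced: list[str],
    grid: SimexGrid,
    link: str = "logistic",
    family: str = "quadratic",
    stabilized: bool = True,
) -> AteResult:
    """ATE with must-include covariates added to the selected model.

    Forced covariates that the penalty shrank to zero re-enter with their
    unpenalized SIMEX-extrapolated coefficients from ``gamma_tilde``; already
    selected covariates are unchanged, so forcing them is a no-op.
    """
    names = sample.names
    unknown = [f for f in forced if f not in names]
    if unknown:
        raise ValueError(f"unknown covariate name(s): {unknown}")
    active = selection.active.copy()
    gamma = selection.gamma_hat.copy()
    for f in forced:
        j = 1 + names.index(f)
        if not active[j]:
            active[j] = True
            gamma[j] = gamma_tilde[j]
    return simex_ate(
        sample, gamma, active, grid, link=link, family=family, stabilized=stabilized
    )


class SimexSelectAte(BaseEstimator):
    """Five-step ATE estimator: SIMEX error correction + penalized confounder
    selection + stabilized IPW.

    Parameters
    ----------
    sigma_e : measurement-error covariance of the surrogates X*.  A scalar is
        expanded to ``sigma_e * I``; 0 (or a zero matrix) collapses the whole
        pipeline to the naive analysis that treats X* as exact.
    link : treatment-model link, {"logistic", "probit", "cloglog"}.
    psi_grid : SIMEX noise-level grid C (must start at 0).
    K : pseudo-error replicates per psi.
    extrapolant : {"quadratic", "linear", "rational_linear"}.
    penalty : {"scad", "lasso"} or a full :class:`PenaltySpec`; ``None``
        disables step 4 (the "full model" analysis).
    a, n_lambda, lambda_grid, V : forwarded to :class:`PenaltySpec`.
    forced : names of must-include covariates (their penalty weight is 0).
    stabilized : use the stabilized IPW form (default) or the simple-mean one.
    refit : refit the unpenalized SIMEX pipeline on the selected submodel
        before step 5 (off by default; the shrunken coefficients are used
        as-is).
    psi_scaling : pseudo-error scaling, "sqrt" (standard) or "linear".
    n_bootstrap : bootstrap replicates for SE/CI/p-value; 0 skips inference.
    random_state : seed for pseudo-errors (and the bootstrap).

    Attributes (after ``fit``)
    --------------------------
    trajectory_ : :class:`SimexTrajectory` of full-model coefficients.
    gamma_tilde_ : extrapolated (unpenalized) coefficients at psi = -1.
    selection_ : :class:`SelectionResult` (None when penalty is None).
    gamma_hat_, active_ : selected coefficients and active-set mask.
    tau_hat_, result_ : point estimate and full :class:`AteResult`.
    se_, ci_, p_value_ : bootstrap inference when ``n_bootstrap > 0``.
    """

    def __init__(
        self,
        sigma_e=0.0,
        link="logistic",
        psi_grid=DEFAULT_PSI,
        K=500,
        extrapolant="quadratic",
        penalty="scad",
        a=3.7,
        n_lambda=50,
        lambda_grid=None,
        V=None,
        forced=None,
        stabilized=True,
        refit=False,
        psi_scaling="sqrt",
        n_bootstrap=0,
        random_state=None,
    ):
        self.sigma_e = sigma_e
        self.link = link
        self.psi_grid = psi_grid
        self.K = K
        self.extrapolant = extrapolant
        self.penalty = penalty
        self.a = a
        self.n_lambda = n_lambda
        self.lambda_grid = lambda_grid
        self.V = V
        self.forced = forced
        self.stabilized = stabilized
        self.refit = refit
        self.psi_scaling = psi_scaling
        self.n_bootstrap = n_bootstrap
        self.random_state = random_state

    # -- internal helpers -------------------------------------------------
    def _grid(self, sample: ObservedSample, seed=None) -> SimexGrid:
        sig = np.asarray(self.sigma_e, dtype=float)
        if sig.ndim == 0:
            sig = float(sig) * np.eye(sample.px)
        return SimexGrid(
            sigma_e=sig,
            psi=tuple(self.psi_grid),
            K=self.K,
            seed=self.random_state if seed is None else seed,
            psi_scaling=self.psi_scaling,
        )

    def _penalty_spec(self) -> PenaltySpec | None:
        if self.penalty is None:
            return None
        if isinstance(self.penalty, PenaltySpec):
            return self.penalty
        return PenaltySpec(
            kind=self.penalty,
            a=self.a,
            lambda_grid=self.lambda_grid,
            n_lambda=self.n_lambda,
            V=self.V,
        )

    def _forced_mask(self, sample: ObservedSample) -> np.ndarray | None:
        if not self.forced:
            return None
        names = sample.names
        mask = np.zeros(1 + sample.p, dtype=bool)
        for f in self.forced:
            if f not in names:
                raise ValueError(f"unknown forced covariate {f!r}")
            mask[1 + names.index(f)] = True
        return mask

    def _point_estimate(self, sample: ObservedSample, seed=None):
        grid = self._grid(sample, seed=seed)
        traj = run_simex(sample, self.link, grid)
        gamma_tilde = extrapolate_trajectory(traj, self.extrapolant)
        spec = self._penalty_spec()
        if spec is None:
            selection = None
            gamma_hat = gamma_tilde.copy()
            active = np.ones_like(gamma_hat, dtype=bool)
        else:
            selection = select(
                gamma_tilde,
                spec,
                sample.n,
                forced=self._forced_mask(sample),
                names=["intercept"] + sample.names,
            )
            gamma_hat, active = selection.gamma_hat, selection.active
            if self.refit:
                gamma_hat, active = self._refit_active(sample, grid, active)
        result = simex_ate(
            sample,
            gamma_hat,
            active,
            grid,
            link=self.link,
            family=self.extrapolant,
            stabilized=self.stabilized,
        )
        return traj, gamma_tilde, selection, gamma_hat, active, result

    def _refit_active(self, sample: ObservedSample, grid: SimexGrid, active):
        """Unpenalized SIMEX refit restricted to the selected covariates."""
        px = sample.px
        x_keep = np.flatnonzero(active[1 : 1 + px])
        z_keep = np.flatnonzero(active[1 + px :])
        sub = ObservedSample(
            T=sample.T,
            Y=sample.Y,
            Xstar=sample.Xstar[:, x_keep],
            Z=sample.Z[:, z_keep],
            x_names=[sample.x_names[j] for j in x_keep],
            z_names=[sample.z_names[j] for j in z_keep],
        )
        sub_grid = SimexGrid(
            sigma_e=np.asarray(grid.sigma_e)[np.ix_(x_keep, x_keep)]
            if np.asarray(grid.sigma_e).ndim == 2
            else grid.sigma_e,
            psi=grid.psi,
            K=grid.K,
            seed=grid.seed,
            psi_scaling=grid.psi_scaling,
        )
        sub_tilde = extrapolate_trajectory(
            run_simex(sub, self.link, sub_grid), self.extrapolant
        )
        gamma_hat = np.zeros(1 + sample.p)
        gamma_hat[0] = sub_tilde[0]
        gamma_hat[1 + x_keep] = sub_tilde[1 : 1 + len(x_keep)]
        gamma_hat[1 + px + z_keep] = sub_tilde[1 + len(x_keep) :]
        return gamma_hat, active

    # -- public API --------------------------------------------------------
    def fit(self, sample: ObservedSample):
        """Run steps 1-5 (and the bootstrap when ``n_bootstrap > 0``)."""
        (
            self.trajectory_,
            self.gamma_tilde_,
            self.selection_,
            self.gamma_hat_,
            self.active_,
            self.result_,
        ) = self._point_estimate(sample)
        self.tau_hat_ = self.result_.tau_hat
        self.n_features_in_ = sample.p
        if self.n_bootstrap:
            se, ci, p = bootstrap_se(
                sample,
                self.get_params(),
                B=self.n_bootstrap,
                random_state=self.random_state,
                tau_hat=self.tau_hat_,
            )
            self.se_, self.ci_, self.p_value_ = se, ci, p
            self.result_.se = se
            self.result_.ci = ci
            self.result_.p_value = p
            self.result_.n_boot = self.n_bootstrap
        return self

    def forced_ate(self, sample: ObservedSample, forced: list[str]) -> AteResult:
        """Re-run step 5 with extra must-include covariates (tau_hat_F)."""
        if self.selection_ is None:
            raise ValueError("forced inclusion requires a penalized fit")
        return forced_inclusion_ate(
            sample,
            self.selection_,
            self.gamma_tilde_,
            forced,
            self._grid(sample),
            link=self.link,
            family=self.extrapolant,
            stabilized=self.stabilized,
        )


def bootstrap_se(
    sample: ObservedSample,
    params: dict,
    B: int = 200,
    random_state=None,
    tau_hat: float | None = None,
):
    """Nonparametric bootstrap over subjects for the full pipeline.

    Each resample re-runs steps 1-5 with fresh pseudo-errors.  Returns
    (S.E., normal-approximation 95% CI, two-sided p-value for tau_0 = 0).
    Errors out if more than 20% of the replicates fail.
    """
    if B < 50:
        raise ValueError("need at least 50 bootstrap replicates")
    ss = np.random.SeedSequence(random_state)
    children = ss.spawn(B + 1)
    rng = np.random.default_rng(children[0])
    params = dict(params, n_bootstrap=0)
    taus = []
    failures = 0
    for b in range(B):
        idx = rng.integers(0, sample.n, size=sample.n)
        try:
            boot = sample.subset(idx)
            est = SimexSelectAte(**params)
            seed = int(children[b + 1].generate_state(1)[0] % (2**31))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, _, _, _, _, res = est._point_estimate(boot, seed=seed)
            taus.append(res.tau_hat)
        except Exception:
            failures += 1
    if failures > 0.2 * B:
        raise RuntimeError(f"{failures}/{B} bootstrap replicates failed")
    taus = np.asarray(taus)
    se = float(taus.std(ddof=1))
    center = float(np.mean(taus)) if tau_hat is None else float(tau_hat)
    zq = stats.norm.ppf(0.975)
    ci = (center - zq * se, center + zq * se)
    if se == 0:
        p = 0.0 if center != 0 else 1.0
    else:
        p = float(2.0 * stats.norm.sf(abs(center) / se))
    return se, ci, p
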