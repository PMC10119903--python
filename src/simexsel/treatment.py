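"""Parametric propensity-score (treatment) models.

Three binary-regression links are supported — logistic, probit and
complementary log-log.  The treatment model is

    pi_i = g(gamma_0 + gamma_x' X_i + gamma_z' Z_i),

and the unpenalized estimator solves the likelihood score equation
``sum_i S_i(gamma) = 0`` by Fisher scoring with step-halving.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import expit, ndtr
from sklearn.base import BaseEstimator

from .data import ObservedSample

__all__ = [
    "LINKS",
    "TreatmentModelSpec",
    "ConvergenceError",
    "SeparationWarning",
    "link_prob",
    "link_deriv",
    "score",
    "log_likelihood",
    "fit_treatment_model",
    "PropensityModel",
]

# Probabilities are clipped into the open unit interval for numerical
# stability of the score/weights at extreme linear predictors.
PROB_CLIP = 1e-10
# Coefficients beyond this magnitude (on standardized covariates) indicate
# complete or quasi-complete separation.
SEPARATION_CAP = 1e2


class ConvergenceError(RuntimeError):
    """Raised when Fisher scoring fails; carries the last iterate."""

    def __init__(self, message: str, coef: np.ndarray):
        super().__init__(message)
        self.coef = coef


class SeparationWarning(UserWarning):
    pass


def _logistic_prob(eta):
    return expit(eta)


def _logistic_deriv(eta):
    p = expit(eta)
    return p * (1.0 - p)


def _probit_prob(eta):
    return ndtr(eta)


def _probit_deriv(eta):
    return stats.norm.pdf(eta)


def _cloglog_prob(eta):
    # 1 - exp(-exp(eta)); clip eta so exp() cannot overflow
    return -np.expm1(-np.exp(np.clip(eta, -700.0, 30.0)))


def _cloglog_deriv(eta):
    e = np.clip(eta, -700.0, 30.0)
    return np.exp(e - np.exp(e))


LINKS = {
    "logistic": (_logistic_prob, _logistic_deriv),
    "probit": (_probit_prob, _probit_deriv),
    "cloglog": (_cloglog_prob, _cloglog_deriv),
}


@dataclass(frozen=True)
class TreatmentModelSpec:
    """Link family plus the coefficient layout ``(gamma_0, gamma_x, gamma_z)``."""

    link: str = "logistic"

    def __post_init__(self):
        if self.link not in LINKS:
            raise ValueError(
                f"unknown link {self.link!r}; choose one of {sorted(LINKS)}"
            )


def _resolve_link(spec) -> str:
    if isinstance(spec, TreatmentModelSpec):
        return spec.link
    if spec in LINKS:
        return spec
    raise ValueError(f"unknown link {spec!r}; choose one of {sorted(LINKS)}")


def link_prob(spec, eta: np.ndarray) -> np.ndarray:
    """Success probability g(eta), clipped into (0, 1)."""
    prob, _ = LINKS[_resolve_link(spec)]
    return np.clip(prob(np.asarray(eta, dtype=float)), PROB_CLIP, 1.0 - PROB_CLIP)


def link_deriv(spec, eta: np.ndarray) -> np.ndarray:
    """Derivative g'(eta)."""
    _, deriv = LINKS[_resolve_link(spec)]
    return deriv(np.asarray(eta, dtype=float))


def _design(sample: ObservedSample, X_override=None) -> np.ndarray:
    W = sample.W(X_override)
    return np.hstack([np.ones((sample.n, 1)), W])


def log_likelihood(spec, gamma, T, D) -> float:
    p = link_prob(spec, D @ gamma)
    return float(np.sum(T * np.log(p) + (1.0 - T) * np.log1p(-p)))


def score(
    spec,
    gamma: np.ndarray,
    sample: ObservedSample,
    X_override: np.ndarray | None = None,
) -> np.ndarray:
    """Total likelihood score sum_i S_i(gamma) for the Bernoulli model.

    ``X_override`` substitutes a pseudo-data matrix X*(k, psi) for the
    observed surrogates (SIMEX step 2).
    """
    D = _design(sample, X_override)
    gamma = np.asarray(gamma, dtype=float)
    if gamma.shape[0] != D.shape[1]:
        raise ValueError(f"gamma has length {gamma.shape[0]}, expected {D.shape[1]}")
    return _score_design(spec, gamma, sample.T, D)


def _score_design(spec, gamma, T, D) -> np.ndarray:
    eta = D @ gamma
    p = link_prob(spec, eta)
    g1 = link_deriv(spec, eta)
    r = (T - p) * g1 / (p * (1.0 - p))
    return D.T @ r


def _fisher_info(spec, gamma, D) -> np.ndarray:
    eta = D @ gamma
    p = link_prob(spec, eta)
    g1 = link_deriv(spec, eta)
    w = g1 * g1 / (p * (1.0 - p))
    return (D * w[:, None]).T @ D


def _newton_fit(spec, T, D, tol=1e-8, max_iter=100):
    """Fisher scoring from a zero start with step-halving on the log-likelihood."""
    link = _resolve_link(spec)
    q = D.shape[1]
    gamma = np.zeros(q)
    ll = log_likelihood(link, gamma, T, D)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        s = _score_design(link, gamma, T, D)
        if np.max(np.abs(s)) < tol:
            converged = True
            break
        H = _fisher_info(link, gamma, D)
        try:
            step = np.linalg.solve(H, s)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, s, rcond=None)[0]
        t = 1.0
        for _ in range(40):
            cand = gamma + t * step
            ll_new = log_likelihood(link, cand, T, D)
            if ll_new >= ll - 1e-12:
                break
            t *= 0.5
        gamma = gamma + t * step
        ll = log_likelihood(link, gamma, T, D)
    else:
        s = _score_design(link, gamma, T, D)
        converged = bool(np.max(np.abs(s)) < tol)
    if np.max(np.abs(gamma)) > SEPARATION_CAP:
        warnings.warn(
            "treatment-model coefficients exceed the separation cap; the fit is "
            "likely (quasi-)separated and the estimate has been capped",
            SeparationWarning,
            stacklevel=3,
        )
        gamma = np.clip(gamma, -SEPARATION_CAP, SEPARATION_CAP)
    return gamma, converged, it


def fit_treatment_model(
    spec,
    sample: ObservedSample,
    X_override: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> np.ndarray:
    """Solve ``sum_i S_i(gamma) = 0`` for the full treatment model.

    Returns the coefficient vector ``(gamma_0, gamma_x, gamma_z)``.  Raises
    :class:`ConvergenceError` (carrying the last iterate) if the score does
    not reach the tolerance within ``max_iter`` iterations.
    """
    D = _design(sample, X_override)
    gamma, converged, it = _newton_fit(spec, sample.T, D, tol=tol, max_iter=max_iter)
    if not converged:
        raise ConvergenceError(
            f"treatment-model fit did not converge in {it} iterations", gamma
        )
    return gamma


class PropensityModel(BaseEstimator):
    """Parametric propensity-score model with a named link.

    A small scikit-learn style estimator: ``fit(W, T)`` solves the likelihood
    score equation; fitted coefficients are exposed as ``intercept_`` and
    ``coef_`` and probabilities via :meth:`predict_proba`.

    Parameters
    ----------
    link : {"logistic", "probit", "cloglog"}
    tol : convergence tolerance on the max-norm of the score.
    max_iter : Fisher-scoring iteration cap.
    """

    def __init__(self, link: str = "logistic", tol: float = 1e-8, max_iter: int = 100):
        self.link = link
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, W, T):
        W = np.atleast_2d(np.asarray(W, dtype=float))
        T = np.asarray(T, dtype=float).ravel()
        D = np.hstack([np.ones((W.shape[0], 1)), W])
        gamma, converged, it = _newton_fit(
            self.link, T, D, tol=self.tol, max_iter=self.max_iter
        )
        if not converged:
            raise ConvergenceError(
                f"propensity model did not converge in {it} iterations", gamma
            )
        self.intercept_ = float(gamma[0])
        self.coef_ = gamma[1:].copy()
        self.n_iter_ = it
        self.converged_ = converged
        return self

    def decision_function(self, W) -> np.ndarray:
        W = np.atleast_2d(np.asarray(W, dtype=float))
        return self.intercept_ + W @ self.coef_

    def predict_proba(self, W) -> np.ndarray:
        p1 = link_prob(self.link, self.decision_function(W))
        return np.column_stack([1.0 - p1, p1])
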