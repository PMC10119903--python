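"""Synthetic-data generators for the benchmark simulation designs.

The generator emulates an observational study with a rich, correlated
pre-treatment covariate set of which only half predicts the treatment:

* covariates (X, Z) ~ N(0, Sigma_w) with unit-variance AR(rho) blocks
  Sigma_xx, Sigma_zz and cross-covariances (j,k) = 0.4^(2 + |j-k|);
* a binary treatment from a logistic / probit / cloglog model with
  gamma_0 = 1 and gamma_x = gamma_z = (1_{dx/2}, -1_{dx/2}, 0);
* a continuous outcome  Y = T + beta_x' X + beta_z' Z + eps, eps ~ N(0,1)
  ("model1_linear", true ATE exactly 1), or a binary outcome with
  logit P(Y=1 | T, X, Z) = T + beta_x' X + beta_z' Z ("model2_logistic",
  true ATE obtained by Monte Carlo integration over the covariate law);
* surrogates X* = X + e with e ~ N(0, sigma_e2 * I) (classical additive,
  non-differential error).

Defaults: n = 400, px = pz = 15, dx = dz = ceil(px/2) = 8 active outcome
covariates per block, sigma2 = 1, rho = 0.5, sigma_e2 in {0.15, 0.50, 0.75}.

Note on the cross-covariance: the entry is read as the *power* 0.4^(2+|j-k|);
a multiplicative reading 0.4*(2+|j-k|) would produce cross-covariances above
1 between unit-variance components and an invalid (indefinite) Sigma_w.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data import ObservedSample
from .treatment import link_prob

__all__ = ["SimulationDesign", "build_sigma_w", "generate_dataset", "true_tau", "TruthRecord"]

OUTCOME_MODELS = ("model1_linear", "model2_logistic")


def _half_signs(d: int, p: int) -> np.ndarray:
    h = d // 2
    return np.concatenate([np.ones(h), -np.ones(d - h), np.zeros(p - d)])


def _ones_block(d: int, p: int) -> np.ndarray:
    return np.concatenate([np.ones(d), np.zeros(p - d)])


@dataclass
class SimulationDesign:
    """Parameters of one simulation scenario (defaults give the benchmark
    design described in the module docstring)."""

    n: int = 400
    px: int = 15
    pz: int = 15
    outcome_model: str = "model1_linear"
    treatment_link: str = "logistic"
    gamma0: float = 1.0
    gamma_x: np.ndarray | None = None
    gamma_z: np.ndarray | None = None
    beta_x: np.ndarray | None = None
    beta_z: np.ndarray | None = None
    sigma_x2: float = 1.0
    sigma_z2: float = 1.0
    rho_x: float = 0.5
    rho_z: float = 0.5
    sigma_e2: float = 0.15
    seed: int | None = None

    def __post_init__(self):
        if self.outcome_model not in OUTCOME_MODELS:
            raise ValueError(f"outcome_model must be one of {OUTCOME_MODELS}")
        if self.sigma_e2 < 0:
            raise ValueError("sigma_e2 must be non-negative")
        if self.gamma_x is None:
            self.gamma_x = _half_signs(self.dx, self.px)
        if self.gamma_z is None:
            self.gamma_z = _half_signs(self.dz, self.pz)
        if self.beta_x is None:
            self.beta_x = _ones_block(self.dx, self.px)
        if self.beta_z is None:
            self.beta_z = _ones_block(self.dz, self.pz)
        for name, vec, p in (
            ("gamma_x", self.gamma_x, self.px),
            ("gamma_z", self.gamma_z, self.pz),
            ("beta_x", self.beta_x, self.px),
            ("beta_z", self.beta_z, self.pz),
        ):
            arr = np.asarray(vec, dtype=float)
            if arr.shape != (p,):
                raise ValueError(f"{name} must have length {p}")
            setattr(self, name, arr)

    @property
    def dx(self) -> int:
        return math.ceil(self.px / 2)

    @property
    def dz(self) -> int:
        return math.ceil(self.pz / 2)

    @property
    def gamma(self) -> np.ndarray:
        """True treatment-model coefficients (intercept first)."""
        return np.concatenate([[self.gamma0], self.gamma_x, self.gamma_z])

    @property
    def beta(self) -> np.ndarray:
        return np.concatenate([self.beta_x, self.beta_z])


def build_sigma_w(design: SimulationDesign) -> np.ndarray:
    """Covariate covariance Sigma_w = [[Sxx, Sxz], [Sxz', Szz]].

    Sxx(j,k) = sigma_x2 * rho_x^|j-k|, Szz analogous, Sxz(j,k) = 0.4^(2+|j-k|).
    Raises if the assembled matrix is not positive definite.
    """
    jx = np.arange(design.px)
    jz = np.arange(design.pz)
    Sxx = design.sigma_x2 * design.rho_x ** np.abs(jx[:, None] - jx[None, :])
    Szz = design.sigma_z2 * design.rho_z ** np.abs(jz[:, None] - jz[None, :])
    Sxz = 0.4 ** (2.0 + np.abs(jx[:, None] - jz[None, :]))
    Sw = np.block([[Sxx, Sxz], [Sxz.T, Szz]])
    if np.linalg.eigvalsh(Sw).min() <= 0:
        raise ValueError("Sigma_w is not positive definite for these parameters")
    return Sw


@dataclass
class TruthRecord:
    """Ground truth attached to a generated dataset."""

    X: np.ndarray  # error-free covariates
    gamma: np.ndarray  # true treatment coefficients (intercept first)
    beta: np.ndarray
    pi: np.ndarray  # true propensity scores
    design: SimulationDesign = field(repr=False, default=None)


def generate_dataset(
    design: SimulationDesign, rng=None
) -> tuple[ObservedSample, TruthRecord]:
    """Draw one dataset: covariates, treatment, outcome and surrogates.

    Returns the observable sample (with X* in the X slot) and a
    :class:`TruthRecord` carrying the true X, coefficients and propensities.
    """
    rng = np.random.default_rng(design.seed if rng is None else rng)
    Sw = build_sigma_w(design)
    L = np.linalg.cholesky(Sw)
    W = rng.standard_normal((design.n, design.px + design.pz)) @ L.T
    X, Z = W[:, : design.px], W[:, design.px :]
    eta = design.gamma0 + X @ design.gamma_x + Z @ design.gamma_z
    pi = link_prob(design.treatment_link, eta)
    T = (rng.random(design.n) < pi).astype(float)
    lin = T + X @ design.beta_x + Z @ design.beta_z
    if design.outcome_model == "model1_linear":
        Y = lin + rng.standard_normal(design.n)
    else:
        Y = (rng.random(design.n) < link_prob("logistic", lin)).astype(float)
    e = math.sqrt(design.sigma_e2) * rng.standard_normal((design.n, design.px))
    Xstar = X + e
    sample = ObservedSample(T=T, Y=Y, Xstar=Xstar, Z=Z)
    return sample, TruthRecord(X=X, gamma=design.gamma, beta=design.beta, pi=pi, design=design)


def true_tau(design: SimulationDesign, n_mc: int = 5000, rng=None) -> float:
    """True average treatment effect tau_0 under the design.

    model1_linear: exactly 1 (the treatment enters additively with unit
    coefficient and the covariate terms cancel in the contrast).
    model2_logistic: Monte Carlo average of
    expit(1 + beta' w) - expit(beta' w) over w ~ N(0, Sigma_w).
    """
    if design.outcome_model == "model1_linear":
        return 1.0
    if n_mc < 1000:
        raise ValueError("n_mc must be at least 1000 for the logistic outcome model")
    rng = np.random.default_rng(design.seed if rng is None else rng)
    L = np.linalg.cholesky(build_sigma_w(design))
    u = (rng.standard_normal((n_mc, design.px + design.pz)) @ L.T) @ design.beta
    p1 = link_prob("logistic", 1.0 + u)
    p0 = link_prob("logistic", u)
    return float(np.mean(p1 - p0))
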