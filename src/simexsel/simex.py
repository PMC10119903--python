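"""Simulation-extrapolation (SIMEX) engine.

SIMEX removes the bias induced by additive covariate measurement error
X* = X + e, e ~ N(0, Sigma_e), by *adding* extra pseudo-error of known
variance psi * Sigma_e, tracing the resulting estimate as a function of psi,
and extrapolating the trend back to psi = -1 where the cumulative error
variance (1 + psi) * Sigma_e vanishes.

The engine implements the first three pipeline steps:

1. pseudo-data generation  X*(k, psi) = X* + sqrt(psi) * e_ik,
2. per-psi estimation of the full treatment model, averaged over the K
   pseudo-error replicates, and
3. componentwise extrapolation of the coefficient trajectory to psi = -1.

The pseudo-errors e_ik are a deterministic function of the grid seed and the
indices (i, k) only — the ATE step (step 5) reuses exactly the same draws.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .data import ObservedSample
from .treatment import ConvergenceError, fit_treatment_model

__all__ = [
    "SimexGrid",
    "SimexTrajectory",
    "ExtrapolationFit",
    "pseudo_errors",
    "generate_pseudo_data",
    "run_simex",
    "fit_extrapolant",
    "extrapolate_trajectory",
    "DEFAULT_PSI",
]

# psi grid used in the simulation studies: 0 to 2 in steps of 0.25.
DEFAULT_PSI = (0.0, 0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 1.75, 2.0)

EXTRAPOLANTS = ("linear", "quadratic", "rational_linear")


def _psd_factor(sigma: np.ndarray) -> np.ndarray:
    """Matrix square root of a symmetric PSD matrix (eigen-based, tolerant of
    zero eigenvalues)."""
    sigma = np.atleast_2d(np.asarray(sigma, dtype=float))
    if sigma.shape[0] != sigma.shape[1]:
        raise ValueError("Sigma_e must be square")
    if not np.allclose(sigma, sigma.T, atol=1e-10):
        raise ValueError("Sigma_e must be symmetric")
    vals, vecs = np.linalg.eigh(sigma)
    if vals.min(initial=0.0) < -1e-8 * max(1.0, vals.max(initial=0.0)):
        raise ValueError("Sigma_e must be positive semi-definite")
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


@dataclass(frozen=True)
class SimexGrid:
    """Pseudo-error design: psi grid C, replicate count K, error covariance.

    Parameters
    ----------
    sigma_e : (px, px) symmetric PSD measurement-error covariance.  A scalar
        is interpreted as ``sigma_e * I``.
    psi : ordered grid C = {psi_1, ..., psi_M} with psi_1 = 0.
    K : number of pseudo-error replicates per psi.
    seed : seed for the pseudo-error draws (keyed by (i, k) only).
    psi_scaling : "sqrt" adds sqrt(psi) * e_ik so that the cumulative error
        variance is (1 + psi) * Sigma_e and psi = -1 is error-free (the
        standard SIMEX convention, the default); "linear" adds psi * e_ik.
    """

    sigma_e: np.ndarray
    psi: tuple = DEFAULT_PSI
    K: int = 500
    seed: int | None = None
    psi_scaling: str = "sqrt"

    def __post_init__(self):
        psi = tuple(float(v) for v in self.psi)
        if psi[0] != 0.0:
            raise ValueError("psi grid must start at 0")
        if any(b <= a for a, b in zip(psi, psi[1:])):
            raise ValueError("psi values must be strictly increasing")
        if self.K < 1:
            raise ValueError("K must be a positive integer")
        if self.psi_scaling not in ("sqrt", "linear"):
            raise ValueError("psi_scaling must be 'sqrt' or 'linear'")
        object.__setattr__(self, "psi", psi)
        object.__setattr__(self, "_factor", _psd_factor(self.sigma_e))

    @property
    def M(self) -> int:
        return len(self.psi)

    @property
    def px(self) -> int:
        return self._factor.shape[0]

    def scale(self, psi: float) -> float:
        return math.sqrt(psi) if self.psi_scaling == "sqrt" else psi

    @property
    def is_error_free(self) -> bool:
        return bool(np.all(np.asarray(self.sigma_e) == 0.0))


def pseudo_errors(grid: SimexGrid, n: int) -> np.ndarray:
    """All pseudo-error draws e_ik ~ N(0, Sigma_e), shape (K, n, px).

    Deterministic in (seed, i, k); shared by steps 1-2 and step 5.
    """
    rng = np.random.default_rng(grid.seed)
    z = rng.standard_normal((grid.K, n, grid.px))
    return z @ grid._factor.T


def generate_pseudo_data(
    sample: ObservedSample, grid: SimexGrid, k: int, psi: float, errors=None
) -> np.ndarray:
    """Pseudo-data matrix X*(k, psi) = X* + sqrt(psi) * e_ik.

    ``errors`` may pass a precomputed :func:`pseudo_errors` array to avoid
    regenerating all K draws per call.
    """
    if not 0 <= k < grid.K:
        raise ValueError(f"replicate index k={k} outside [0, {grid.K})")
    if psi not in grid.psi:
        raise ValueError(f"psi={psi} is not on the grid")
    E = pseudo_errors(grid, sample.n) if errors is None else errors
    return sample.Xstar + grid.scale(psi) * E[k]


@dataclass
class SimexTrajectory:
    """The map psi -> gamma_hat(psi) (K-averaged coefficients per psi)."""

    psi: np.ndarray
    gamma: np.ndarray  # (M, 1+p) K-averaged estimates
    gamma_k: np.ndarray | None = None  # (M, K, 1+p) per-replicate fits
    n_dropped: int = 0
    names: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: one row per (component, psi)."""
        ncomp = self.gamma.shape[1]
        comp = self.names or [f"g{j}" for j in range(ncomp)]
        rows = [
            {"component": comp[j], "psi": float(ps), "estimate": self.gamma[m, j]}
            for j in range(ncomp)
            for m, ps in enumerate(self.psi)
        ]
        return pd.DataFrame(rows)


def run_simex(
    sample: ObservedSample,
    spec,
    grid: SimexGrid,
    keep_replicates: bool = False,
) -> SimexTrajectory:
    """Steps 1-2: K-averaged full-model fits on pseudo-data for each psi.

    Fits that fail to converge are dropped from the K-average (with a warning
    if more than 10% are dropped); if every fit at some psi fails a
    RuntimeError identifies the offending psi.
    """
    if grid.px != sample.px:
        raise ValueError(
            f"Sigma_e dimension {grid.px} does not match px={sample.px}"
        )
    q = 1 + sample.p
    names = ["intercept"] + sample.names

    if grid.is_error_free:
        # Sigma_e = 0: every pseudo-data set equals X*, so a single fit gives
        # the whole (constant) trajectory exactly.
        gamma = fit_treatment_model(spec, sample)
        G = np.tile(gamma, (grid.M, 1))
        gk = np.tile(gamma, (grid.M, grid.K, 1)) if keep_replicates else None
        return SimexTrajectory(np.asarray(grid.psi), G, gk, 0, names)

    E = pseudo_errors(grid, sample.n)
    G = np.zeros((grid.M, q))
    gk = np.full((grid.M, grid.K, q), np.nan) if keep_replicates else None
    dropped = 0
    for m, psi in enumerate(grid.psi):
        fits = []
        for k in range(grid.K):
            Xk = sample.Xstar + grid.scale(psi) * E[k]
            try:
                gamma = fit_treatment_model(spec, sample, X_override=Xk)
            except ConvergenceError:
                dropped += 1
                continue
            fits.append(gamma)
            if gk is not None:
                gk[m, k] = gamma
        if not fits:
            raise RuntimeError(f"all {grid.K} treatment-model fits failed at psi={psi}")
        G[m] = np.mean(fits, axis=0)
    if dropped > 0.1 * grid.M * grid.K:
        warnings.warn(
            f"{dropped} of {grid.M * grid.K} pseudo-data fits failed to converge "
            "and were dropped from the K-averages",
            stacklevel=2,
        )
    return SimexTrajectory(np.asarray(grid.psi), G, gk, dropped, names)


@dataclass
class ExtrapolationFit:
    """A fitted extrapolant family and its value at psi = -1."""

    family: str
    coef: np.ndarray
    value_at_minus_one: float
    rss: float

    def __call__(self, psi) -> np.ndarray:
        psi = np.asarray(psi, dtype=float)
        if self.family == "rational_linear":
            a, b, c = self.coef
            return a + b / (c + psi)
        return np.polynomial.polynomial.polyval(psi, self.coef)


def _rational_init(psi: np.ndarray, v: np.ndarray):
    """Exact rational-linear solution through three spread points."""
    i1, i2, i3 = 0, len(psi) // 2, len(psi) - 1
    p1, p2, p3 = psi[i1], psi[i2], psi[i3]
    v1, v2, v3 = v[i1], v[i2], v[i3]
    d23 = v2 - v3
    if d23 == 0 or v1 == v2:
        return None
    r = (v1 - v2) / d23
    denom = r * (p3 - p2) - (p2 - p1)
    if denom == 0:
        return None
    c = ((p2 - p1) * p3 - r * (p3 - p2) * p1) / denom
    if c + p1 == 0 or c + p2 == 0:
        return None
    b = (v1 - v2) * (c + p1) * (c + p2) / (p2 - p1)
    a = v1 - b / (c + p1)
    return np.array([a, b, c])


def fit_extrapolant(psi, values, family: str = "quadratic") -> ExtrapolationFit:
    """Step 3 regression of {(psi, value)} and evaluation at psi = -1.

    linear / quadratic: exact ordinary least squares in psi.
    rational_linear: nonlinear least squares for a + b / (c + psi), seeded by
    the exact solution through three spread grid points; if the fitted pole
    ``-c`` lies inside [-1, psi_M] the fit falls back to quadratic with a
    warning.
    """
    psi = np.asarray(psi, dtype=float)
    v = np.asarray(values, dtype=float)
    if family not in EXTRAPOLANTS:
        raise ValueError(f"unknown extrapolant family {family!r}")
    degree = {"linear": 1, "quadratic": 2, "rational_linear": 2}[family]
    if len(np.unique(psi)) < degree + 1:
        raise ValueError(f"{family} extrapolation needs >= {degree + 1} distinct psi")

    if family in ("linear", "quadratic"):
        coef = np.polynomial.polynomial.polyfit(psi, v, degree)
        pred = np.polynomial.polynomial.polyval(psi, coef)
        val = float(np.polynomial.polynomial.polyval(-1.0, coef))
        return ExtrapolationFit(family, coef, val, float(np.sum((v - pred) ** 2)))

    if np.allclose(v, v[0]):
        coef = np.array([v[0], 0.0, 1.0])
        return ExtrapolationFit(family, coef, float(v[0]), 0.0)
    x0 = _rational_init(psi, v)
    if x0 is None or x0[2] + psi.min() <= 0:
        x0 = np.array([v[-1], (v[0] - v[-1]) * 2.0, 2.0])
    sol = least_squares(
        lambda th: th[0] + th[1] / (th[2] + psi) - v, x0, method="lm", xtol=1e-14
    )
    a, b, c = sol.x
    if c - 1.0 <= 0 or c + psi.min() <= 0:
        warnings.warn(
            "rational-linear extrapolant has a pole inside [-1, psi_M]; "
            "falling back to quadratic",
            stacklevel=2,
        )
        return fit_extrapolant(psi, v, "quadratic")
    pred = a + b / (c + psi)
    return ExtrapolationFit(
        "rational_linear",
        np.array([a, b, c]),
        float(a + b / (c - 1.0)),
        float(np.sum((v - pred) ** 2)),
    )


def extrapolate_trajectory(
    traj: SimexTrajectory, family: str = "quadratic"
) -> np.ndarray:
    """Componentwise extrapolation of gamma_hat(psi) to psi = -1 (step 3)."""
    return np.array(
        [
            fit_extrapolant(traj.psi, traj.gamma[:, j], family).value_at_minus_one
            for j in range(traj.gamma.shape[1])
        ]
    )
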