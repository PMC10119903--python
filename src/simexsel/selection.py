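"""Penalized confounder selection (pipeline step 4).

The extrapolated coefficient vector gamma_tilde is refined by minimizing a
penalized quadratic loss

    l_P(gamma) = 1/2 (gamma - gamma_tilde)' V_n (gamma - gamma_tilde)
                 + n * sum_{j>=1} p'_lambda(|gamma_tilde_j|) |gamma_j|,

a one-step weighted-L1 (adaptive) penalty whose derivative weights come from
the LASSO or SCAD penalty evaluated at the pilot estimate.  The intercept is
never penalized.  The tuning parameter is chosen by a BIC criterion

    BIC(lambda) = 2 l(gamma_hat(lambda)) + 2 log(n) df_lambda,

with df_lambda the number of non-zero components of gamma_hat(lambda).

V_n is user-specified through the weight matrix V with V_n = n * V (the
asymptotic theory requires V_n / n to converge to a positive-definite limit);
the default V = I gives the closed-form componentwise soft-threshold
gamma_hat_j = sign(gamma_tilde_j) (|gamma_tilde_j| - p'_lambda(|gamma_tilde_j|))_+.
For a general positive-definite V the minimizer is found by cyclic coordinate
descent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PenaltySpec",
    "SelectionResult",
    "penalty_derivative_weight",
    "default_lambda_grid",
    "minimize_penalized_loss",
    "bic_score",
    "select",
]

ZERO_TOL = 1e-10  # |gamma_j| below this counts as excluded (df, #S)


@dataclass(frozen=True)
class PenaltySpec:
    """Penalty family, SCAD shape, lambda grid and weight matrix.

    Parameters
    ----------
    kind : {"lasso", "scad"}
    a : SCAD shape parameter (> 2); the conventional value is 3.7.
    lambda_grid : explicit grid; when None a log-spaced grid of ``n_lambda``
        values spanning [1e-4, 1] times max|gamma_tilde_j| is built per call.
    n_lambda : size of the default grid.
    V : positive-definite weight matrix (V_n = n V); None means identity.
    """

    kind: str = "scad"
    a: float = 3.7
    lambda_grid: tuple | None = None
    n_lambda: int = 50
    V: np.ndarray | None = None

    def __post_init__(self):
        if self.kind not in ("lasso", "scad"):
            raise ValueError("penalty kind must be 'lasso' or 'scad'")
        if self.a <= 2:
            raise ValueError("SCAD shape parameter a must exceed 2")
        if self.lambda_grid is not None:
            grid = tuple(float(v) for v in self.lambda_grid)
            if not grid or min(grid) <= 0:
                raise ValueError("lambda grid must be non-empty and positive")
            object.__setattr__(self, "lambda_grid", grid)


def penalty_derivative_weight(kind: str, lam: float, u, a: float = 3.7):
    """First derivative p'_lambda(u) of the penalty at u >= 0.

    LASSO: constant lambda.  SCAD: lambda for u <= lambda, then the linearly
    decaying (a lambda - u)_+ / (a - 1) which vanishes for u >= a lambda —
    large pilot coefficients are left unpenalized (near-unbiasedness).
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("u must be non-negative")
    if kind == "lasso":
        return np.full_like(u, lam)
    if kind == "scad":
        return np.where(u <= lam, lam, np.maximum(a * lam - u, 0.0) / (a - 1.0))
    raise ValueError("penalty kind must be 'lasso' or 'scad'")


def default_lambda_grid(gamma_tilde: np.ndarray, n_lambda: int = 50) -> np.ndarray:
    """Log-spaced grid spanning from shrink-nothing to shrink-everything.

    The effective soft-threshold is p'_lambda(|gamma_tilde_j|); spanning
    [1e-4, 1] times max|gamma_tilde_j| covers both regimes.
    """
    mx = float(np.max(np.abs(gamma_tilde[1:]), initial=0.0))
    if mx == 0:
        return np.array([1e-8])
    return np.geomspace(1e-4 * mx, mx, n_lambda)


def _weights(gamma_tilde: np.ndarray, penalty: PenaltySpec, lam: float) -> np.ndarray:
    w = np.zeros_like(gamma_tilde)
    w[1:] = penalty_derivative_weight(penalty.kind, lam, np.abs(gamma_tilde[1:]), penalty.a)
    return w


def _check_V(V: np.ndarray, q: int) -> np.ndarray:
    V = np.atleast_2d(np.asarray(V, dtype=float))
    if V.shape != (q, q):
        raise ValueError(f"V has shape {V.shape}, expected {(q, q)}")
    if not np.allclose(V, V.T, atol=1e-10):
        raise ValueError("V must be symmetric")
    if np.linalg.eigvalsh(V).min() <= 0:
        raise ValueError("V must be positive definite")
    return V


def _coordinate_descent(gamma_tilde, V, w, tol=1e-9, max_sweeps=10000):
    """Minimize 1/2 (g - gt)' V (g - gt) + sum_j w_j |g_j| (V in per-n units)."""
    q = len(gamma_tilde)
    g = gamma_tilde.copy()
    diag = np.diag(V)
    for _ in range(max_sweeps):
        delta = 0.0
        for j in range(q):
            r = V[j] @ (g - gamma_tilde) - diag[j] * (g[j] - gamma_tilde[j])
            u = gamma_tilde[j] - r / diag[j]
            if w[j] > 0:
                new = np.sign(u) * max(abs(u) - w[j] / diag[j], 0.0)
            else:
                new = u
            delta = max(delta, abs(new - g[j]))
            g[j] = new
        if delta < tol:
            break
    return g


def minimize_penalized_loss(
    gamma_tilde: np.ndarray,
    penalty: PenaltySpec,
    lam: float,
    n: int,
    forced: np.ndarray | None = None,
) -> np.ndarray:
    """argmin of the penalized quadratic loss at a single lambda.

    ``forced`` is a boolean mask (length 1+p) of components whose penalty
    weight is forced to zero (must-include covariates); the intercept is
    always unpenalized.
    """
    gamma_tilde = np.asarray(gamma_tilde, dtype=float)
    w = _weights(gamma_tilde, penalty, lam)
    if forced is not None:
        w[np.asarray(forced, bool)] = 0.0
    if penalty.V is None:
        # V = I: exact componentwise soft-threshold (n cancels from V_n = n I
        # against the n in front of the penalty).
        return np.sign(gamma_tilde) * np.maximum(np.abs(gamma_tilde) - w, 0.0)
    V = _check_V(penalty.V, len(gamma_tilde))
    return _coordinate_descent(gamma_tilde, V, w)


def bic_score(
    gamma_hat: np.ndarray,
    gamma_tilde: np.ndarray,
    n: int,
    V: np.ndarray | None = None,
) -> float:
    """BIC(lambda) = 2 l(gamma_hat) + 2 log(n) df, with l the quadratic loss
    1/2 (gamma_hat - gamma_tilde)' V_n (gamma_hat - gamma_tilde), V_n = n V."""
    d = np.asarray(gamma_hat, dtype=float) - np.asarray(gamma_tilde, dtype=float)
    if d.shape != np.shape(gamma_tilde):
        raise ValueError("gamma_hat and gamma_tilde must be aligned")
    quad = d @ d if V is None else d @ _check_V(V, len(d)) @ d
    df = int(np.sum(np.abs(gamma_hat) > ZERO_TOL))
    return float(n * quad + 2.0 * np.log(n) * df)


@dataclass
class SelectionResult:
    """Selected treatment model: estimate, active set and the BIC path."""

    gamma_hat: np.ndarray
    active: np.ndarray  # bool mask over (intercept, covariates); intercept True
    lambdas: np.ndarray
    path: np.ndarray  # (n_lambda, 1+p)
    df: np.ndarray
    bic: np.ndarray
    lambda_star: float
    names: list[str] = field(default_factory=list)

    @property
    def n_selected(self) -> int:
        """Number of selected covariates (intercept not counted)."""
        return int(np.sum(self.active[1:]))

    def path_frame(self) -> pd.DataFrame:
        cols = self.names or [f"g{j}" for j in range(self.path.shape[1])]
        df = pd.DataFrame(self.path, columns=cols)
        df.insert(0, "bic", self.bic)
        df.insert(0, "df", self.df)
        df.insert(0, "lambda", self.lambdas)
        return df


def select(
    gamma_tilde: np.ndarray,
    penalty: PenaltySpec,
    n: int,
    forced: np.ndarray | None = None,
    names: list[str] | None = None,
) -> SelectionResult:
    """Step 4: solve the penalized loss over the lambda grid and pick the BIC
    minimizer (ties broken toward the larger lambda, i.e. the sparser model)."""
    gamma_tilde = np.asarray(gamma_tilde, dtype=float)
    lams = (
        np.asarray(penalty.lambda_grid, dtype=float)
        if penalty.lambda_grid is not None
        else default_lambda_grid(gamma_tilde, penalty.n_lambda)
    )
    if lams.size == 0:
        raise ValueError("empty lambda grid")
    lams = np.sort(lams)
    path = np.zeros((lams.size, gamma_tilde.size))
    dfs = np.zeros(lams.size, dtype=int)
    bics = np.zeros(lams.size)
    best = None
    for i, lam in enumerate(lams):
        gh = minimize_penalized_loss(gamma_tilde, penalty, lam, n, forced=forced)
        path[i] = gh
        dfs[i] = int(np.sum(np.abs(gh) > ZERO_TOL))
        bics[i] = bic_score(gh, gamma_tilde, n, penalty.V)
        if best is None or bics[i] <= best[0] + 1e-12:
            best = (bics[i], i)
    i_star = best[1]
    gamma_hat = path[i_star].copy()
    active = np.abs(gamma_hat) > ZERO_TOL
    active[0] = True
    return SelectionResult(
        gamma_hat=gamma_hat,
        active=active,
        lambdas=lams,
        path=path,
        df=dfs,
        bic=bics,
        lambda_star=float(lams[i_star]),
        names=list(names) if names else [],
    )
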