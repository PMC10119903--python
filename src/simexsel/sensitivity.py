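"""Measurement-error covariance inputs.

Three ways to obtain Sigma_e for the pipeline:

* supply it directly (``known``);
* estimate it from replicate surrogate measurements by the within-subject
  method of moments (``replicates``);
* construct it from a reliability ratio R = sigma_X / sigma_X* via
  sigma_e_ij = (1/R - 1) * sigma_X_ij, sweeping R over a grid as a
  sensitivity analysis when no external error information exists.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.linalg import block_diag

from .ate import SimexSelectAte
from .data import ObservedSample

__all__ = [
    "sigma_e_from_reliability",
    "sigma_e_from_replicates",
    "estimate_sigma_x",
    "sensitivity_sweep",
]


def _ensure_psd(sigma: np.ndarray, label: str) -> np.ndarray:
    sigma = 0.5 * (sigma + sigma.T)
    vals, vecs = np.linalg.eigh(sigma)
    if vals.min(initial=0.0) < -1e-10 * max(1.0, abs(vals).max(initial=0.0)):
        warnings.warn(
            f"{label} is not PSD; negative eigenvalues clipped to zero", stacklevel=3
        )
        sigma = (vecs * np.clip(vals, 0.0, None)) @ vecs.T
    return sigma


def sigma_e_from_reliability(R, sigma_x: np.ndarray) -> np.ndarray:
    """Error covariance implied by a reliability ratio.

    With R = sigma_X / sigma_X* constant across entries,
    sigma_e_ij = (1/R - 1) * sigma_X_ij; R = 1 means no measurement error and
    R = 0.5 makes the error as large as the signal.  ``R`` may also be a
    matrix of per-entry ratios.
    """
    sigma_x = np.atleast_2d(np.asarray(sigma_x, dtype=float))
    R = np.asarray(R, dtype=float)
    if np.any(R <= 0) or np.any(R > 1):
        raise ValueError("reliability ratio must lie in (0, 1]")
    if R.ndim == 0:
        factor = 1.0 / float(R) - 1.0
        return _ensure_psd(factor * sigma_x, "Sigma_e")
    if R.shape != sigma_x.shape:
        raise ValueError("per-entry R matrix must match Sigma_X's shape")
    return _ensure_psd((1.0 / R - 1.0) * sigma_x, "Sigma_e")


def estimate_sigma_x(Xstar: np.ndarray, shrink: float = 0.9) -> np.ndarray:
    """Proxy for the (unobservable) Sigma_X: a shrink factor times the sample
    covariance of the surrogates (the true covariance is necessarily smaller
    than the surrogate covariance under additive error)."""
    return shrink * np.cov(np.asarray(Xstar, dtype=float), rowvar=False).reshape(
        Xstar.shape[1], Xstar.shape[1]
    )


def _group_mom(table: np.ndarray) -> np.ndarray:
    """Within-subject method-of-moments covariance for one variable group.

    ``table`` has shape (subjects, replicates, vars) or (subjects, replicates)
    for a single variable; NaN marks missing replicates.  Subjects with fewer
    than two observed replicates are dropped with a warning.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    nsub, nrep, nvar = arr.shape
    num = np.zeros((nvar, nvar))
    den = 0.0
    dropped = 0
    for i in range(nsub):
        rows = arr[i]
        ok = ~np.isnan(rows).any(axis=1)
        ri = rows[ok]
        if ri.shape[0] < 2:
            dropped += 1
            continue
        dev = ri - ri.mean(axis=0)
        num += dev.T @ dev
        den += ri.shape[0] - 1
    if den == 0:
        raise ValueError("no subject has two or more replicates")
    if dropped:
        warnings.warn(
            f"{dropped} subject(s) with fewer than two replicates dropped",
            stacklevel=3,
        )
    return num / den


def sigma_e_from_replicates(*groups) -> np.ndarray:
    """Block-diagonal method-of-moments estimate of Sigma_e.

    Each group is a replicate table (subjects x replicates [x vars]) of
    surrogate measurements of one variable or one jointly-measured block;
    within-subject covariances are estimated per group and assembled
    block-diagonally.
    """
    if not groups:
        raise ValueError("at least one replicate table is required")
    blocks = [_group_mom(g) for g in groups]
    return _ensure_psd(block_diag(*blocks), "assembled Sigma_e")


def sensitivity_sweep(
    sample: ObservedSample,
    R_values,
    shrink: float = 0.9,
    n_bootstrap: int = 0,
    **estimator_params,
) -> pd.DataFrame:
    """One full pipeline run per reliability ratio R.

    Sigma_X is taken as ``shrink`` times the sample covariance of X*; for
    each R the implied Sigma_e feeds a fresh :class:`SimexSelectAte` fit.
    R = 1 gives Sigma_e = 0, i.e. the naive (no-correction) analysis.
    Returns a tidy table (R, tau_hat, se, ci_low, ci_high, p_value,
    n_selected, active).
    """
    R_values = list(R_values)
    if any(r <= 0 or r > 1 for r in R_values):
        raise ValueError("all reliability ratios must lie in (0, 1]")
    sigma_x = estimate_sigma_x(sample.Xstar, shrink=shrink)
    rows = []
    for R in R_values:
        est = SimexSelectAte(
            sigma_e=sigma_e_from_reliability(R, sigma_x),
            n_bootstrap=n_bootstrap,
            **estimator_params,
        )
        est.fit(sample)
        active = [n for n, a in zip(sample.names, est.active_[1:]) if a]
        rows.append(
            {
                "R": R,
                "tau_hat": est.tau_hat_,
                "se": getattr(est, "se_", None),
                "ci_low": getattr(est, "ci_", (None, None))[0],
                "ci_high": getattr(est, "ci_", (None, None))[1],
                "p_value": getattr(est, "p_value_", None),
                "n_selected": int(np.sum(est.active_[1:])),
                "active": ",".join(active),
            }
        )
    return pd.DataFrame(rows)
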