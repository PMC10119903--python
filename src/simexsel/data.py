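"""Observed-sample container and CSV I/O.

The estimators in this package consume a single rectangular dataset with one
row per subject: a binary treatment ``T``, an outcome ``Y`` (continuous or
binary), error-prone covariate surrogates ``X*`` and error-free covariates
``Z``.  :class:`ObservedSample` holds these as validated numpy arrays and is
the only data input the pipeline needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["ObservedSample", "read_sample", "standardize"]


@dataclass
class ObservedSample:
    """Per-subject records ``(T, Y, X*, Z)``.

    Parameters
    ----------
    T : (n,) array of 0/1 treatment indicators.
    Y : (n,) array of outcomes.
    Xstar : (n, px) array of observed surrogates for the error-prone
        covariates X.  May have zero columns.
    Z : (n, pz) array of error-free covariates.  May have zero columns.
    x_names, z_names : column labels; generated as ``X1..`` / ``Z1..`` when
        omitted.
    """

    T: np.ndarray
    Y: np.ndarray
    Xstar: np.ndarray
    Z: np.ndarray
    x_names: list[str] = field(default_factory=list)
    z_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float).ravel()
        self.Y = np.asarray(self.Y, dtype=float).ravel()
        n = self.T.shape[0]
        self.Xstar = np.atleast_2d(np.asarray(self.Xstar, dtype=float))
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        if self.Xstar.size == 0:
            self.Xstar = np.empty((n, 0))
        if self.Z.size == 0:
            self.Z = np.empty((n, 0))
        if self.Y.shape[0] != n or self.Xstar.shape[0] != n or self.Z.shape[0] != n:
            raise ValueError("T, Y, Xstar and Z must share the same number of rows")
        if n < 2:
            raise ValueError("need at least two subjects")
        if not np.all(np.isin(self.T, (0.0, 1.0))):
            raise ValueError("T must be binary 0/1")
        if self.T.min() == self.T.max():
            raise ValueError("both treatment arms must be present")
        for name, arr in (("T", self.T), ("Y", self.Y), ("Xstar", self.Xstar), ("Z", self.Z)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains missing or non-finite entries")
        if self.p < 1:
            raise ValueError("need at least one covariate (px + pz >= 1)")
        if not self.x_names:
            self.x_names = [f"X{j + 1}" for j in range(self.px)]
        if not self.z_names:
            self.z_names = [f"Z{j + 1}" for j in range(self.pz)]
        if len(self.x_names) != self.px or len(self.z_names) != self.pz:
            raise ValueError("covariate names do not match matrix shapes")

    @property
    def n(self) -> int:
        return self.T.shape[0]

    @property
    def px(self) -> int:
        return self.Xstar.shape[1]

    @property
    def pz(self) -> int:
        return self.Z.shape[1]

    @property
    def p(self) -> int:
        return self.px + self.pz

    @property
    def names(self) -> list[str]:
        return list(self.x_names) + list(self.z_names)

    def W(self, X_override: np.ndarray | None = None) -> np.ndarray:
        """Covariate matrix ``[X, Z]`` with ``Xstar`` (or an override) in the
        X slot."""
        X = self.Xstar if X_override is None else np.asarray(X_override, dtype=float)
        if X.shape != self.Xstar.shape:
            raise ValueError(
                f"X_override has shape {X.shape}, expected {self.Xstar.shape}"
            )
        return np.hstack([X, self.Z])

    def subset(self, idx: np.ndarray) -> "ObservedSample":
        """Row-subset (used by the bootstrap)."""
        return replace(
            self, T=self.T[idx], Y=self.Y[idx], Xstar=self.Xstar[idx], Z=self.Z[idx]
        )


def standardize(sample: ObservedSample) -> ObservedSample:
    """Center each covariate column at 0 and scale it to unit variance.

    The treatment-model theory assumes standardized covariates; synthetic
    data generated by :mod:`simexsel.synthetic` is already standardized by
    construction and does not need this step.
    """

    def _std(M: np.ndarray) -> np.ndarray:
        if M.shape[1] == 0:
            return M
        sd = M.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("constant covariate column cannot be standardized")
        return (M - M.mean(axis=0)) / sd

    return replace(sample, Xstar=_std(sample.Xstar), Z=_std(sample.Z))


def read_sample(
    path,
    x_cols: list[str] | None = None,
    z_cols: list[str] | None = None,
    t_col: str = "T",
    y_col: str = "Y",
) -> ObservedSample:
    """Read a sample from CSV.

    By default columns named ``X1..Xpx`` are taken as error-prone surrogates
    and ``Z1..Zpz`` as error-free covariates; pass ``x_cols``/``z_cols`` to
    name them explicitly (e.g. from a sidecar config).
    """
    df = pd.read_csv(path)
    if x_cols is None:
        x_cols = sorted(
            (c for c in df.columns if c.startswith("X") and c[1:].isdigit()),
            key=lambda c: int(c[1:]),
        )
    if z_cols is None:
        z_cols = sorted(
            (c for c in df.columns if c.startswith("Z") and c[1:].isdigit()),
            key=lambda c: int(c[1:]),
        )
    return ObservedSample(
        T=df[t_col].to_numpy(),
        Y=df[y_col].to_numpy(),
        Xstar=df[x_cols].to_numpy() if x_cols else np.empty((len(df), 0)),
        Z=df[z_cols].to_numpy() if z_cols else np.empty((len(df), 0)),
        x_names=list(x_cols),
        z_names=list(z_cols),
    )
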