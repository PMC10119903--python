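"""Replicate-level simulation driver and evaluation metrics.

The benchmark re-runs the full pipeline on freshly generated datasets and
summarizes, per method cell:

* coefficient metrics — L1 and L2 estimation losses over all components of
  gamma (intercept included), the number of selected covariates #S and the
  number of falsely excluded important covariates #FN;
* ATE metrics — Bias = mean(tau_hat) - tau_0, empirical S.E. = sd(tau_hat),
  RMSE = sqrt(Bias^2 + S.E.^2) and, when bootstrap CIs are requested, the
  95% coverage rate CR%.

Method cells combine a correction strategy with a selection penalty:
``proposed`` (SIMEX on X*, per extrapolant), ``naive`` (X* treated as exact,
no SIMEX) and ``trueX`` (the error-free X used directly); each with SCAD,
LASSO, or no selection (``full``).  Replicates draw independent seeds from a
single master seed, so results are independent of execution order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ate import bootstrap_se, simex_ate
from .data import ObservedSample
from .selection import ZERO_TOL, PenaltySpec, select
from .simex import DEFAULT_PSI, SimexGrid, extrapolate_trajectory, run_simex
from .synthetic import SimulationDesign, generate_dataset, true_tau

__all__ = ["gamma_metrics", "run_benchmark", "summarize"]

CORRECTIONS = ("proposed", "naive", "trueX")
PENALTIES = ("scad", "lasso", "full")


def gamma_metrics(gamma_hat, gamma_true, zero_tol: float = ZERO_TOL) -> dict:
    """Selection/estimation metrics for one fitted coefficient vector.

    L1 = sum_k |gamma_hat_k - gamma_k| and L2 = sum_k (gamma_hat_k - gamma_k)^2
    run over k = 0..p (intercept included); #S counts non-zero non-intercept
    components of gamma_hat; #FN counts truly non-zero covariates estimated
    as zero.
    """
    gh = np.asarray(gamma_hat, dtype=float)
    gt = np.asarray(gamma_true, dtype=float)
    if gh.shape != gt.shape:
        raise ValueError(f"length mismatch: {gh.shape} vs {gt.shape}")
    d = gh - gt
    sel = np.abs(gh[1:]) > zero_tol
    return {
        "l1": float(np.sum(np.abs(d))),
        "l2": float(np.sum(d * d)),
        "n_selected": int(np.sum(sel)),
        "n_false_negative": int(np.sum(~sel & (gt[1:] != 0.0))),
    }


def _cell_estimate(sample, traj, grid, link, penalty_kind, extrapolant, stabilized):
    """gamma_hat, active mask and tau_hat for one method cell, given the
    (shared) SIMEX trajectory."""
    gamma_tilde = extrapolate_trajectory(traj, extrapolant)
    if penalty_kind == "full":
        gamma_hat = gamma_tilde
        active = np.ones_like(gamma_hat, dtype=bool)
    else:
        res = select(gamma_tilde, PenaltySpec(kind=penalty_kind), sample.n)
        gamma_hat, active = res.gamma_hat, res.active
    ate = simex_ate(
        sample, gamma_hat, active, grid, link=link, family=extrapolant,
        stabilized=stabilized,
    )
    return gamma_hat, active, ate.tau_hat


def run_benchmark(
    design: SimulationDesign,
    corrections=CORRECTIONS,
    penalties=PENALTIES,
    extrapolants=("quadratic",),
    reps: int = 100,
    K: int = 50,
    psi=DEFAULT_PSI,
    seed=None,
    stabilized: bool = True,
    bootstrap_B: int = 0,
    tau0: float | None = None,
    n_mc_tau: int = 5000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the pipeline over ``reps`` replicates of ``design``.

    Returns ``(records, summary)``: one record per (replicate, correction,
    penalty, extrapolant) cell, and the aggregated summary table.  A cell in
    which every replicate fails raises an error naming the cell.
    """
    if reps < 2:
        raise ValueError("need at least two replicates")
    unknown = set(corrections) - set(CORRECTIONS)
    if unknown:
        raise ValueError(f"unknown correction(s): {sorted(unknown)}")
    unknown = set(penalties) - set(PENALTIES)
    if unknown:
        raise ValueError(f"unknown penalty(ies): {sorted(unknown)}")
    if tau0 is None:
        tau0 = true_tau(design, n_mc=n_mc_tau, rng=np.random.default_rng(
            np.random.SeedSequence(seed).generate_state(1)[0] % (2**31)))
    link = design.treatment_link

    children = np.random.SeedSequence(seed).spawn(reps)
    records = []
    for r in range(reps):
        rep_seed = int(children[r].generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(children[r])
        sample, truth = generate_dataset(design, rng=rng)
        zero = np.zeros((sample.px, sample.px))
        samples = {"proposed": sample, "naive": sample}
        if "trueX" in corrections:
            samples["trueX"] = ObservedSample(
                T=sample.T, Y=sample.Y, Xstar=truth.X, Z=sample.Z,
                x_names=sample.x_names, z_names=sample.z_names,
            )
        for corr in corrections:
            sig = design.sigma_e2 * np.eye(sample.px) if corr == "proposed" else zero
            grid = SimexGrid(sigma_e=sig, psi=tuple(psi), K=K, seed=rep_seed)
            fams = extrapolants if corr == "proposed" else ("quadratic",)
            try:
                traj = run_simex(samples[corr], link, grid)
            except Exception as exc:  # noqa: BLE001 - tallied below
                for fam in fams:
                    for pen in penalties:
                        records.append(
                            {"rep": r, "seed": rep_seed, "correction": corr,
                             "penalty": pen, "extrapolant": fam if corr == "proposed" else "-",
                             "failed": True, "error": str(exc)}
                        )
                continue
            for fam in fams:
                for pen in penalties:
                    try:
                        gamma_hat, active, tau = _cell_estimate(
                            samples[corr], traj, grid, link, pen, fam, stabilized
                        )
                    except Exception as exc:  # noqa: BLE001 - tallied below
                        records.append(
                            {"rep": r, "seed": rep_seed, "correction": corr,
                             "penalty": pen, "extrapolant": fam if corr == "proposed" else "-",
                             "failed": True, "error": str(exc)}
                        )
                        continue
                    rec = {
                        "rep": r,
                        "seed": rep_seed,
                        "correction": corr,
                        "penalty": pen,
                        "extrapolant": fam if corr == "proposed" else "-",
                        "tau_hat": tau,
                        "failed": False,
                        **gamma_metrics(gamma_hat, truth.gamma),
                    }
                    if bootstrap_B:
                        from .ate import SimexSelectAte  # local: avoid cycle at import

                        params = SimexSelectAte(
                            sigma_e=sig, link=link, psi_grid=tuple(psi), K=K,
                            extrapolant=fam,
                            penalty=None if pen == "full" else pen,
                            random_state=rep_seed,
                        ).get_params()
                        se, ci, _ = bootstrap_se(
                            samples[corr], params, B=bootstrap_B,
                            random_state=rep_seed, tau_hat=tau,
                        )
                        rec["se_boot"] = se
                        rec["covered"] = bool(ci[0] <= tau0 <= ci[1])
                    records.append(rec)
    records = pd.DataFrame(records)
    for (corr, pen, fam), grp in records.groupby(["correction", "penalty", "extrapolant"]):
        if grp["failed"].all():
            raise RuntimeError(
                f"all replicates failed in cell ({corr}, {pen}, {fam})"
            )
    return records, summarize(records, tau0)


def summarize(records: pd.DataFrame, tau0: float) -> pd.DataFrame:
    """Aggregate per-replicate records into the benchmark summary table."""
    ok = records[~records["failed"]]
    rows = []
    for (corr, pen, fam), grp in ok.groupby(["correction", "penalty", "extrapolant"]):
        bias = float(grp["tau_hat"].mean() - tau0)
        se = float(grp["tau_hat"].std(ddof=1))
        row = {
            "correction": corr,
            "penalty": pen,
            "extrapolant": fam,
            "n_reps": len(grp),
            "L1": float(grp["l1"].mean()),
            "L2": float(grp["l2"].mean()),
            "n_selected": float(grp["n_selected"].mean())
            if pen != "full"
            else float("nan"),
            "n_false_negative": float(grp["n_false_negative"].mean())
            if pen != "full"
            else float("nan"),
            "bias": bias,
            "se": se,
            "rmse": float(np.hypot(bias, se)),
            "cr_pct": float(100.0 * grp["covered"].mean())
            if "covered" in grp
            else float("nan"),
            "tau0": tau0,
        }
        rows.append(row)
    return pd.DataFrame(rows)
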