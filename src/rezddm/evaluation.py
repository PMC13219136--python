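"""Diagnostic-accuracy (ROC/AUC) and parameter-recovery (RMSE, bias) metrics.

A simulation study yields, per replicate, a scalar evidence value for the
effect-size test plus posterior-mean estimates of the generating
parameters. Discrimination between null (beta = 0) and effect (beta != 0)
replicates is summarized by the ROC curve — detection rate against
false-alarm rate as the decision threshold sweeps from maximally
conservative to maximally liberal — and its area (AUC), computed by the
rank (Mann-Whitney) formulation with ties counted one half, which equals
the trapezoidal area under the swept curve.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["CellResult", "RocResult", "roc_auc", "rmse", "bias", "bin_by_truth"]


@dataclass(frozen=True)
class CellResult:
    """One fitted replicate of one design cell of the simulation study."""

    P: int
    T: int
    beta_true: float
    preset: str
    integrity: str       # "clean" or "contaminated"
    method: str          # "standard" or "robust"
    replicate: int
    beta_mean: float     # posterior mean of the effect size
    beta_sd: float
    statistic: float     # decision statistic (evidence for beta != 0)
    mu_nu_true: float
    mu_nu_mean: float    # posterior mean of the drift intercept
    converged: bool

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class RocResult:
    """Threshold-sweep ROC points (monotone from (0,0) to (1,1)) and AUC."""

    far: np.ndarray  # false-alarm rates
    dr: np.ndarray   # detection rates
    auc: float


def roc_auc(null_stats, alt_stats) -> RocResult:
    """ROC curve and AUC discriminating effect replicates from null ones.

    The AUC is the Mann-Whitney probability that a randomly chosen effect
    statistic exceeds a randomly chosen null statistic, ties counted 1/2.
    ``roc_auc(x, x) == 0.5`` exactly for any finite multiset ``x`` (the
    null-against-itself convention used at beta = 0), and the value is
    invariant under any strictly increasing transform of the statistics.
    """
    null_stats = np.asarray(null_stats, dtype=float)
    alt_stats = np.asarray(alt_stats, dtype=float)
    if null_stats.size == 0 or alt_stats.size == 0:
        raise ValueError("both statistic sets must be nonempty")
    if not (np.all(np.isfinite(null_stats)) and np.all(np.isfinite(alt_stats))):
        raise ValueError("non-finite decision statistics")

    n0, n1 = null_stats.size, alt_stats.size
    ranks = rankdata(np.concatenate([null_stats, alt_stats]))  # ties -> average
    u = ranks[n0:].sum() - n1 * (n1 + 1) / 2
    auc = u / (n0 * n1)

    # threshold sweep over the pooled values, conservative -> liberal
    thresholds = np.unique(np.concatenate([null_stats, alt_stats]))[::-1]
    far = np.empty(thresholds.size + 2)
    dr = np.empty(thresholds.size + 2)
    far[0], dr[0] = 0.0, 0.0
    for i, t in enumerate(thresholds, start=1):
        far[i] = np.mean(null_stats >= t)
        dr[i] = np.mean(alt_stats >= t)
    far[-1], dr[-1] = 1.0, 1.0
    return RocResult(far=far, dr=dr, auc=float(auc))


def rmse(estimates, truth) -> float:
    """Root mean squared error of estimates against generating truth."""
    estimates = np.asarray(estimates, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if estimates.shape != truth.shape or estimates.size == 0:
        raise ValueError("estimates and truth must be equal-length, nonempty")
    return float(np.sqrt(np.mean((estimates - truth) ** 2)))


def bias(estimates, truth) -> float:
    """Mean signed error, ``mean(estimate - truth)``: negative = underestimation."""
    estimates = np.asarray(estimates, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if estimates.shape != truth.shape or estimates.size == 0:
        raise ValueError("estimates and truth must be equal-length, nonempty")
    return float(np.mean(estimates - truth))


def bin_by_truth(
    results: list[CellResult] | pd.DataFrame,
    n_bins: int = 5,
    value_range: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Per-bin AUC and bias over equal-width bins of the true drift intercept.

    Effect replicates in each bin are scored against the pooled null
    (beta_true == 0) replicates of the whole batch. Returns one row per bin
    with AUC, bias of the drift-intercept estimate, bias of the effect-size
    estimate, and the replicate count; empty bins appear with NaN metrics
    and ``n = 0`` rather than being fabricated.
    """
    df = results if isinstance(results, pd.DataFrame) else pd.DataFrame(
        [r.to_dict() for r in results]
    )
    if df.empty:
        raise ValueError("no results to bin")
    null_stats = df.loc[df["beta_true"] == 0, "statistic"].to_numpy()
    lo, hi = value_range if value_range is not None else (
        df["mu_nu_true"].min(), df["mu_nu_true"].max()
    )
    edges = np.linspace(lo, hi, n_bins + 1)
    rows = []
    for b in range(n_bins):
        left, right = edges[b], edges[b + 1]
        if b == n_bins - 1:
            mask = (df["mu_nu_true"] >= left) & (df["mu_nu_true"] <= right)
        else:
            mask = (df["mu_nu_true"] >= left) & (df["mu_nu_true"] < right)
        sub = df[mask]
        row = {
            "bin_left": left,
            "bin_right": right,
            "bin_mid": (left + right) / 2,
            "n": int(len(sub)),
            "auc": np.nan,
            "bias_mu_nu": np.nan,
            "bias_beta": np.nan,
        }
        if len(sub):
            row["bias_mu_nu"] = bias(sub["mu_nu_mean"], sub["mu_nu_true"])
            row["bias_beta"] = bias(sub["beta_mean"], sub["beta_true"])
            alt = sub.loc[sub["beta_true"] != 0, "statistic"].to_numpy()
            if alt.size and null_stats.size:
                row["auc"] = roc_auc(null_stats, alt).auc
        rows.append(row)
    return pd.DataFrame(rows)
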