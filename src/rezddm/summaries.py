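"""Per-cell summary statistics: standard (mean/variance) and robust (median/IQR).

The robust scale estimate is

    Var_IQR = ((Q3 - Q1) / 1.349)^2

which is consistent for the variance under normality, since the IQR of a
standard normal is ``2 * Phi^{-1}(0.75) = 1.349...``. Quartiles use linear
interpolation of order statistics ("type 7"), so cells need at least 4
trials. Accuracy is always summarized as the count of correct responses over
all trials of the cell, whichever RT statistics are requested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ddm_core import TrialSet
from .synthetic_data import Dataset

__all__ = [
    "SummaryCell",
    "IQR_NORMAL_DIVISOR",
    "standard_summaries",
    "robust_summaries",
    "summarize_dataset",
    "cells_to_frame",
]

#: Normal-consistency divisor for the IQR: IQR of N(0,1).
IQR_NORMAL_DIVISOR = 1.349

_MIN_CELL = 4


@dataclass(frozen=True)
class SummaryCell:
    """Summary statistics of one participant-condition cell.

    ``n`` counts the trials entering the RT statistics (which depends on the
    rt scope); ``n_total`` is the full trial count of the cell, the binomial
    denominator for ``n_correct``.
    """

    participant: int
    condition: int
    n: int
    n_correct: int
    loc: float    # location statistic, seconds
    scale: float  # variance statistic, seconds^2
    method: str   # "standard" or "robust"
    n_total: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_correct <= self.n_total:
            raise ValueError("n_correct must lie in [0, n_total]")
        if self.scale < 0 or self.loc <= 0:
            raise ValueError("scale must be >= 0 and loc > 0")
        if self.method not in ("standard", "robust"):
            raise ValueError(f"unknown summary method {self.method!r}")


def _check_cell(trials: TrialSet) -> None:
    if len(trials) < _MIN_CELL:
        raise ValueError(
            f"cell has {len(trials)} trials; need >= {_MIN_CELL} for stable "
            "variance/quartile statistics"
        )


def standard_summaries(
    trials: TrialSet, participant: int = 0, condition: int = 0
) -> SummaryCell:
    """Mean RT, unbiased sample variance (n-1), and correct-response count."""
    _check_cell(trials)
    return SummaryCell(
        participant=participant,
        condition=condition,
        n=len(trials),
        n_correct=int(trials.accuracy.sum()),
        loc=float(np.mean(trials.rt)),
        scale=float(np.var(trials.rt, ddof=1)),
        method="standard",
        n_total=len(trials),
    )


def robust_summaries(
    trials: TrialSet, participant: int = 0, condition: int = 0
) -> SummaryCell:
    """Median RT, IQR-based variance estimate, and correct-response count."""
    _check_cell(trials)
    q1, q3 = np.quantile(trials.rt, [0.25, 0.75])  # type-7 interpolation
    return SummaryCell(
        participant=participant,
        condition=condition,
        n=len(trials),
        n_correct=int(trials.accuracy.sum()),
        loc=float(np.median(trials.rt)),
        scale=float(((q3 - q1) / IQR_NORMAL_DIVISOR) ** 2),
        method="robust",
        n_total=len(trials),
    )


def summarize_dataset(
    data: Dataset, method: str = "standard", rt_scope: str = "correct_only"
) -> list[SummaryCell]:
    """One SummaryCell per participant-condition cell of a dataset.

    ``rt_scope`` selects which trials enter the RT statistics:
    ``"correct_only"`` (the classical EZ convention) or ``"all"``.
    ``n_correct``/``n_total`` always cover every trial of the cell.

    Raises if any cell is empty (or smaller than 4 trials) after scoping,
    naming the offending cell.
    """
    if method not in ("standard", "robust"):
        raise ValueError(f"unknown summary method {method!r}")
    if rt_scope not in ("correct_only", "all"):
        raise ValueError(f"unknown rt scope {rt_scope!r}")
    summarize = standard_summaries if method == "standard" else robust_summaries
    cells: list[SummaryCell] = []
    for (p, k), sub in data.df.groupby(["participant", "condition"]):
        rt = sub["rt"].to_numpy()
        acc = sub["accuracy"].to_numpy()
        n_total = len(sub)
        n_correct = int(acc.sum())
        if rt_scope == "correct_only":
            rt = rt[acc == 1]
        if rt.size < _MIN_CELL:
            raise ValueError(
                f"cell (participant={p}, condition={k}) has {rt.size} trials "
                f"after rt_scope={rt_scope!r}; need >= {_MIN_CELL}"
            )
        cell = summarize(TrialSet(rt=rt, accuracy=np.ones(rt.size, dtype=int)), p, k)
        cells.append(
            SummaryCell(
                participant=int(p),
                condition=int(k),
                n=rt.size,
                n_correct=n_correct,
                loc=cell.loc,
                scale=cell.scale,
                method=method,
                n_total=n_total,
            )
        )
    return cells


def cells_to_frame(cells: list[SummaryCell]) -> pd.DataFrame:
    """Tabulate summary cells as a DataFrame (delimited-text friendly)."""
    return pd.DataFrame(
        {
            "participant": [c.participant for c in cells],
            "condition": [c.condition for c in cells],
            "n": [c.n for c in cells],
            "n_correct": [c.n_correct for c in cells],
            "loc": [c.loc for c in cells],
            "scale": [c.scale for c in cells],
            "method": [c.method for c in cells],
            "n_total": [c.n_total for c in cells],
        }
    )
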