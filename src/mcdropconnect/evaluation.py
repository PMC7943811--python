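"""Uncertainty-quality metrics: the four-way correctness x certainty
confusion, the ratios R_cc, R_iu and UA, threshold sweeps with AUC
summaries, and distribution separation between correct and incorrect
predictions.

At a threshold I_T on the normalised uncertainty, predictions split into
certain (I_norm < I_T) and uncertain groups; crossing with correctness gives
the four counts N_cc, N_ic, N_cu, N_iu and

    R_cc = N_cc / (N_cc + N_ic)      P(correct | certain)
    R_iu = N_iu / (N_iu + N_ic)      P(uncertain | incorrect)
    UA   = (N_cc + N_iu) / N         overall uncertainty accuracy

Items exactly at the threshold count as uncertain (the defining inequalities
are strict; assigning ties to "uncertain" is the conservative choice for
safety-critical use).  A 0/0 ratio is undefined and stored as NaN; for the
AUC sweep the undefined head of R_cc and tail of R_iu are filled with 1
(vacuously, no incorrect-certain case exists there) - configurable, and
recorded in the curve metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InvalidInputError, InvalidParameterError, ShapeMismatchError

DEFAULT_GRID = 101  # evenly spaced thresholds on [0, 1]


class ConfusionCounts(NamedTuple):
    n_cc: int
    n_ic: int
    n_cu: int
    n_iu: int

    @property
    def total(self) -> int:
        return self.n_cc + self.n_ic + self.n_cu + self.n_iu


class RatioMetrics(NamedTuple):
    r_cc: float  # NaN when nothing is certain
    r_iu: float  # NaN when nothing is incorrect
    ua: float


def correctness_map(predicted_labels: np.ndarray, true_labels: np.ndarray) -> np.ndarray:
    """Boolean map, true where prediction equals ground truth."""
    pred = np.asarray(predicted_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape:
        raise ShapeMismatchError(f"label shapes differ: {pred.shape} vs {true.shape}")
    return pred == true


def certainty_split(i_norm: np.ndarray, threshold: float) -> np.ndarray:
    """Certain iff I_norm < I_T; ties (== I_T) are classed uncertain."""
    if not (0.0 <= threshold <= 1.0):
        raise InvalidParameterError(f"threshold must lie in [0, 1], got {threshold}")
    u = np.asarray(i_norm, dtype=np.float64)
    if np.any(u < -1e-9) or np.any(u > 1 + 1e-9):
        raise InvalidInputError("normalised uncertainties must lie in [0, 1]")
    return u < threshold


def confusion_counts(correct: np.ndarray, certain: np.ndarray) -> ConfusionCounts:
    correct = np.asarray(correct, dtype=bool).ravel()
    certain = np.asarray(certain, dtype=bool).ravel()
    if correct.shape != certain.shape:
        raise ShapeMismatchError(f"length mismatch: {correct.shape} vs {certain.shape}")
    return ConfusionCounts(
        n_cc=int(np.sum(correct & certain)),
        n_ic=int(np.sum(~correct & certain)),
        n_cu=int(np.sum(correct & ~certain)),
        n_iu=int(np.sum(~correct & ~certain)),
    )


def ratio_metrics(counts: ConfusionCounts) -> RatioMetrics:
    counts = ConfusionCounts(*counts)
    if any(c < 0 for c in counts):
        raise InvalidInputError("counts must be nonnegative")
    n = counts.total
    if n == 0:
        raise InvalidInputError("all counts are zero")
    cert = counts.n_cc + counts.n_ic
    inc = counts.n_iu + counts.n_ic
    return RatioMetrics(
        r_cc=counts.n_cc / cert if cert else float("nan"),
        r_iu=counts.n_iu / inc if inc else float("nan"),
        ua=(counts.n_cc + counts.n_iu) / n,
    )


@dataclass
class ThresholdEvaluation:
    """Counts and ratios at one uncertainty threshold."""

    threshold: float
    counts: ConfusionCounts
    ratios: RatioMetrics

    @classmethod
    def at(cls, i_norm, correct, threshold) -> "ThresholdEvaluation":
        counts = confusion_counts(correct, certainty_split(i_norm, threshold))
        return cls(threshold=float(threshold), counts=counts, ratios=ratio_metrics(counts))


@dataclass
class MetricCurve:
    """One metric over an ascending threshold grid plus its AUC (percent).

    Undefined (0/0) points are NaN in ``values``; ``fill_value`` is what the
    AUC integration substituted for them.
    """

    name: str
    thresholds: np.ndarray
    values: np.ndarray
    auc_percent: float
    fill_value: float = 1.0


@dataclass
class UncertaintyCurves:
    """R_cc, R_iu and UA swept over a threshold grid."""

    table: pd.DataFrame
    curves: dict = field(default_factory=dict)

    @property
    def auc(self) -> dict:
        return {name: c.auc_percent for name, c in self.curves.items()}


def auc_percent(thresholds: np.ndarray, values: np.ndarray, fill: float) -> float:
    v = np.where(np.isnan(values), fill, values)
    span = thresholds[-1] - thresholds[0]
    return float(np.trapezoid(v, thresholds) / span * 100.0)


def metric_curves(i_norm: np.ndarray, correct: np.ndarray,
                  thresholds: Optional[Sequence[float]] = None,
                  fill_r_cc: float = 1.0, fill_r_iu: float = 1.0) -> UncertaintyCurves:
    """Evaluate the confusion and all three ratios at every grid threshold.

    The default grid is 101 evenly spaced points on [0, 1]; a custom grid
    must be strictly increasing from 0 to 1.
    """
    if thresholds is None:
        grid = np.linspace(0.0, 1.0, DEFAULT_GRID)
    else:
        grid = np.asarray(thresholds, dtype=np.float64)
        if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
            raise InvalidParameterError("threshold grid must be strictly increasing")
        if grid[0] != 0.0 or grid[-1] != 1.0:
            raise InvalidParameterError("threshold grid must cover [0, 1]")
    correct = np.asarray(correct, dtype=bool).ravel()
    u = np.asarray(i_norm, dtype=np.float64).ravel()
    if u.shape != correct.shape:
        raise ShapeMismatchError("i_norm and correctness lengths differ")
    # vectorised sweep: counts of certain items via sorted uncertainties
    order = np.argsort(u, kind="stable")
    u_sorted = u[order]
    corr_sorted = correct[order].astype(np.int64)
    cum_correct = np.concatenate([[0], np.cumsum(corr_sorted)])
    n = u.size
    n_correct = int(correct.sum())
    rows = []
    for tau in grid:
        k = int(np.searchsorted(u_sorted, tau, side="left"))  # certain: u < tau
        n_cc = int(cum_correct[k])
        n_ic = k - n_cc
        n_cu = n_correct - n_cc
        n_iu = (n - n_correct) - n_ic
        counts = ConfusionCounts(n_cc, n_ic, n_cu, n_iu)
        r = ratio_metrics(counts)
        rows.append((tau, *counts, r.r_cc, r.r_iu, r.ua))
    table = pd.DataFrame(rows, columns=["threshold", "n_cc", "n_ic", "n_cu", "n_iu",
                                        "r_cc", "r_iu", "ua"])
    curves = {
        "r_cc": MetricCurve("r_cc", grid, table["r_cc"].to_numpy(),
                            auc_percent(grid, table["r_cc"].to_numpy(), fill_r_cc), fill_r_cc),
        "r_iu": MetricCurve("r_iu", grid, table["r_iu"].to_numpy(),
                            auc_percent(grid, table["r_iu"].to_numpy(), fill_r_iu), fill_r_iu),
        "ua": MetricCurve("ua", grid, table["ua"].to_numpy(),
                          auc_percent(grid, table["ua"].to_numpy(), 0.0), 0.0),
    }
    return UncertaintyCurves(table=table, curves=curves)


def ks_separation(i_norm_correct: np.ndarray, i_norm_incorrect: np.ndarray):
    """Two-sample Kolmogorov-Smirnov D and asymptotic p between the
    uncertainty distributions of correct and incorrect predictions."""
    a = np.asarray(i_norm_correct, dtype=np.float64).ravel()
    b = np.asarray(i_norm_incorrect, dtype=np.float64).ravel()
    if a.size == 0 or b.size == 0:
        raise InvalidInputError("both groups must be nonempty for the KS test")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)
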