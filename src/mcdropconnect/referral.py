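"""Uncertainty-informed referral (selective prediction).

Predictions are sorted by epistemic uncertainty; rejecting the most
uncertain items to a fallback (e.g. a human expert) and scoring accuracy on
the retained set yields accuracy as a function of the tolerated uncertainty
or of the retained-data fraction.  A random-rejection baseline (same
retained sizes, no use of uncertainty) quantifies the informativeness of the
uncertainty signal; it is reported as mean +/- std over repeated samplings
(default 20).

Referral operates on I_norm by default; any strictly monotone transform of
the uncertainty (e.g. raw mutual information) gives identical
retained-fraction curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .evaluation import certainty_split, confusion_counts, ratio_metrics
from .exceptions import InvalidInputError, InvalidParameterError

DEFAULT_FRACTIONS = 20  # evenly spaced retained fractions in (0, 1]
DEFAULT_REPETITIONS = 20  # random-baseline samplings


@dataclass
class ReferralCurve:
    """Accuracy over retained items along a tolerance or fraction grid.

    ``accuracy`` is NaN where nothing is retained.
    """

    mode: str  # "by_tolerance" | "by_retained_fraction"
    x: np.ndarray
    accuracy: np.ndarray
    n_retained: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({self.mode: self.x, "accuracy": self.accuracy,
                             "n_retained": self.n_retained})

    def plot(self, baseline: Optional[pd.DataFrame] = None, path=None):
        """Accuracy vs. tolerance / retained fraction, optionally with the
        random-rejection baseline band (mean +/- std)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(self.x, self.accuracy, marker="o", ms=3, label="uncertainty-informed")
        if baseline is not None:
            ax.plot(baseline["fraction"], baseline["accuracy_mean"], color="k",
                    label="random rejection")
            ax.fill_between(baseline["fraction"],
                            baseline["accuracy_mean"] - baseline["accuracy_std"],
                            baseline["accuracy_mean"] + baseline["accuracy_std"],
                            color="k", alpha=0.2)
        ax.set_xlabel("tolerated uncertainty" if self.mode == "by_tolerance"
                      else "retained fraction")
        ax.set_ylabel("accuracy")
        ax.legend(loc="lower left", fontsize=8)
        fig.tight_layout()
        if path:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


def _as_vectors(i_norm, correct):
    u = np.asarray(i_norm, dtype=np.float64).ravel()
    c = np.asarray(correct, dtype=bool).ravel()
    if u.shape != c.shape:
        raise InvalidInputError("uncertainty and correctness lengths differ")
    if u.size == 0:
        raise InvalidInputError("empty evaluation set")
    return u, c


def referral_by_tolerance(i_norm, correct,
                          tolerance_grid: Optional[Sequence[float]] = None) -> ReferralCurve:
    """Accuracy over items whose uncertainty does not exceed the tolerance tau
    (retained: i_norm <= tau)."""
    u, c = _as_vectors(i_norm, correct)
    grid = (np.linspace(0.0, 1.0, DEFAULT_FRACTIONS + 1) if tolerance_grid is None
            else np.asarray(tolerance_grid, dtype=np.float64))
    acc = np.full(grid.size, np.nan)
    n_ret = np.zeros(grid.size, dtype=np.int64)
    for k, tau in enumerate(grid):
        keep = u <= tau
        n_ret[k] = int(keep.sum())
        if n_ret[k]:
            acc[k] = float(c[keep].mean())
    return ReferralCurve("by_tolerance", grid, acc, n_ret)


def retained_count(fraction: float, n: int) -> int:
    """ceil(f * N) items are retained at fraction f."""
    return int(np.ceil(fraction * n - 1e-12))


def referral_by_fraction(i_norm, correct,
                         fraction_grid: Optional[Sequence[float]] = None) -> ReferralCurve:
    """Retain the ceil(f*N) items with smallest uncertainty (stable order on
    ties) and score accuracy on them."""
    u, c = _as_vectors(i_norm, correct)
    grid = (np.linspace(1.0 / DEFAULT_FRACTIONS, 1.0, DEFAULT_FRACTIONS)
            if fraction_grid is None else np.asarray(fraction_grid, dtype=np.float64))
    if np.any(grid <= 0) or np.any(grid > 1):
        raise InvalidParameterError("retained fractions must lie in (0, 1]")
    order = np.argsort(u, kind="stable")
    c_sorted = c[order].astype(np.int64)
    cum = np.concatenate([[0], np.cumsum(c_sorted)])
    acc = np.full(grid.size, np.nan)
    n_ret = np.zeros(grid.size, dtype=np.int64)
    for k, f in enumerate(grid):
        m = retained_count(f, u.size)
        n_ret[k] = m
        if m:
            acc[k] = cum[m] / m
    return ReferralCurve("by_retained_fraction", grid, acc, n_ret)


def random_rejection_baseline(correct, fraction_grid: Optional[Sequence[float]] = None,
                              repetitions: int = DEFAULT_REPETITIONS,
                              seed: int = 0) -> pd.DataFrame:
    """Accuracy of uniformly random retained subsets of the same sizes,
    aggregated as mean +/- std over the repetitions."""
    if repetitions < 2:
        raise InvalidParameterError(f"repetitions must be >= 2, got {repetitions}")
    c = np.asarray(correct, dtype=bool).ravel()
    if c.size == 0:
        raise InvalidInputError("empty evaluation set")
    grid = (np.linspace(1.0 / DEFAULT_FRACTIONS, 1.0, DEFAULT_FRACTIONS)
            if fraction_grid is None else np.asarray(fraction_grid, dtype=np.float64))
    if np.any(grid <= 0) or np.any(grid > 1):
        raise InvalidParameterError("retained fractions must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    accs = np.empty((repetitions, grid.size))
    for r in range(repetitions):
        for k, f in enumerate(grid):
            m = retained_count(f, c.size)
            keep = rng.choice(c.size, size=m, replace=False)
            accs[r, k] = float(c[keep].mean())
    return pd.DataFrame({"fraction": grid,
                         "accuracy_mean": accs.mean(axis=0),
                         "accuracy_std": accs.std(axis=0, ddof=0)})


def _ua_objective(counts) -> float:
    return ratio_metrics(counts).ua


_OBJECTIVES: dict = {"ua": _ua_objective,
                     "r_cc": lambda c: ratio_metrics(c).r_cc,
                     "r_iu": lambda c: ratio_metrics(c).r_iu}


def select_operating_threshold(i_norm, correct,
                               objective: Union[str, Callable] = "ua",
                               grid: Optional[Sequence[float]] = None) -> float:
    """Grid-search the threshold maximising the objective (default UA) on a
    validation set; the result is frozen for test use.

    Ties: the midpoint of the first contiguous plateau of grid maxima is
    returned, so a perfectly separable validation set yields the middle of
    the optimal band.
    """
    u, c = _as_vectors(i_norm, correct)
    fn = _OBJECTIVES[objective] if isinstance(objective, str) else objective
    grid = np.linspace(0.0, 1.0, 101) if grid is None else np.asarray(grid, dtype=np.float64)
    vals = np.empty(grid.size)
    for k, tau in enumerate(grid):
        v = fn(confusion_counts(c, certainty_split(u, tau)))
        vals[k] = -np.inf if np.isnan(v) else v
    best = vals.max()
    at_best = np.isclose(vals, best, rtol=0, atol=1e-12)
    start = int(np.argmax(at_best))
    end = start
    while end + 1 < grid.size and at_best[end + 1]:
        end += 1
    return float((grid[start] + grid[end]) / 2.0)
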