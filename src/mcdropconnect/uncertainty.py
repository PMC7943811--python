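"""Per-item epistemic uncertainty from MC samples.

Predictive entropy of the MC-mean distribution captures total predictive
uncertainty,

    H_hat(x) = - sum_c p_MC(c|x) log p_MC(c|x),

while the mutual information between the prediction and the weights,

    I_hat(x) = H_hat(x) - (1/T) sum_t H(p(.|x, w_t)),

isolates the epistemic part: it is zero when every stochastic pass agrees
(however flat the shared distribution, i.e. pure aleatoric noise) and grows
with disagreement among passes.  Because the raw scale of I depends on the
data set, architecture and T, downstream metrics operate on the min-max
normalised I_norm in [0, 1].

Natural log is the default base; I_norm is invariant to the base.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .exceptions import InvalidInputError

_EPS = 1e-12


def _log(p: np.ndarray, base: Optional[float]) -> np.ndarray:
    out = np.log(np.clip(p, _EPS, None))
    if base is not None:
        out = out / np.log(base)
    return out


def _check_probs(p: np.ndarray, tol: float = 1e-6):
    if np.any(p < -tol):
        raise InvalidInputError("probability entries must be nonnegative")
    if np.any(np.abs(p.sum(axis=-1) - 1.0) > tol):
        raise InvalidInputError("probability rows must sum to 1")


def predictive_entropy(mean_probs: np.ndarray, base: Optional[float] = None) -> np.ndarray:
    """Entropy -sum p log p (0 log 0 := 0) of the MC-mean distribution.

    Accepts a single C-vector or any (..., C) stack; returns a scalar or the
    matching leading shape.
    """
    p = np.asarray(mean_probs, dtype=np.float64)
    _check_probs(p)
    h = -np.sum(np.where(p > 0, p * _log(p, base), 0.0), axis=-1)
    return h if h.ndim else float(h)


def expected_sample_entropy(samples: np.ndarray, base: Optional[float] = None) -> np.ndarray:
    """(1/T) sum_t H(sample_t): the aleatoric component of the entropy."""
    s = np.asarray(samples, dtype=np.float64)
    h_t = -np.sum(np.where(s > 0, s * _log(s, base), 0.0), axis=-1)
    return h_t.mean(axis=0)


def mutual_information(samples: np.ndarray, base: Optional[float] = None) -> np.ndarray:
    """Epistemic uncertainty of one item (T x C) or a batch (T x N x C).

    Clamped to >= 0 (floating point can yield tiny negatives of order 1e-16).
    """
    s = np.asarray(samples, dtype=np.float64)
    if s.ndim < 2 or s.shape[0] < 1:
        raise InvalidInputError("need a (T, ..., C) array with T >= 1")
    _check_probs(s)
    mean = s.mean(axis=0)
    h_mean = -np.sum(np.where(mean > 0, mean * _log(mean, base), 0.0), axis=-1)
    mi = h_mean - expected_sample_entropy(s, base)
    mi = np.maximum(mi, 0.0)
    return mi if np.ndim(mi) else float(mi)


def classwise_variance(samples: np.ndarray) -> np.ndarray:
    """Per-class population variance of the T softmax samples (the alternative
    uncertainty measure of Kendall-style pipelines; not the default here)."""
    s = np.asarray(samples, dtype=np.float64)
    if s.ndim < 2 or s.shape[0] < 2:
        raise InvalidInputError("classwise variance needs T >= 2 samples")
    return s.var(axis=0, ddof=0)


def normalize_uncertainty(raw: np.ndarray, bounds: Optional[tuple] = None):
    """Min-max scale raw mutual information onto [0, 1].

    By default I_min/I_max are taken over the provided set itself.  Passing
    ``bounds=(i_min, i_max)`` applies a frozen normaliser from a reference set
    (values outside the range are clipped), which is what the referral
    workflow needs when a validation-set threshold is applied to test data.

    Returns ``(i_norm, i_min, i_max)``.
    """
    r = np.asarray(raw, dtype=np.float64)
    if r.size == 0:
        raise InvalidInputError("cannot normalise an empty uncertainty set")
    if np.any(r < -_EPS):
        raise InvalidInputError("raw mutual information must be nonnegative")
    if bounds is None:
        i_min, i_max = float(r.min()), float(r.max())
    else:
        i_min, i_max = map(float, bounds)
    if i_max > i_min:
        i_norm = np.clip((r - i_min) / (i_max - i_min), 0.0, 1.0)
    else:
        i_norm = np.zeros_like(r)
    return i_norm, i_min, i_max


@dataclass
class UncertaintyResult:
    """Per-item uncertainty summaries over one evaluation set."""

    entropy: np.ndarray
    mutual_info: np.ndarray
    i_norm: np.ndarray
    i_min: float
    i_max: float

    @classmethod
    def from_samples(cls, samples: np.ndarray, bounds: Optional[tuple] = None,
                     base: Optional[float] = None) -> "UncertaintyResult":
        """Compute all measures from a (T, N, C) sample tensor (accepts an
        MCPredictionSet via its ``samples`` attribute as well)."""
        s = getattr(samples, "samples", samples)
        s = np.asarray(s, dtype=np.float64)
        mean = s.mean(axis=0)
        mean = mean / mean.sum(axis=-1, keepdims=True)
        ent = np.atleast_1d(predictive_entropy(mean, base))
        mi = np.atleast_1d(mutual_information(s, base))
        i_norm, i_min, i_max = normalize_uncertainty(mi, bounds=bounds)
        return cls(entropy=ent, mutual_info=mi, i_norm=i_norm, i_min=i_min, i_max=i_max)
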