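"""Monte Carlo posterior predictive: T stochastic forward passes and their
aggregation, plus the convergence-in-T analysis.

The predictive distribution is approximated by keeping the Bernoulli masks
active at test time and averaging ``T`` stochastic softmax outputs,

    p_MC(y | x) = (1/T) sum_t p(y | x, w_t),   w_t ~ q(w),

whose argmax is the network prediction.  Samples are stored in full
(T x N x C) because the mutual-information measure needs per-sample
entropies; a streaming accumulator of (sum p, sum p*log p) is provided as an
equivalent alternative for large N.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError, InvalidParameterError
from .nn import NS_MC, Network

DEFAULT_T = 100  # stochastic forward passes used for model averaging


@dataclass
class MCPredictionSet:
    """T stochastic softmax sample tensors per item.

    ``samples`` has shape (T, N, C).  For segmentation, N enumerates pixels in
    row-major order and ``spatial_shape`` records ``(n_images, H, W)``.
    """

    samples: np.ndarray
    item_ids: Optional[Sequence] = None
    spatial_shape: Optional[tuple] = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 3:
            raise InvalidInputError(f"samples must be (T, N, C), got shape {self.samples.shape}")
        if self.samples.shape[0] < 1:
            raise InvalidInputError("need T >= 1 samples")
        self.validate()

    def validate(self, tol: float = 1e-6):
        if np.any(self.samples < -tol):
            raise InvalidInputError("negative probabilities in MC samples")
        sums = self.samples.sum(axis=-1)
        if np.any(np.abs(sums - 1.0) > tol):
            raise InvalidInputError("MC sample rows must sum to 1")

    @property
    def T(self) -> int:
        return self.samples.shape[0]

    @property
    def n_items(self) -> int:
        return self.samples.shape[1]

    @property
    def n_classes(self) -> int:
        return self.samples.shape[2]

    # -- persistence: compressed array container + text manifest -----------
    def save(self, path, manifest: Optional[dict] = None):
        np.savez_compressed(path, samples=self.samples,
                            spatial_shape=np.array(self.spatial_shape or ()))
        meta = dict(manifest or {})
        meta.update(T=self.T, n_items=self.n_items, n_classes=self.n_classes)
        meta["samples_sha256"] = hashlib.sha256(self.samples.tobytes()).hexdigest()
        with open(str(path) + ".manifest.json", "w") as fh:
            json.dump(meta, fh, indent=2)

    @classmethod
    def load(cls, path) -> "MCPredictionSet":
        with np.load(path) as data:
            shape = tuple(int(v) for v in data["spatial_shape"])
            return cls(samples=data["samples"], spatial_shape=shape or None)


def _proba_samples(net: Network, x: np.ndarray, masks) -> np.ndarray:
    p = net.predict_proba(x, masks=masks)
    if p.ndim == 4:  # segmentation: flatten pixels
        p = p.reshape(-1, p.shape[-1])
    return p


def mc_predict(net: Network, x: np.ndarray, T: int = DEFAULT_T, seed: int = 0,
               start_index: int = 0) -> MCPredictionSet:
    """Run T stochastic forward passes with fresh masks per pass.

    Mask draw ``t`` uses draw index ``start_index + t``, so a run of T=a
    followed by one with ``start_index=a`` of T=b reproduces the first a and
    next b draws of a single T=a+b run.
    """
    if T < 1:
        raise InvalidParameterError(f"T must be >= 1, got {T}")
    x = np.asarray(x, dtype=np.float64)
    spatial = None
    if not net.stochastic_indices:
        warnings.warn("model has no stochastic layers; MC samples are identical",
                      stacklevel=2)
    out = []
    for t in range(T):
        masks = net.sample_masks(seed, NS_MC, start_index + t) if net.stochastic_indices else None
        out.append(_proba_samples(net, x, masks))
    p0 = net.forward(x)
    if p0.ndim == 4:
        spatial = (x.shape[0], p0.shape[1], p0.shape[2])
    return MCPredictionSet(samples=np.stack(out), spatial_shape=spatial)


def predictive_mean(mcset: MCPredictionSet) -> np.ndarray:
    """Elementwise mean over the T samples; rows remain probability vectors."""
    mean = mcset.samples.mean(axis=0)
    return mean / mean.sum(axis=-1, keepdims=True)


def predicted_labels(mean_probs: np.ndarray) -> np.ndarray:
    """Argmax class per item; ties break to the lowest class index."""
    return np.argmax(mean_probs, axis=-1)


def deterministic_predict(net: Network, x: np.ndarray) -> np.ndarray:
    """Single pass with all-ones masks (scale 1): the standard non-Bayesian test."""
    p = net.predict_proba(np.asarray(x, dtype=np.float64))
    if p.ndim == 4:
        p = p.reshape(-1, p.shape[-1])
    return p


class StreamingMC:
    """Accumulates (sum p, sum p log p) over passes; equivalent to storing all
    samples for the mean and mutual-information computations."""

    def __init__(self):
        self.T = 0
        self._sum_p = None
        self._sum_plogp = None

    def update(self, probs: np.ndarray):
        plogp = probs * np.log(np.clip(probs, 1e-12, None))
        if self._sum_p is None:
            self._sum_p = probs.astype(np.float64).copy()
            self._sum_plogp = plogp
        else:
            self._sum_p += probs
            self._sum_plogp += plogp
        self.T += 1

    @property
    def mean(self) -> np.ndarray:
        return self._sum_p / self.T

    def mutual_information(self) -> np.ndarray:
        mean = self.mean
        h_mean = -np.sum(mean * np.log(np.clip(mean, 1e-12, None)), axis=-1)
        h_exp = -np.sum(self._sum_plogp / self.T, axis=-1)
        return np.maximum(h_mean - h_exp, 0.0)


def convergence_curve(net: Network, x: np.ndarray, labels: np.ndarray,
                      T_grid: Sequence[int], repetitions: int = 10,
                      seed: int = 0) -> pd.DataFrame:
    """Prediction error of the MC average as a function of T.

    For each T in the ascending grid, the error of ``argmax(predictive_mean)``
    against ``labels`` is recorded as mean +/- std over independent
    repetitions (default 10).  The returned frame carries two summary
    statistics in ``.attrs``: the smallest T whose mean error falls below the
    deterministic baseline, and the smallest T whose mean error is within one
    standard deviation (at the best T) of the best mean error.
    """
    T_grid = list(T_grid)
    if not T_grid:
        raise InvalidParameterError("T_grid must be nonempty")
    if any(b <= a for a, b in zip(T_grid, T_grid[1:])):
        raise InvalidParameterError("T_grid must be strictly ascending")
    if repetitions < 2:
        raise InvalidParameterError(f"repetitions must be >= 2, got {repetitions}")
    labels = np.asarray(labels).reshape(-1)
    t_max = T_grid[-1]
    errors = np.empty((repetitions, len(T_grid)))
    for r in range(repetitions):
        acc = None
        done = 0
        for k, t in enumerate(T_grid):
            block = mc_predict(net, x, T=t - done, seed=seed, start_index=r * t_max + done)
            s = block.samples.sum(axis=0)
            acc = s if acc is None else acc + s
            done = t
            pred = predicted_labels(acc / done)
            errors[r, k] = float(np.mean(pred != labels))
    det_error = float(np.mean(predicted_labels(deterministic_predict(net, x)) != labels))
    mean_err = errors.mean(axis=0)
    std_err = errors.std(axis=0, ddof=0)
    df = pd.DataFrame({"T": T_grid, "error_mean": mean_err, "error_std": std_err})
    below = [t for t, e in zip(T_grid, mean_err) if e < det_error]
    best_k = int(np.argmin(mean_err))
    within = [t for t, e in zip(T_grid, mean_err)
              if e <= mean_err[best_k] + std_err[best_k]]
    df.attrs["baseline_error"] = det_error
    df.attrs["smallest_T_below_baseline"] = below[0] if below else None
    df.attrs["smallest_T_within_one_std_of_best"] = within[0] if within else None
    df.attrs["best_T"] = T_grid[best_k]
    return df
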