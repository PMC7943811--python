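"""Bernoulli-masked layer primitives.

Two mask granularities are supported:

* ``weight`` (DropConnect): one Bernoulli variate per entry of the variational
  weight matrix Theta, so the layer computes ``a = sigma((Z (*) Theta) v)``.
* ``unit`` (Dropout baseline): one variate per output unit, masking the
  pre-activations, ``a = sigma(z (*) (Theta v))``.

Biases follow the convention of being folded into the weight matrix as a final
row with a fixed input of one, so by default they are masked like any other
weight (configurable).  Keeping the masks active at prediction time is what
turns the fitted network into an approximate Bayesian posterior sampler.

With ``scale_by_inverse_p`` (the default) kept weights are rescaled by ``1/p``
so the deterministic all-ones pass (with scale 1) equals the expected
stochastic activation; switching it off gives the literal unscaled
parameterisation, whose expectation is ``p * Theta v``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np

from . import convops
from .exceptions import InvalidParameterError, ShapeMismatchError

__all__ = ["StochasticLayerSpec", "MaskDraw", "sample_mask", "stochastic_forward"]

_KINDS = ("affine", "convolution")
_MODES = ("weight", "unit")


def _entropy(stream: Union[int, Sequence[int]]) -> tuple[int, ...]:
    if isinstance(stream, (int, np.integer)):
        stream = (int(stream),)
    ent = tuple(int(s) for s in stream)
    if any(s < 0 for s in ent):
        raise InvalidParameterError(f"seed stream entries must be nonnegative, got {ent}")
    return ent


@dataclass
class StochasticLayerSpec:
    """Variational description of one Bernoulli-masked layer.

    ``theta`` always has shape ``(fan_in + 1, fan_out)`` with the bias as the
    last row.  For ``kind='convolution'`` the input rows are im2col patches of
    size ``kernel_size**2 * in_channels`` and ``fan_out`` is the number of
    output channels.
    """

    kind: str
    theta: np.ndarray
    keep_prob: float = 0.5
    mask_mode: str = "weight"
    scale_by_inverse_p: bool = True
    mask_bias: bool = True
    seed_stream: Union[int, Sequence[int]] = 0
    kernel_size: int = 1
    in_channels: int = 1

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise InvalidParameterError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.mask_mode not in _MODES:
            raise InvalidParameterError(f"mask_mode must be one of {_MODES}, got {self.mask_mode!r}")
        if not (0.0 < self.keep_prob <= 1.0):
            raise InvalidParameterError(f"keep_prob must lie in (0, 1], got {self.keep_prob}")
        self.theta = np.asarray(self.theta, dtype=np.float64)
        if self.theta.ndim != 2:
            raise ShapeMismatchError(f"theta must be 2-D (fan_in+1, fan_out), got {self.theta.shape}")
        if self.kind == "convolution":
            expect = self.kernel_size * self.kernel_size * self.in_channels + 1
            if self.theta.shape[0] != expect:
                raise ShapeMismatchError(
                    f"convolution theta has {self.theta.shape[0]} rows, expected "
                    f"{expect} for kernel_size={self.kernel_size}, in_channels={self.in_channels}"
                )

    @property
    def fan_in(self) -> int:
        return self.theta.shape[0] - 1

    @property
    def fan_out(self) -> int:
        return self.theta.shape[1]

    @property
    def scale(self) -> float:
        return 1.0 / self.keep_prob if self.scale_by_inverse_p else 1.0

    def mask_shape(self) -> tuple[int, ...]:
        if self.mask_mode == "weight":
            return self.theta.shape
        return (self.fan_out,)


@dataclass
class MaskDraw:
    """One realisation of the binary mask Z for a layer."""

    z: np.ndarray
    draw_seed: tuple = field(default=())

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=np.float64)
        vals = np.unique(self.z)
        if not np.all(np.isin(vals, (0.0, 1.0))):
            raise InvalidParameterError("mask entries must be binary")


def sample_mask(spec: StochasticLayerSpec, draw_index: int) -> MaskDraw:
    """Draw the Bernoulli mask for one forward pass.

    Deterministic given ``(spec.seed_stream, draw_index)``: the RNG is rebuilt
    from that pair, so the same draw index always reproduces the same mask.
    """
    if draw_index < 0:
        raise InvalidParameterError(f"draw_index must be nonnegative, got {draw_index}")
    ent = _entropy(spec.seed_stream) + (int(draw_index),)
    rng = np.random.default_rng(ent)
    z = (rng.random(spec.mask_shape()) < spec.keep_prob).astype(np.float64)
    if spec.mask_mode == "weight" and not spec.mask_bias:
        z[-1, :] = 1.0
    return MaskDraw(z=z, draw_seed=ent)


def deterministic_mask(spec: StochasticLayerSpec) -> MaskDraw:
    """The all-ones mask used for the standard (non-Bayesian) test pass."""
    return MaskDraw(z=np.ones(spec.mask_shape()), draw_seed=())


def _augment(x: np.ndarray) -> np.ndarray:
    return np.concatenate([x, np.ones((*x.shape[:-1], 1), dtype=x.dtype)], axis=-1)


def masked_affine(
    theta: np.ndarray,
    x1: np.ndarray,
    mask: np.ndarray,
    mask_mode: str,
    scale: float,
) -> np.ndarray:
    """Affine map with mask applied at weight or unit granularity.

    ``x1`` already carries the fixed bias input of one as its last column.
    """
    if mask_mode == "weight":
        return x1 @ (theta * mask * scale)
    return (x1 @ theta) * (mask * scale)


def stochastic_forward(
    spec: StochasticLayerSpec,
    x: np.ndarray,
    mask: MaskDraw,
    activation: Optional[Callable[[np.ndarray], np.ndarray]] = None,
) -> np.ndarray:
    """Apply one masked forward pass of the layer described by ``spec``.

    ``scale`` is the deterministic all-ones convention: pass
    ``mask=deterministic_mask(spec)`` together with a spec whose
    ``scale_by_inverse_p`` handling is wanted; the all-ones mask with scale 1
    is obtained through :func:`deterministic_mask` plus ``keep_prob=1``.
    """
    x = np.asarray(x, dtype=np.float64)
    if mask.z.shape != spec.mask_shape():
        raise ShapeMismatchError(
            f"mask shape {mask.z.shape} does not match spec mask shape {spec.mask_shape()}"
        )
    if spec.kind == "affine":
        squeeze = x.ndim == 1
        if squeeze:
            x = x[None, :]
        if x.shape[-1] != spec.fan_in:
            raise ShapeMismatchError(f"input has {x.shape[-1]} features, layer expects {spec.fan_in}")
        out = masked_affine(spec.theta, _augment(x), mask.z, spec.mask_mode, spec.scale)
        if squeeze:
            out = out[0]
    else:
        if x.ndim != 4 or x.shape[-1] != spec.in_channels:
            raise ShapeMismatchError(
                f"convolution expects (N, H, W, {spec.in_channels}) input, got {x.shape}"
            )
        n, h, w, _ = x.shape
        cols = convops.im2col(x, spec.kernel_size).reshape(n * h * w, spec.fan_in)
        out = masked_affine(spec.theta, _augment(cols), mask.z, spec.mask_mode, spec.scale)
        out = out.reshape(n, h, w, spec.fan_out)
    if activation is not None:
        out = activation(out)
    return out
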