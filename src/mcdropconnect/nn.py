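"""Miniature neural networks with Bernoulli-masked weights, plus their trainer.

Every parametric layer keeps its parameters in a single matrix ``theta`` of
shape ``(fan_in + 1, fan_out)`` whose last row is the bias (fixed input of
one), so weight-level masks cover biases too.  Convolutions are affine maps
over im2col patches; see :mod:`mcdropconnect.convops`.

Training minimises

    (1/N) sum_n CE(y_n, yhat(x_n, w_hat_n)) + lambda * sum_i ||Theta_i||^2

by minibatch SGD with momentum, drawing a fresh Bernoulli mask configuration
for every step, which is the Monte Carlo estimate of the negative evidence
lower bound under the Bernoulli variational posterior (the prior KL term
reducing to the L2 penalty).

All randomness flows from one root seed split into named streams (parameter
init, per-step training masks, test-time MC masks, shuffling, data), so runs
are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import convops
from .exceptions import (
    InvalidParameterError,
    ShapeMismatchError,
    TrainingDivergenceError,
)
from .masking import MaskDraw, StochasticLayerSpec, sample_mask

# named RNG stream ids (combined with the root seed and layer index)
NS_INIT, NS_TRAIN, NS_MC, NS_SHUFFLE, NS_DATA = 1, 2, 3, 4, 5


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. the logits.

    ``logits`` may be (N, C) or (N, H, W, C) with labels of matching leading
    shape (segmentation is pixel-wise classification).
    """
    flat = logits.reshape(-1, logits.shape[-1])
    y = np.asarray(labels).reshape(-1)
    if y.shape[0] != flat.shape[0]:
        raise ShapeMismatchError("labels do not match logits leading shape")
    m = flat.shape[0]
    z = flat - flat.max(axis=-1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=-1, keepdims=True))
    loss = -np.mean(logp[np.arange(m), y])
    dlogits = np.exp(logp)
    dlogits[np.arange(m), y] -= 1.0
    dlogits /= m
    return loss, dlogits.reshape(logits.shape)


class Layer:
    trainable = False
    stochastic = False

    def forward(self, x, mask: Optional[MaskDraw] = None, train: bool = False):
        raise NotImplementedError

    def backward(self, d):
        raise NotImplementedError

    def config(self) -> dict:
        return {"type": type(self).__name__}


class _MaskedAffineLayer(Layer):
    """Shared masked-affine machinery for dense and convolutional layers."""

    trainable = True
    stochastic = True

    def __init__(self, fan_in, fan_out, keep_prob, mask_mode, scale_by_inverse_p, mask_bias):
        if not (0.0 < keep_prob <= 1.0):
            raise InvalidParameterError(f"keep_prob must lie in (0, 1], got {keep_prob}")
        self.fan_in = int(fan_in)
        self.fan_out = int(fan_out)
        self.keep_prob = float(keep_prob)
        self.mask_mode = mask_mode
        self.scale_by_inverse_p = bool(scale_by_inverse_p)
        self.mask_bias = bool(mask_bias)
        self.theta = np.zeros((self.fan_in + 1, self.fan_out))
        self.grad_theta = None
        self._cache = None

    # -- spec bridge -------------------------------------------------------
    def spec(self, seed_stream=0) -> StochasticLayerSpec:
        kw = {}
        if isinstance(self, Conv2dDC):
            kw = {"kind": "convolution", "kernel_size": self.kernel_size, "in_channels": self.in_channels}
        else:
            kw = {"kind": "affine"}
        s = StochasticLayerSpec(
            theta=self.theta,
            keep_prob=self.keep_prob,
            mask_mode=self.mask_mode,
            scale_by_inverse_p=self.scale_by_inverse_p,
            mask_bias=self.mask_bias,
            seed_stream=seed_stream,
            **kw,
        )
        s.theta = self.theta  # share storage; spec construction copies via asarray only if needed
        return s

    def init_params(self, rng: np.random.Generator):
        self.theta = np.zeros((self.fan_in + 1, self.fan_out))
        self.theta[:-1, :] = rng.normal(0.0, np.sqrt(2.0 / self.fan_in), size=(self.fan_in, self.fan_out))

    @property
    def scale(self) -> float:
        return 1.0 / self.keep_prob if self.scale_by_inverse_p else 1.0

    def _effective(self, mask: Optional[MaskDraw]):
        """(weight matrix, unit multiplier) for this pass."""
        if mask is None:  # deterministic pass: all-ones mask, scale 1
            return self.theta, None
        if self.mask_mode == "weight":
            z = mask.z
            if not self.mask_bias:
                z = z.copy()
                z[-1, :] = 1.0
            return self.theta * z * self.scale, None
        return self.theta, mask.z * self.scale

    def _affine(self, x1, mask, train):
        w_eff, unit = self._effective(mask)
        out = x1 @ w_eff
        if unit is not None:
            out = out * unit
        if train:
            self._cache = (x1, mask)
        return out

    def _affine_backward(self, d):
        x1, mask = self._cache
        w_eff, unit = self._effective(mask)
        if unit is not None:
            d = d * unit
        self.grad_theta = x1.T @ d
        if mask is not None and self.mask_mode == "weight":
            z = mask.z
            if not self.mask_bias:
                z = z.copy()
                z[-1, :] = 1.0
            self.grad_theta = self.grad_theta * z * self.scale
            dx1 = d @ (w_eff).T
        else:
            dx1 = d @ self.theta.T
        return dx1[..., :-1]


class DenseDC(_MaskedAffineLayer):
    """Fully connected Bernoulli-masked layer."""

    def __init__(self, fan_in, fan_out, keep_prob=0.5, mask_mode="weight",
                 scale_by_inverse_p=True, mask_bias=True):
        super().__init__(fan_in, fan_out, keep_prob, mask_mode, scale_by_inverse_p, mask_bias)

    def forward(self, x, mask=None, train=False):
        if x.shape[-1] != self.fan_in:
            raise ShapeMismatchError(f"input has {x.shape[-1]} features, expected {self.fan_in}")
        x1 = np.concatenate([x, np.ones((*x.shape[:-1], 1))], axis=-1)
        return self._affine(x1, mask, train)

    def backward(self, d):
        return self._affine_backward(d)

    def config(self):
        return {"type": "DenseDC", "fan_in": self.fan_in, "fan_out": self.fan_out,
                "keep_prob": self.keep_prob, "mask_mode": self.mask_mode,
                "scale_by_inverse_p": self.scale_by_inverse_p, "mask_bias": self.mask_bias}


class Conv2dDC(_MaskedAffineLayer):
    """Stride-1 same-padded convolution with weight-level (or output-channel) masks."""

    def __init__(self, in_channels, out_channels, kernel_size=3, keep_prob=0.5,
                 mask_mode="weight", scale_by_inverse_p=True, mask_bias=True):
        self.in_channels = int(in_channels)
        self.kernel_size = int(kernel_size)
        super().__init__(kernel_size * kernel_size * in_channels, out_channels,
                         keep_prob, mask_mode, scale_by_inverse_p, mask_bias)

    def forward(self, x, mask=None, train=False):
        n, h, w, c = x.shape
        if c != self.in_channels:
            raise ShapeMismatchError(f"input has {c} channels, expected {self.in_channels}")
        cols = convops.im2col(x, self.kernel_size).reshape(n * h * w, self.fan_in)
        x1 = np.concatenate([cols, np.ones((cols.shape[0], 1))], axis=-1)
        out = self._affine(x1, mask, train)
        if train:
            self._shape = (n, h, w)
        return out.reshape(n, h, w, self.fan_out)

    def backward(self, d):
        n, h, w = self._shape
        dcols = self._affine_backward(d.reshape(n * h * w, self.fan_out))
        return convops.col2im(dcols.reshape(n, h, w, self.fan_in), self.kernel_size, self.in_channels)

    def config(self):
        return {"type": "Conv2dDC", "in_channels": self.in_channels, "out_channels": self.fan_out,
                "kernel_size": self.kernel_size, "keep_prob": self.keep_prob,
                "mask_mode": self.mask_mode, "scale_by_inverse_p": self.scale_by_inverse_p,
                "mask_bias": self.mask_bias}


class ReLU(Layer):
    def forward(self, x, mask=None, train=False):
        if train:
            self._pos = x > 0
        return np.maximum(x, 0.0)

    def backward(self, d):
        return d * self._pos


class MaxPool2(Layer):
    def forward(self, x, mask=None, train=False):
        out, onehot = convops.maxpool2(x)
        if train:
            self._onehot = onehot
        return out

    def backward(self, d):
        return convops.maxpool2_backward(d, self._onehot)


class Upsample2(Layer):
    def forward(self, x, mask=None, train=False):
        return convops.upsample2(x)

    def backward(self, d):
        return convops.upsample2_backward(d)


class Flatten(Layer):
    def forward(self, x, mask=None, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, d):
        return d.reshape(self._shape)


_LAYER_TYPES = {c.__name__: c for c in (DenseDC, Conv2dDC, ReLU, MaxPool2, Upsample2, Flatten)}


class Network:
    """A plain feed-forward stack of layers ending in class logits."""

    def __init__(self, layers, seed: int = 0):
        self.layers = list(layers)
        self.seed = int(seed)
        self.init_params(seed)

    # -- parameters --------------------------------------------------------
    @property
    def stochastic_indices(self):
        return [i for i, l in enumerate(self.layers) if l.stochastic]

    @property
    def trainable_layers(self):
        return [l for l in self.layers if l.trainable]

    def n_params(self) -> int:
        return int(sum(l.theta.size for l in self.trainable_layers))

    def init_params(self, seed: int):
        for i, layer in enumerate(self.layers):
            if layer.trainable:
                layer.init_params(np.random.default_rng((int(seed), NS_INIT, i)))

    def set_keep_prob(self, keep_prob: float):
        for l in self.layers:
            if l.stochastic:
                if not (0.0 < keep_prob <= 1.0):
                    raise InvalidParameterError(f"keep_prob must lie in (0, 1], got {keep_prob}")
                l.keep_prob = float(keep_prob)

    # -- masks -------------------------------------------------------------
    def sample_masks(self, seed: int, namespace: int, draw_index: int) -> dict:
        """One fresh mask per stochastic layer, shared across the batch."""
        masks = {}
        for i in self.stochastic_indices:
            spec = self.layers[i].spec(seed_stream=(int(seed), int(namespace), i))
            masks[i] = sample_mask(spec, draw_index)
        return masks

    # -- passes ------------------------------------------------------------
    def forward(self, x, masks: Optional[dict] = None, train: bool = False) -> np.ndarray:
        h = np.asarray(x, dtype=np.float64)
        for i, layer in enumerate(self.layers):
            m = masks.get(i) if (masks is not None and layer.stochastic) else None
            h = layer.forward(h, mask=m, train=train)
        return h

    def predict_proba(self, x, masks: Optional[dict] = None) -> np.ndarray:
        return softmax(self.forward(x, masks=masks))

    def loss_and_grads(self, x, y, masks, weight_decay: float = 0.0):
        """Objective value (data CE + L2 penalty) and per-layer gradients."""
        logits = self.forward(x, masks=masks, train=True)
        data_loss, dlogits = softmax_cross_entropy(logits, y)
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)
        reg = 0.0
        grads = []
        for layer in self.trainable_layers:
            g = layer.grad_theta
            if weight_decay:
                reg += weight_decay * float(np.sum(layer.theta**2))
                g = g + 2.0 * weight_decay * layer.theta
            grads.append(g)
        return data_loss + reg, grads

    # -- persistence -------------------------------------------------------
    def save(self, path):
        arrays = {f"theta_{i}": l.theta for i, l in enumerate(self.trainable_layers)}
        arch = json.dumps({"seed": self.seed, "layers": [l.config() for l in self.layers]})
        np.savez_compressed(path, arch=np.frombuffer(arch.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "Network":
        with np.load(path) as data:
            arch = json.loads(bytes(data["arch"]).decode())
            layers = []
            for cfg in arch["layers"]:
                cfg = dict(cfg)
                layers.append(_LAYER_TYPES[cfg.pop("type")](**cfg))
            net = cls.__new__(cls)
            net.layers = layers
            net.seed = arch["seed"]
            for i, l in enumerate(net.trainable_layers):
                l.theta = data[f"theta_{i}"]
        return net


@dataclass
class TrainingConfig:
    """Hyperparameters of the Bernoulli-variational training objective."""

    keep_prob: Optional[float] = None  # None: keep each layer's own rate
    weight_decay: float = 1e-4
    epochs: int = 30
    learning_rate: float = 0.02
    batch_size: int = 64
    momentum: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if self.weight_decay < 0:
            raise InvalidParameterError(f"weight_decay must be >= 0, got {self.weight_decay}")
        if self.keep_prob is not None and not (0.0 < self.keep_prob <= 1.0):
            raise InvalidParameterError(f"keep_prob must lie in (0, 1], got {self.keep_prob}")


def train_model(net: Network, x: np.ndarray, y: np.ndarray, config: TrainingConfig):
    """SGD with momentum on the masked cross-entropy + L2 objective.

    A fresh mask configuration is drawn per optimisation step (the
    single-sample Monte Carlo estimate of the expected log likelihood).
    Returns ``(net, loss_trace)`` with one objective value per step.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y)
    if config.keep_prob is not None:
        net.set_keep_prob(config.keep_prob)
    shuffle_rng = np.random.default_rng((config.seed, NS_SHUFFLE))
    velocity = [np.zeros_like(l.theta) for l in net.trainable_layers]
    trace: list[float] = []
    step = 0
    n = x.shape[0]
    for _epoch in range(config.epochs):
        perm = shuffle_rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            masks = net.sample_masks(config.seed, NS_TRAIN, step)
            loss, grads = net.loss_and_grads(x[idx], y[idx], masks, config.weight_decay)
            if not np.isfinite(loss):
                raise TrainingDivergenceError(
                    f"loss became non-finite at step {step}", loss_trace=trace
                )
            for v, g, layer in zip(velocity, grads, net.trainable_layers):
                v *= config.momentum
                v -= config.learning_rate * g
                layer.theta += v
            trace.append(float(loss))
            step += 1
    return net, trace
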