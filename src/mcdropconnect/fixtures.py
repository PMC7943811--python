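"""Synthetic tasks and miniature reference models.

The classification task is a mixture of Gaussian class blobs whose overlap
is set so that a nontrivial Bayes error (roughly 10-20% at the defaults)
guarantees misclassifications to evaluate uncertainty against, plus
out-of-distribution probe points placed far outside every class - the desk
equivalent of testing a digit classifier on distorted out-of-distribution
digits.  The segmentation task renders toy scenes (disk, rectangle, one
deliberately rare small object on a dominant background) with pixel noise
and boundary jitter, emulating the class-frequency imbalance and ambiguous
object boundaries of street-scene or organ-segmentation data.

The miniatures mirror the full-scale architectures the method targets: an
MLP, a small fully-convolutional classifier of three blocks with two
convolutional layers each, and an encoder-decoder segmenter - every weight
layer Bernoulli-masked, with weight-level (DropConnect) and unit-level
(Dropout baseline) variants sharing identical architectures and parameter
counts.

What these generators do NOT emulate: natural-image texture, label noise,
class hierarchies, or covariate shift subtler than the far-OOD probes; a
passing behavioural suite shows the machinery orders its own uncertainties
correctly, not that any particular clinical data set would behave alike.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .exceptions import InvalidParameterError
from .nn import (
    NS_DATA,
    Conv2dDC,
    DenseDC,
    Flatten,
    MaxPool2,
    Network,
    ReLU,
    TrainingConfig,
    Upsample2,
    train_model,
)

__all__ = [
    "BlobTaskSpec", "ToySegSpec", "TrainingConfig", "generate_blob_task",
    "generate_toy_segmentation", "tiny_mlp", "small_cnn", "tiny_segmenter",
    "reference_models", "train_model", "bayes_error",
]


def _default_means() -> np.ndarray:
    # class means on orthogonal axes of an 8-dimensional space, pairwise
    # distance 2.8 with unit-variance blobs (Bayes error ~ 14%).  The ambient
    # dimension keeps the decision boundaries in sparsely sampled territory,
    # so the model's epistemic uncertainty remains informative about errors;
    # a low-dimensional densely covered task would make almost all residual
    # error aleatoric, which mutual information deliberately ignores.
    c = 2.8 / np.sqrt(2.0)
    means = np.zeros((3, 8))
    np.fill_diagonal(means[:, :3], c)
    return means


@dataclass
class BlobTaskSpec:
    """Gaussian-blob classification task with OOD probes."""

    n_classes: int = 3
    n_samples: int = 2000
    means: Optional[np.ndarray] = None  # (n_classes, dim); default: triangle, dim 2
    covariances: Optional[Sequence] = None  # per class: scalar variance or (dim, dim) PSD
    ood_offset: float = 2.0  # probe radius as multiple of the in-distribution extent
    n_ood: int = 100
    seed: int = 0

    def resolved_means(self) -> np.ndarray:
        m = _default_means() if self.means is None else np.asarray(self.means, dtype=np.float64)
        if m.ndim != 2 or m.shape[0] != self.n_classes:
            raise InvalidParameterError("means must be (n_classes, dim)")
        return m

    def resolved_covs(self) -> list:
        dim = self.resolved_means().shape[1]
        covs = self.covariances
        if covs is None:
            covs = [1.0] * self.n_classes
        out = []
        for c in covs:
            c = np.asarray(c, dtype=np.float64)
            if c.ndim == 0:
                if c < 0:
                    raise InvalidParameterError("variance must be >= 0")
                c = float(c) * np.eye(dim)
            if c.shape != (dim, dim) or not np.allclose(c, c.T):
                raise InvalidParameterError("covariance must be symmetric (dim, dim)")
            ev = np.linalg.eigvalsh(c)
            if ev.min() < -1e-10:
                raise InvalidParameterError("covariance must be positive semidefinite")
            out.append(c)
        if len(out) != self.n_classes:
            raise InvalidParameterError("one covariance per class required")
        return out


def generate_blob_task(spec: BlobTaskSpec):
    """Sample the blob task.

    Returns ``(features, labels, ood_probes)``; class counts are balanced to
    within one sample, and every probe lies farther from every class mean
    than the 99th percentile of in-distribution distances to that mean.
    """
    means = spec.resolved_means()
    covs = spec.resolved_covs()
    dim = means.shape[1]
    rng = np.random.default_rng((spec.seed, NS_DATA))
    counts = [spec.n_samples // spec.n_classes] * spec.n_classes
    for k in range(spec.n_samples % spec.n_classes):
        counts[k] += 1
    xs, ys = [], []
    for k in range(spec.n_classes):
        xs.append(rng.multivariate_normal(means[k], covs[k], size=counts[k],
                                          method="eigh"))
        ys.append(np.full(counts[k], k, dtype=np.int64))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    perm = rng.permutation(x.shape[0])
    x, y = x[perm], y[perm]

    # probes on a sphere far outside every class
    d99 = np.array([np.percentile(np.linalg.norm(x - means[k], axis=1), 99)
                    for k in range(spec.n_classes)])
    radius = spec.ood_offset * float(np.max(np.linalg.norm(means, axis=1) + d99))
    dirs = rng.normal(size=(spec.n_ood, dim))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    ood = radius * dirs
    return x, y, ood


def bayes_error(spec: BlobTaskSpec, n_mc: int = 200_000, seed: int = 12345) -> float:
    """Bayes error of the blob mixture, by Monte Carlo integration of the true
    class densities (the generator's difficulty oracle)."""
    from scipy.stats import multivariate_normal

    means = spec.resolved_means()
    covs = spec.resolved_covs()
    rng = np.random.default_rng(seed)
    per = n_mc // spec.n_classes
    err = 0
    total = 0
    jitter = 1e-9 * np.eye(means.shape[1])
    dists = [multivariate_normal(means[k], covs[k] + jitter, allow_singular=True)
             for k in range(spec.n_classes)]
    for k in range(spec.n_classes):
        pts = rng.multivariate_normal(means[k], covs[k], size=per, method="eigh")
        dens = np.stack([d.pdf(pts) for d in dists], axis=1)
        err += int(np.sum(np.argmax(dens, axis=1) != k))
        total += per
    return err / total


@dataclass
class ToySegSpec:
    """Toy segmentation scenes: background + disk + rectangle + rare object."""

    image_size: int = 24
    n_images: int = 24
    noise_sd: float = 0.25
    boundary_jitter: int = 1  # +/- pixels of random size perturbation
    disk_radius: int = 5
    rect_size: tuple = (8, 6)
    rare_size: int = 3  # 3x3 square => 9/576 ~ 1.6% of pixels, < 2% by construction
    intensities: tuple = (0.1, 0.45, 0.7, 0.95)  # background, disk, rect, rare
    seed: int = 0

    N_CLASSES = 4

    def validate(self):
        s = self.image_size
        if 2 * (self.disk_radius + self.boundary_jitter) + 2 > s:
            raise InvalidParameterError("disk does not fit in the image")
        if max(self.rect_size) + 2 * self.boundary_jitter + 2 > s or self.rare_size + 2 > s:
            raise InvalidParameterError("shape larger than image")
        if self.rare_size**2 / s**2 >= 0.02:
            raise InvalidParameterError("rare object must occupy < 2% of pixels")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")


def generate_toy_segmentation(spec: ToySegSpec):
    """Render scenes and their ground-truth label maps.

    Returns ``(images, labels)`` with images (N, H, W, 1) float and labels
    (N, H, W) int in {0..3}.  Boundary jitter perturbs the shape sizes before
    rendering, so image and mask stay consistent by construction.
    """
    spec.validate()
    s = spec.image_size
    rng = np.random.default_rng((spec.seed, NS_DATA))
    yy, xx = np.mgrid[0:s, 0:s]
    images = np.empty((spec.n_images, s, s, 1))
    labels = np.empty((spec.n_images, s, s), dtype=np.int64)
    for n in range(spec.n_images):
        lab = np.zeros((s, s), dtype=np.int64)
        j = spec.boundary_jitter
        # disk (class 1)
        r = spec.disk_radius + (rng.integers(-j, j + 1) if j else 0)
        margin = r + 1
        cy, cx = rng.integers(margin, s - margin, size=2)
        lab[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = 1
        # rectangle (class 2), may occlude the disk
        rh = spec.rect_size[0] + (rng.integers(-j, j + 1) if j else 0)
        rw = spec.rect_size[1] + (rng.integers(-j, j + 1) if j else 0)
        ty = rng.integers(1, s - rh - 1)
        tx = rng.integers(1, s - rw - 1)
        lab[ty : ty + rh, tx : tx + rw] = 2
        # rare small square (class 3), fixed size to keep its pixel share < 2%
        k = spec.rare_size
        ry = rng.integers(1, s - k - 1)
        rx = rng.integers(1, s - k - 1)
        lab[ry : ry + k, rx : rx + k] = 3
        img = np.asarray(spec.intensities, dtype=np.float64)[lab]
        img = img + rng.normal(0.0, spec.noise_sd, size=(s, s))
        images[n, :, :, 0] = img
        labels[n] = lab
    return images, labels


# ---------------------------------------------------------------------------
# reference miniatures
# ---------------------------------------------------------------------------

def _mask_kw(keep_prob, mask_mode, scale_by_inverse_p):
    return dict(keep_prob=keep_prob, mask_mode=mask_mode,
                scale_by_inverse_p=scale_by_inverse_p)


def tiny_mlp(n_features: int = 8, n_classes: int = 3, hidden: Sequence[int] = (64, 64),
             keep_prob: float = 0.5, mask_mode: str = "weight",
             scale_by_inverse_p: bool = True, seed: int = 0) -> Network:
    """Fully connected classifier with every weight layer stochastic."""
    kw = _mask_kw(keep_prob, mask_mode, scale_by_inverse_p)
    layers = []
    fan = n_features
    for h in hidden:
        layers += [DenseDC(fan, h, **kw), ReLU()]
        fan = h
    layers.append(DenseDC(fan, n_classes, **kw))
    return Network(layers, seed=seed)


def small_cnn(input_shape=(16, 16, 1), n_classes: int = 3, filters=(8, 16, 32),
              keep_prob: float = 0.5, mask_mode: str = "weight",
              scale_by_inverse_p: bool = True, seed: int = 0) -> Network:
    """Fully convolutional classifier: three blocks of two 3x3 convolutions
    each followed by 2x2 max pooling, then a dense softmax head."""
    kw = _mask_kw(keep_prob, mask_mode, scale_by_inverse_p)
    h, w, c = input_shape
    layers = []
    cin = c
    for f in filters:
        layers += [Conv2dDC(cin, f, 3, **kw), ReLU(),
                   Conv2dDC(f, f, 3, **kw), ReLU(), MaxPool2()]
        cin = f
        h, w = h // 2, w // 2
    layers += [Flatten(), DenseDC(h * w * cin, n_classes, **kw)]
    return Network(layers, seed=seed)


def tiny_segmenter(in_channels: int = 1, n_classes: int = 4, base: int = 8,
                   keep_prob: float = 0.5, mask_mode: str = "weight",
                   scale_by_inverse_p: bool = True, stochastic: str = "central",
                   seed: int = 0) -> Network:
    """Encoder-decoder segmenter: two convolutions, pool, bottleneck
    convolution, upsample, two convolutions to per-pixel logits.

    ``stochastic`` places the Bernoulli masks: ``"central"`` (default) masks
    the bottleneck and the first decoder convolution only, the placement used
    for Bayesian encoder-decoder segmenters (masking every layer of so small
    a network regularises it into the dominant background class); ``"all"``
    masks every weight layer.
    """
    if stochastic not in ("central", "all"):
        raise InvalidParameterError("stochastic must be 'central' or 'all'")
    kw = _mask_kw(keep_prob, mask_mode, scale_by_inverse_p)
    det = _mask_kw(1.0, mask_mode, scale_by_inverse_p) if stochastic == "central" else kw
    layers = [
        Conv2dDC(in_channels, base, 3, **det), ReLU(),
        Conv2dDC(base, base, 3, **det), ReLU(),
        MaxPool2(),
        Conv2dDC(base, 2 * base, 3, **kw), ReLU(),
        Upsample2(),
        Conv2dDC(2 * base, base, 3, **kw), ReLU(),
        Conv2dDC(base, n_classes, 3, **det),
    ]
    return Network(layers, seed=seed)


def reference_models(keep_prob: float = 0.5, mask_mode: str = "weight",
                     seed: int = 0) -> dict:
    """The three miniatures under a common masking configuration."""
    return {
        "mlp": tiny_mlp(keep_prob=keep_prob, mask_mode=mask_mode, seed=seed),
        "cnn": small_cnn(keep_prob=keep_prob, mask_mode=mask_mode, seed=seed),
        "segmenter": tiny_segmenter(keep_prob=keep_prob, mask_mode=mask_mode, seed=seed),
    }
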