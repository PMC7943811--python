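"""Segmentation scoring and map rendering.

Prediction quality follows the standard confusion-matrix metrics for
semantic segmentation (with n_ij the count of class-i pixels predicted as
class j, t_i the row sum, and C' the number of classes present in the
ground truth):

    pixel accuracy = sum_i n_ii / sum_i t_i
    mean accuracy  = (1/C') sum_i n_ii / t_i
    mean IoU       = (1/C') sum_i n_ii / (t_i + sum_j n_ji - n_ii)

Pixels carrying the ignore label (void class, default 255) are excluded from
every count.  Confidence-percentile accuracy scores the most certain pixels
only (Table-style confidence sweeps), and the map renderer produces the
binary correctness / confidence images (white = correct / certain, gray =
ignored).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
from PIL import Image

from .exceptions import InvalidInputError, InvalidParameterError, ShapeMismatchError

IGNORE_LABEL = 255


class SegmentationScores(NamedTuple):
    pixel_accuracy: float
    mean_accuracy: float
    mean_iou: float


@dataclass
class SegmentationBatch:
    """Predicted and true label maps (any matching shape), optional ignore mask."""

    predicted: np.ndarray
    true: np.ndarray
    n_classes: int
    ignore: Optional[np.ndarray] = None  # True where the pixel is excluded

    def __post_init__(self):
        self.predicted = np.asarray(self.predicted)
        self.true = np.asarray(self.true)
        if self.predicted.shape != self.true.shape:
            raise ShapeMismatchError(
                f"prediction shape {self.predicted.shape} != truth shape {self.true.shape}")
        if self.ignore is None:
            self.ignore = (self.true == IGNORE_LABEL)
        else:
            self.ignore = np.asarray(self.ignore, dtype=bool)
            if self.ignore.shape != self.true.shape:
                raise ShapeMismatchError("ignore mask shape mismatch")
            self.ignore = self.ignore | (self.true == IGNORE_LABEL)
        valid_true = self.true[~self.ignore]
        if valid_true.size and (valid_true.min() < 0 or valid_true.max() >= self.n_classes):
            raise InvalidInputError("true labels outside [0, n_classes) on unignored pixels")

    @property
    def valid(self) -> np.ndarray:
        return ~self.ignore


def confusion_matrix(batch: SegmentationBatch) -> np.ndarray:
    """C x C matrix with rows = true class, columns = predicted class."""
    keep = batch.valid
    t = batch.true[keep].astype(np.int64)
    p = np.clip(batch.predicted[keep].astype(np.int64), 0, batch.n_classes - 1)
    if t.size == 0:
        raise InvalidInputError("no unignored pixels to score")
    c = batch.n_classes
    return np.bincount(t * c + p, minlength=c * c).reshape(c, c)


def segmentation_scores(batch: SegmentationBatch) -> SegmentationScores:
    """Pixel accuracy, mean accuracy and mean IoU; class means run over the
    classes present in the ground truth (C' convention)."""
    n = confusion_matrix(batch).astype(np.float64)
    diag = np.diag(n)
    t = n.sum(axis=1)
    present = t > 0
    pixel_acc = diag.sum() / t.sum()
    mean_acc = float(np.mean(diag[present] / t[present]))
    union = t + n.sum(axis=0) - diag
    mean_iou = float(np.mean(diag[present] / union[present]))
    return SegmentationScores(float(pixel_acc), mean_acc, mean_iou)


def confidence_percentile_accuracy(i_norm, correct, q: float) -> float:
    """Accuracy over the (100-q)% most certain pixels.

    q=0 scores all pixels; q=90 keeps the 10% most certain.  Percentile cut
    ties resolve by stable order (lowest index first).
    """
    if not (0.0 <= q < 100.0):
        raise InvalidParameterError(f"percentile must lie in [0, 100), got {q}")
    u = np.asarray(i_norm, dtype=np.float64).ravel()
    c = np.asarray(correct, dtype=bool).ravel()
    if u.shape != c.shape:
        raise ShapeMismatchError("uncertainty and correctness lengths differ")
    if u.size == 0:
        raise InvalidInputError("no pixels to score")
    m = int(np.ceil((1.0 - q / 100.0) * u.size - 1e-12))
    order = np.argsort(u, kind="stable")
    return float(c[order[:m]].mean())


def render_maps(batch: SegmentationBatch, i_norm_map: np.ndarray, threshold: float):
    """Binary correctness and confidence maps as PIL images.

    Correct / certain pixels are white (255), incorrect / uncertain black
    (0), ignored pixels neutral gray (127).  Certainty uses the strict
    inequality I_norm < I_T, so threshold 0 yields an all-black (bar ignored)
    confidence map.
    """
    if not (0.0 <= threshold <= 1.0):
        raise InvalidParameterError(f"threshold must lie in [0, 1], got {threshold}")
    u = np.asarray(i_norm_map, dtype=np.float64)
    if u.shape != batch.true.shape:
        raise ShapeMismatchError("uncertainty map shape mismatch")
    correct = (batch.predicted == batch.true)
    certain = u < threshold
    corr_img = np.where(correct, 255, 0).astype(np.uint8)
    conf_img = np.where(certain, 255, 0).astype(np.uint8)
    corr_img[batch.ignore] = 127
    conf_img[batch.ignore] = 127
    return Image.fromarray(corr_img, mode="L"), Image.fromarray(conf_img, mode="L")


def save_uncertainty_map(i_norm_map: np.ndarray, path_prefix: str):
    """Persist a pixel-wise uncertainty map as a 32-bit array container plus
    a PNG heat map (hot colormap, 0 = certain, 1 = maximally uncertain)."""
    u = np.asarray(i_norm_map, dtype=np.float32)
    np.savez_compressed(str(path_prefix) + ".npz", i_norm=u)
    import matplotlib
    matplotlib.use("Agg")

    rgba = matplotlib.colormaps["hot"](np.clip(u, 0.0, 1.0))
    Image.fromarray((rgba[..., :3] * 255).astype(np.uint8)).save(
        str(path_prefix) + ".png")


def load_nifti_slices(path) -> np.ndarray:
    """Optional 3-D support: load a NIfTI label or image volume and return it
    as a stack of axial 2-D slices (Z, H, W) for slice-wise processing."""
    import nibabel as nib

    vol = np.asanyarray(nib.load(str(path)).dataobj)
    if vol.ndim != 3:
        raise InvalidInputError(f"expected a 3-D volume, got shape {vol.shape}")
    return np.moveaxis(vol, -1, 0)
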