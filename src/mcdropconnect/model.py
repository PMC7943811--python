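"""Model / Results objects tying the pipeline together.

``DropConnectClassifier`` and ``DropConnectSegmenter`` are built from data
(arrays or a DataFrame), hold the architecture and masking configuration,
and ``fit()`` returns a results object that carries the trained network, the
loss trace, and everything downstream: Monte Carlo sampling, uncertainty
measures, threshold-sweep evaluation, referral analysis and map rendering,
plus a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import evaluation, mc, referral, segmentation, uncertainty
from .exceptions import InvalidInputError
from .fixtures import tiny_mlp, tiny_segmenter
from .nn import Network, TrainingConfig, train_model


def _fmt_table(title: str, rows: list) -> str:
    width = max(len(k) for k, _ in rows) + 2
    lines = [title, "=" * (width + 24)]
    for k, v in rows:
        if isinstance(v, float):
            v = f"{v:.4f}"
        lines.append(f"{k:<{width}}{v}")
    lines.append("=" * (width + 24))
    return "\n".join(lines)


@dataclass
class ClassificationAssessment:
    """Joint prediction / uncertainty evaluation on one labelled set."""

    error_standard: float  # deterministic single-pass error rate
    error_mc: float  # MC-averaged error rate
    correct: np.ndarray
    unc: uncertainty.UncertaintyResult
    curves: evaluation.UncertaintyCurves
    ks_statistic: Optional[float] = None
    ks_pvalue: Optional[float] = None

    def summary(self) -> str:
        rows = [
            ("N items", int(self.correct.size)),
            ("Standard error (%)", 100 * self.error_standard),
            ("MC error (%)", 100 * self.error_mc),
            ("R_iu AUC (%)", self.curves.auc["r_iu"]),
            ("R_cc AUC (%)", self.curves.auc["r_cc"]),
            ("UA AUC (%)", self.curves.auc["ua"]),
        ]
        if self.ks_statistic is not None:
            rows += [("KS D (correct vs incorrect)", self.ks_statistic),
                     ("KS p-value", self.ks_pvalue)]
        return _fmt_table("Uncertainty evaluation", rows)

    def metrics_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "error_standard_percent": 100 * self.error_standard,
            "error_mc_percent": 100 * self.error_mc,
            "auc_r_iu_percent": self.curves.auc["r_iu"],
            "auc_r_cc_percent": self.curves.auc["r_cc"],
            "auc_ua_percent": self.curves.auc["ua"],
        }])

    def plot_curves(self, path=None):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 3.5))
        t = self.curves.table
        for name in ("r_cc", "r_iu", "ua"):
            ax.plot(t["threshold"], t[name],
                    label=f"{name.upper()} (AUC {self.curves.auc[name]:.1f}%)")
        ax.set_xlabel("uncertainty threshold $I_T$")
        ax.set_ylabel("metric value")
        ax.legend(loc="lower right", fontsize=8)
        fig.tight_layout()
        if path:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


class _FittedMixin:
    """Shared MC / uncertainty plumbing for the results objects."""

    network: Network

    def mc_samples(self, x, T: int = mc.DEFAULT_T, seed: int = 0) -> mc.MCPredictionSet:
        return mc.mc_predict(self.network, x, T=T, seed=seed)

    def predict_proba(self, x, T: int = mc.DEFAULT_T, seed: int = 0) -> np.ndarray:
        return mc.predictive_mean(self.mc_samples(x, T=T, seed=seed))

    def predict(self, x, T: int = mc.DEFAULT_T, seed: int = 0) -> np.ndarray:
        return mc.predicted_labels(self.predict_proba(x, T=T, seed=seed))

    def uncertainty(self, x, T: int = mc.DEFAULT_T, seed: int = 0,
                    bounds=None) -> uncertainty.UncertaintyResult:
        return uncertainty.UncertaintyResult.from_samples(
            self.mc_samples(x, T=T, seed=seed), bounds=bounds)

    def _assess(self, x, labels, T, seed, with_ks=True) -> ClassificationAssessment:
        labels = np.asarray(labels).reshape(-1)
        mcset = self.mc_samples(x, T=T, seed=seed)
        mean = mc.predictive_mean(mcset)
        pred_mc = mc.predicted_labels(mean)
        pred_det = mc.predicted_labels(mc.deterministic_predict(self.network, x))
        correct = evaluation.correctness_map(pred_mc, labels)
        unc = uncertainty.UncertaintyResult.from_samples(mcset)
        curves = evaluation.metric_curves(unc.i_norm, correct)
        ks_d = ks_p = None
        if with_ks and correct.any() and (~correct).any():
            ks_d, ks_p = evaluation.ks_separation(unc.i_norm[correct], unc.i_norm[~correct])
        return ClassificationAssessment(
            error_standard=float(np.mean(pred_det != labels)),
            error_mc=float(np.mean(pred_mc != labels)),
            correct=correct, unc=unc, curves=curves,
            ks_statistic=ks_d, ks_pvalue=ks_p)


class DropConnectClassifier:
    """Bernoulli-masked MLP classifier built from labelled feature arrays.

    Parameters
    ----------
    x, y : arrays (N, d) and (N,)
    hidden : hidden layer widths
    keep_prob : Bernoulli keep probability p (0.5 is the field convention)
    mask_mode : "weight" (DropConnect) or "unit" (Dropout baseline)
    """

    def __init__(self, x, y, *, n_classes: Optional[int] = None,
                 hidden: Sequence[int] = (64, 64), keep_prob: float = 0.5,
                 mask_mode: str = "weight", scale_by_inverse_p: bool = True,
                 seed: int = 0):
        self.x = np.asarray(x, dtype=np.float64)
        self.y = np.asarray(y, dtype=np.int64).reshape(-1)
        if self.x.ndim != 2 or self.x.shape[0] != self.y.shape[0]:
            raise InvalidInputError("x must be (N, d) with matching labels")
        self.n_classes = int(n_classes if n_classes is not None else self.y.max() + 1)
        self.seed = int(seed)
        self.network = tiny_mlp(n_features=self.x.shape[1], n_classes=self.n_classes,
                                hidden=tuple(hidden), keep_prob=keep_prob,
                                mask_mode=mask_mode,
                                scale_by_inverse_p=scale_by_inverse_p, seed=seed)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "label",
                       feature_cols: Optional[Sequence[str]] = None,
                       **kwargs) -> "DropConnectClassifier":
        cols = [c for c in df.columns if c != label_col] if feature_cols is None else list(feature_cols)
        return cls(df[cols].to_numpy(dtype=np.float64), df[label_col].to_numpy(), **kwargs)

    def fit(self, *, epochs: int = 80, learning_rate: float = 0.01,
            batch_size: int = 64, weight_decay: float = 1e-4,
            momentum: float = 0.9) -> "DropConnectResults":
        config = TrainingConfig(weight_decay=weight_decay, epochs=epochs,
                                learning_rate=learning_rate, batch_size=batch_size,
                                momentum=momentum, seed=self.seed)
        _, trace = train_model(self.network, self.x, self.y, config)
        return DropConnectResults(model=self, network=self.network,
                                  loss_trace=trace, config=config)


@dataclass
class DropConnectResults(_FittedMixin):
    """Fitted classifier: carries the network and the downstream analyses."""

    model: DropConnectClassifier
    network: Network
    loss_trace: list
    config: TrainingConfig

    def evaluate(self, x, y, T: int = mc.DEFAULT_T, seed: int = 0) -> ClassificationAssessment:
        return self._assess(x, y, T, seed)

    def referral_by_fraction(self, x, y, T: int = mc.DEFAULT_T, seed: int = 0,
                             fraction_grid=None) -> referral.ReferralCurve:
        a = self._assess(x, y, T, seed, with_ks=False)
        return referral.referral_by_fraction(a.unc.i_norm, a.correct, fraction_grid)

    def convergence(self, x, y, T_grid, repetitions: int = 10, seed: int = 0):
        return mc.convergence_curve(self.network, x, y, T_grid,
                                    repetitions=repetitions, seed=seed)

    def summary(self) -> str:
        rows = [
            ("Architecture", " -> ".join(type(l).__name__ for l in self.network.layers)),
            ("Parameters", self.network.n_params()),
            ("keep_prob", self.network.layers[self.network.stochastic_indices[0]].keep_prob),
            ("mask granularity", self.network.layers[self.network.stochastic_indices[0]].mask_mode),
            ("Training steps", len(self.loss_trace)),
            ("Final objective", self.loss_trace[-1] if self.loss_trace else float("nan")),
            ("weight decay", self.config.weight_decay),
        ]
        return _fmt_table("MC-DropConnect classifier fit", rows)


@dataclass
class SegmentationAssessment:
    """Segmentation scores plus pixel-wise uncertainty evaluation."""

    scores: segmentation.SegmentationScores
    assessment: ClassificationAssessment  # pixel-wise view
    predicted: np.ndarray
    i_norm_maps: np.ndarray

    def percentile_accuracy(self, q: float) -> float:
        return segmentation.confidence_percentile_accuracy(
            self.assessment.unc.i_norm, self.assessment.correct, q)

    def summary(self) -> str:
        rows = [
            ("Pixel accuracy (%)", 100 * self.scores.pixel_accuracy),
            ("Mean accuracy (%)", 100 * self.scores.mean_accuracy),
            ("Mean IoU (%)", 100 * self.scores.mean_iou),
            ("UA AUC (%)", self.assessment.curves.auc["ua"]),
            ("R_cc AUC (%)", self.assessment.curves.auc["r_cc"]),
            ("R_iu AUC (%)", self.assessment.curves.auc["r_iu"]),
        ]
        return _fmt_table("Segmentation evaluation", rows)


class DropConnectSegmenter:
    """Bernoulli-masked encoder-decoder segmenter built from labelled scenes."""

    def __init__(self, images, labels, *, n_classes: Optional[int] = None,
                 base: int = 8, keep_prob: float = 0.5, mask_mode: str = "weight",
                 scale_by_inverse_p: bool = True, stochastic: str = "central",
                 seed: int = 0):
        self.images = np.asarray(images, dtype=np.float64)
        self.labels = np.asarray(labels, dtype=np.int64)
        if self.images.ndim != 4 or self.images.shape[:3] != self.labels.shape:
            raise InvalidInputError("images must be (N, H, W, C) with (N, H, W) labels")
        self.n_classes = int(n_classes if n_classes is not None else self.labels.max() + 1)
        self.seed = int(seed)
        self.network = tiny_segmenter(in_channels=self.images.shape[-1],
                                      n_classes=self.n_classes, base=base,
                                      keep_prob=keep_prob, mask_mode=mask_mode,
                                      scale_by_inverse_p=scale_by_inverse_p,
                                      stochastic=stochastic, seed=seed)

    def fit(self, *, epochs: int = 300, learning_rate: float = 0.02,
            batch_size: int = 4, weight_decay: float = 1e-4,
            momentum: float = 0.9) -> "DropConnectSegmenterResults":
        config = TrainingConfig(weight_decay=weight_decay, epochs=epochs,
                                learning_rate=learning_rate, batch_size=batch_size,
                                momentum=momentum, seed=self.seed)
        _, trace = train_model(self.network, self.images, self.labels, config)
        return DropConnectSegmenterResults(model=self, network=self.network,
                                           loss_trace=trace, config=config)


@dataclass
class DropConnectSegmenterResults(_FittedMixin):
    model: DropConnectSegmenter
    network: Network
    loss_trace: list
    config: TrainingConfig

    def evaluate(self, images, labels, T: int = 50, seed: int = 0) -> SegmentationAssessment:
        images = np.asarray(images, dtype=np.float64)
        labels = np.asarray(labels, dtype=np.int64)
        a = self._assess(images, labels.reshape(-1), T, seed)
        shape = labels.shape
        pred = mc.predicted_labels(
            mc.predictive_mean(self.mc_samples(images, T=T, seed=seed))).reshape(shape)
        batch = segmentation.SegmentationBatch(predicted=pred, true=labels,
                                               n_classes=self.model.n_classes)
        return SegmentationAssessment(scores=segmentation.segmentation_scores(batch),
                                      assessment=a, predicted=pred,
                                      i_norm_maps=a.unc.i_norm.reshape(shape))

    def summary(self) -> str:
        rows = [
            ("Architecture", " -> ".join(type(l).__name__ for l in self.network.layers)),
            ("Parameters", self.network.n_params()),
            ("Training steps", len(self.loss_trace)),
            ("Final objective", self.loss_trace[-1] if self.loss_trace else float("nan")),
        ]
        return _fmt_table("MC-DropConnect segmenter fit", rows)
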