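"""Shared fixtures: the multi-seed behavioural study runs are computed once
per session and reused by the property and acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mcdropconnect as mdc
from mcdropconnect import mc, referral

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

N_SEEDS = 20
TRAIN_N = 1000  # of the 2000 generated samples; the rest are the test set


def run_classification_seed(seed: int) -> dict:
    """One full classification study run: train, MC-predict (T=100), score."""
    x, y, ood = mdc.generate_blob_task(mdc.BlobTaskSpec(seed=seed))
    xtr, ytr = x[:TRAIN_N], y[:TRAIN_N]
    xte, yte = x[TRAIN_N:], y[TRAIN_N:]
    res = mdc.DropConnectClassifier(xtr, ytr, seed=seed).fit()
    a = res.evaluate(xte, yte, T=100, seed=seed)
    u_ood = res.uncertainty(ood, T=100, seed=seed + 500,
                            bounds=(a.unc.i_min, a.unc.i_max))
    rc = referral.referral_by_fraction(a.unc.i_norm, a.correct, [0.5, 1.0])
    rb = referral.random_rejection_baseline(a.correct, [0.5], seed=seed)

    def mean_pred_variance(T: int, offset: int, reps: int = 30) -> float:
        means = [mc.predictive_mean(mc.mc_predict(res.network, xte[:200], T=T,
                                                  seed=20000 + offset + r))
                 for r in range(reps)]
        return float(np.stack(means).var(axis=0, ddof=0).mean())

    return {
        "results": res,
        "assessment": a,
        "error_mc": a.error_mc,
        "error_standard": a.error_standard,
        "i_norm_correct_mean": float(a.unc.i_norm[a.correct].mean()),
        "i_norm_incorrect_mean": float(a.unc.i_norm[~a.correct].mean()),
        "ks_pvalue": a.ks_pvalue,
        "ood_i_norm_mean": float(u_ood.i_norm.mean()),
        "in_dist_i_norm_mean": float(a.unc.i_norm.mean()),
        "ua_auc": a.curves.auc["ua"],
        "referral_half": float(rc.accuracy[0]),
        "referral_full": float(rc.accuracy[1]),
        "random_half_mean": float(rb["accuracy_mean"][0]),
        "var_T64": mean_pred_variance(64, seed * 97),
        "var_T4": mean_pred_variance(4, seed * 97 + 43),
    }


def run_segmentation_seed(seed: int) -> dict:
    """One segmentation study run: 24 training scenes, 8 test scenes, T=50."""
    imgs, labs = mdc.generate_toy_segmentation(mdc.ToySegSpec(seed=seed))
    ti, tl = mdc.generate_toy_segmentation(mdc.ToySegSpec(seed=1000 + seed, n_images=8))
    res = mdc.DropConnectSegmenter(imgs, labs, seed=seed).fit()
    a = res.evaluate(ti, tl, T=50, seed=seed)
    qs = {q: a.percentile_accuracy(q) for q in (0, 10, 50, 90)}
    u = a.i_norm_maps
    return {
        "scores": a.scores,
        "percentile_accuracy": qs,
        "rare_uncertainty": float(u[tl == 3].mean()),
        "background_uncertainty": float(u[tl == 0].mean()),
        "test_labels": tl,
    }


@pytest.fixture(scope="session")
def blob_runs():
    return [run_classification_seed(s) for s in range(N_SEEDS)]


@pytest.fixture(scope="session")
def seg_runs():
    return [run_segmentation_seed(s) for s in range(N_SEEDS)]


@pytest.fixture(scope="session")
def quick_classifier():
    """A small, quickly trained classifier for engine-level tests."""
    x, y, _ = mdc.generate_blob_task(mdc.BlobTaskSpec(n_samples=600, seed=11))
    res = mdc.DropConnectClassifier(x[:400], y[:400], hidden=(16,), seed=11).fit(
        epochs=15, learning_rate=0.02)
    return res, x[400:], y[400:]
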