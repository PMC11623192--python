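"""Evaluation metrics and the cross-validated reporting harness.

Implements the standard confusion metrics (accuracy, true-positive rate),
RMSE, the literal lifetime (data-arrival-rate x period) and propagation
latency (distance / speed) formulas with unit pass-through, false-alarm vs
TPR curves, and a stratified k-fold harness that retrains the full detector
per fold and emits a per-fold accuracy/RMSE table (six folds by default).

Hardware resource consumption is not measurable in a portable way; a
deterministic operation-count proxy (floating-point multiply-adds per
scored window) is reported instead and clearly labelled as a proxy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agrnn import (DetectorConfig, _frame_features, detect_windows,
                    fit_window_detector, window_labels)
from .dpca import FeatureMatrix
from .frames import ValidationError
from .rfe import stratified_folds
from .synthgen import LabelledStream

__all__ = [
    "ConfusionCounts",
    "confusion_counts",
    "accuracy",
    "true_positive_rate",
    "rmse",
    "lifetime_and_latency",
    "far_tpr_curve",
    "kfold_report",
    "KFoldReport",
    "flops_per_window",
    "windows_with_labels",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "TN", "FP", "FN"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def confusion_counts(truth, flags) -> ConfusionCounts:
    """Standard 2x2 tally of binary truth vs predictions."""
    truth = np.asarray(truth, dtype=int)
    flags = np.asarray(flags, dtype=int)
    if truth.shape != flags.shape:
        raise ValidationError("truth and flags must have equal length")
    if truth.size == 0:
        raise ValidationError("empty inputs")
    tp = int(np.sum((truth == 1) & (flags == 1)))
    tn = int(np.sum((truth == 0) & (flags == 0)))
    fp = int(np.sum((truth == 0) & (flags == 1)))
    fn = int(np.sum((truth == 1) & (flags == 0)))
    return ConfusionCounts(tp, tn, fp, fn)


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / total; the fraction of correctly classified windows."""
    if c.total == 0:
        raise ValidationError("cannot compute accuracy of zero counts")
    return (c.TP + c.TN) / c.total


def true_positive_rate(c: ConfusionCounts) -> float:
    """TP / (TP + FN); sensitivity, always in [0, 1]."""
    if c.TP + c.FN == 0:
        raise ValidationError("no positive cases in truth")
    return c.TP / (c.TP + c.FN)


def rmse(actual, predicted) -> float:
    """Root mean squared difference between two equally long sequences."""
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape or a.size == 0:
        raise ValidationError("sequences must be equally long and non-empty")
    return float(np.sqrt(np.mean((a - p) ** 2)))


def lifetime_and_latency(
    dar: float, period: float, distance: float, speed: float
) -> tuple[float, float]:
    """Literal lifetime (DAR x period) and propagation latency (D / v).

    Units pass through unconverted: if DAR is in samples/s and the period in
    seconds, the lifetime is a sample count; latency has the unit of
    distance/speed.
    """
    if speed <= 0:
        raise ValidationError("speed must be > 0")
    if dar < 0 or period < 0 or distance < 0:
        raise ValidationError("dar, period and distance must be >= 0")
    return dar * period, distance / speed


def far_tpr_curve(scores, truth, thresholds) -> list[tuple[int, float]]:
    """Per descending threshold: (false-alarm count, TPR) with flag = score > t."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=int)
    thresholds = np.asarray(thresholds, dtype=float)
    if scores.shape != truth.shape:
        raise ValidationError("scores and truth must align")
    if np.any(np.diff(thresholds) > 0):
        raise ValidationError("thresholds must be sorted descending")
    if truth.sum() == 0:
        raise ValidationError("no positive cases in truth")
    curve = []
    for t in thresholds:
        flags = scores > t
        fp = int(np.sum(flags & (truth == 0)))
        tpr = float(np.mean(flags[truth == 1]))
        curve.append((fp, tpr))
    return curve


def flops_per_window(model) -> int:
    """Deterministic operation-count proxy for resource consumption.

    Multiply-adds needed to score one window: encode + one recurrent step +
    readout.  A proxy for, not a measurement of, hardware resource use.
    """
    ae = model.autoencoder
    d = int(model.genome.mask_array.sum())
    h = model.rnn.hidden_dim
    return int(ae.input_dim * ae.bottleneck_dim + h * h + h * d + d * h)


# ------------------------------------------------------------ k-fold harness


@dataclass
class KFoldReport:
    """Per-fold table mirroring the columns Fold / Accuracy (%) / RMSE (%)."""

    table: pd.DataFrame
    mean_accuracy: float
    sd_accuracy: float
    mean_rmse: float
    sd_rmse: float
    seed: int = 0
    extras: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def kfold_report(
    features: FeatureMatrix,
    k: int = 6,
    config: DetectorConfig | None = None,
    seed: int = 0,
) -> KFoldReport:
    """Stratified k-fold evaluation of the full detector over labelled windows.

    For each fold, the detector is retrained on the remaining folds (its
    autoencoder/recurrent stages see only the normal windows; the labelled
    anomalous windows calibrate the genetic threshold search) and evaluated
    on the held-out fold.  Accuracy and the RMSE between predicted flags and
    true labels are reported per fold, in percent, plus mean ± SD.
    """
    if features.labels is None:
        raise ValidationError("kfold_report requires labelled windows")
    if k < 2:
        raise ValidationError("k must be >= 2")
    config = config or DetectorConfig()
    labels = features.labels
    counts = np.bincount(labels, minlength=2)
    if counts.min() < k:
        raise ValidationError(f"each class needs at least k={k} windows")
    folds = stratified_folds(labels, k, seed)
    rows = []
    for i, held in enumerate(folds):
        train_mask = np.ones(features.n_windows, dtype=bool)
        train_mask[held] = False
        idx = np.flatnonzero(train_mask)
        f_train = FeatureMatrix(
            features.values[idx],
            list(features.feature_names),
            [features.window_spans[j] for j in idx],
            labels[idx],
        )
        model = fit_window_detector(f_train, config, seed=seed)
        f_test = FeatureMatrix(
            features.values[held],
            list(features.feature_names),
            [features.window_spans[j] for j in held],
            labels[held],
        )
        report = detect_windows(f_test, model)
        c = confusion_counts(labels[held], report.flags.astype(int))
        acc = accuracy(c)
        err = rmse(labels[held].astype(float), report.flags.astype(float))
        rows.append({"Fold": i + 1, "Accuracy (%)": 100.0 * acc, "RMSE (%)": 100.0 * err})
    table = pd.DataFrame(rows)
    accs = table["Accuracy (%)"].to_numpy() / 100.0
    errs = table["RMSE (%)"].to_numpy() / 100.0
    return KFoldReport(
        table=table,
        mean_accuracy=float(accs.mean()),
        sd_accuracy=float(accs.std()),
        mean_rmse=float(errs.mean()),
        sd_rmse=float(errs.std()),
        seed=seed,
    )


def windows_with_labels(stream: LabelledStream, config: DetectorConfig) -> FeatureMatrix:
    """Window a labelled stream and attach window-level labels."""
    feats = _frame_features(stream.frame, config)
    labs = window_labels(stream.labels, feats.window_spans)
    return FeatureMatrix(feats.values, feats.feature_names, feats.window_spans, labs)
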