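"""Windowed feature extraction and discriminant principal component analysis.

Feature extraction slides a fixed-length window over the stream and, per
channel, computes mean, SD, min, max and slope, plus lag-0 Pearson
cross-correlation for declared channel pairs.  DPCA then couples an
unsupervised variance-preserving projection (PCA) with a supervised
shrinkage-regularized discriminant: class covariances are blended toward
the pooled covariance (gamma) and toward a scaled identity (rho), which
guarantees invertibility even with few windows per class, and windows are
classified by the regularized Mahalanobis score

    h_j(x) = (x - m_j)' S_j(g,r)^{-1} (x - m_j) + ln|S_j(g,r)| - 2 ln phi_j

with class priors phi_j; argmin wins.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .frames import SensorFrame, ValidationError

__all__ = [
    "FeatureMatrix",
    "PCAModel",
    "DiscriminantModel",
    "window_features",
    "pca_fit",
    "variance_proportion",
    "pca_project",
    "pca_reconstruct",
    "lda_fit",
    "mahalanobis_classify",
]

logger = logging.getLogger(__name__)

WINDOW_STATS = ("mean", "sd", "min", "max", "slope")

#: Windows with more than this missing fraction in any channel are dropped.
MAX_MISSING_FRACTION = 0.30


@dataclass
class FeatureMatrix:
    """Rows = windows, columns = named features, optional class labels."""

    values: np.ndarray
    feature_names: list[str]
    window_spans: list[tuple[int, int]]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be 2-D (windows x features)")
        if self.values.shape[1] != len(self.feature_names):
            raise ValidationError("feature_names length must match value columns")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValidationError("feature names must be unique")
        if len(self.window_spans) != self.values.shape[0]:
            raise ValidationError("one window span per row is required")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("feature matrix must not contain missing entries")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if len(self.labels) != self.values.shape[0]:
                raise ValidationError("labels length must match number of windows")

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select(self, names: list[str]) -> "FeatureMatrix":
        idx = [self.feature_names.index(n) for n in names]
        return FeatureMatrix(self.values[:, idx], list(names), list(self.window_spans), self.labels)

    def to_csv(self, path, sidecar_path=None) -> None:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.to_csv(path, index=False)
        if sidecar_path is not None:
            payload = {
                "window_spans": [list(s) for s in self.window_spans],
                "labels": None if self.labels is None else self.labels.tolist(),
            }
            with open(sidecar_path, "w") as fh:
                json.dump(payload, fh)

    @classmethod
    def from_csv(cls, path, sidecar_path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        with open(sidecar_path) as fh:
            meta = json.load(fh)
        labels = None if meta["labels"] is None else np.asarray(meta["labels"], dtype=int)
        spans = [tuple(s) for s in meta["window_spans"]]
        return cls(df.to_numpy(dtype=float), list(df.columns), spans, labels)


def _pearson0(a: np.ndarray, b: np.ndarray) -> float:
    """Lag-0 Pearson correlation; 0 by convention if either side is constant."""
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 2:
        return 0.0
    a, b = a[ok], b[ok]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def window_features(
    frame: SensorFrame,
    window: int,
    stride: int,
    pairs: list[tuple[str, str]] | None = None,
) -> FeatureMatrix:
    """Slide a window over the stream and extract per-channel statistics.

    Stats are computed over the non-missing samples of each window; windows
    in which any channel exceeds 30% missingness are dropped (logged).
    ``pairs`` selects the channel pairs for cross-correlation features
    (default: none).
    """
    if window < 4:
        raise ValidationError("window must be >= 4 samples")
    if stride < 1:
        raise ValidationError("stride must be >= 1")
    n = len(frame)
    if window > n:
        raise ValidationError(f"window {window} longer than stream {n}")
    pairs = pairs or []
    channels = frame.channels
    for a, b in pairs:
        if a not in channels or b not in channels:
            raise ValidationError(f"cross-correlation pair ({a}, {b}) not in channels")

    names = [f"{ch}_{stat}" for ch in channels for stat in WINDOW_STATS]
    names += [f"xcorr_{a}_{b}" for a, b in pairs]
    cols = {ch: frame.values(ch) for ch in channels}

    rows: list[list[float]] = []
    spans: list[tuple[int, int]] = []
    dropped = 0
    for start in range(0, n - window + 1, stride):
        end = start + window
        feats: list[float] = []
        keep = True
        for ch in channels:
            seg = cols[ch][start:end]
            finite = np.isfinite(seg)
            if finite.mean() < 1.0 - MAX_MISSING_FRACTION or finite.sum() < 2:
                keep = False
                break
            vals = seg[finite]
            mean = vals.mean()
            sd = vals.std()
            if finite.all():
                slope = float(np.polyfit(np.arange(window), seg, 1)[0])
            else:
                xs = np.flatnonzero(finite).astype(float)
                slope = float(np.polyfit(xs, vals, 1)[0])
            feats.extend([mean, sd, vals.min(), vals.max(), slope])
        if not keep:
            dropped += 1
            continue
        for a, b in pairs:
            feats.append(_pearson0(cols[a][start:end], cols[b][start:end]))
        rows.append(feats)
        spans.append((start, end))
    if dropped:
        logger.info("window_features: dropped %d windows with excess missingness", dropped)
    if not rows:
        raise ValidationError("all windows were dropped (excess missingness)")
    return FeatureMatrix(np.asarray(rows, dtype=float), names, spans)


# ----------------------------------------------------------------------- PCA


@dataclass
class PCAModel:
    """Mean vector, eigenvalues (descending) and orthonormal eigenvectors."""

    mean_vector: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray      # columns are components
    feature_names: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


def pca_fit(X: FeatureMatrix | np.ndarray) -> PCAModel:
    """Eigendecomposition of the sample covariance (1/(n-1) divisor)."""
    names: list[str] = []
    if isinstance(X, FeatureMatrix):
        names = list(X.feature_names)
        X = X.values
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
        raise ValidationError("PCA needs a 2-D matrix with >= 2 rows and >= 1 column")
    if not np.all(np.isfinite(X)):
        raise ValidationError("PCA input must be finite")
    mean = X.mean(axis=0)
    centered = X - mean
    cov = centered.T @ centered / (X.shape[0] - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    return PCAModel(mean, eigvals, eigvecs, names)


def variance_proportion(model: PCAModel, M: int) -> float:
    """Cumulative fraction of variance carried by the top-M components."""
    if not (1 <= M <= model.n_components):
        raise ValidationError(f"M must be in [1, {model.n_components}]")
    total = model.eigenvalues.sum()
    if total <= 0:
        return 1.0
    return float(model.eigenvalues[:M].sum() / total)


def pca_project(X: FeatureMatrix | np.ndarray, model: PCAModel, K: int) -> np.ndarray:
    """Project centered data onto the top-K components."""
    if isinstance(X, FeatureMatrix):
        if model.feature_names and X.feature_names != model.feature_names:
            raise ValidationError("feature names do not match the fitted PCA model")
        X = X.values
    X = np.asarray(X, dtype=float)
    if not (1 <= K <= model.n_components):
        raise ValidationError(f"K must be in [1, {model.n_components}]")
    return (X - model.mean_vector) @ model.eigenvectors[:, :K]


def pca_reconstruct(scores: np.ndarray, model: PCAModel) -> np.ndarray:
    """Inverse projection back to the original feature space."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    K = scores.shape[1]
    return scores @ model.eigenvectors[:, :K].T + model.mean_vector


# ------------------------------------------------------ regularized LDA


@dataclass
class DiscriminantModel:
    classes: np.ndarray
    class_means: np.ndarray              # classes x dims
    reg_covariances: np.ndarray          # classes x dims x dims
    priors: np.ndarray
    gamma: float
    rho: float

    def __post_init__(self) -> None:
        if not np.isclose(self.priors.sum(), 1.0):
            raise ValidationError("class priors must sum to 1")


def default_rho(class_covs: np.ndarray, n_total: int, dims: int) -> float:
    """Identity-shrinkage default: (tr(mean class cov / n) + d) / d, clipped."""
    tr = float(np.mean([np.trace(c) for c in class_covs])) / max(n_total, 1)
    return float(np.clip((tr + dims) / dims, 0.0, 1.0))


def lda_fit(
    X: np.ndarray,
    labels,
    gamma: float = 1.0,
    rho: float | None = None,
) -> DiscriminantModel:
    """Fit the shrinkage-regularized discriminant.

    Per class j with n_j windows out of n:
      R_j = class scatter;  pooled R = sum_j R_j
      S_j(g)   = [(1-g) R_j + g R] / [(1-g) n_j + g n]
      S_j(g,r) = (1-r) S_j(g) + (r/d) tr[S_j(g)] I

    ``rho=None`` selects the identity-shrinkage default (clipped to [0,1]).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray(labels)
    if X.shape[0] != len(labels):
        raise ValidationError("labels length must match rows of X")
    if not (0.0 <= gamma <= 1.0):
        raise ValidationError("gamma must be in [0, 1]")
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValidationError("at least 2 classes are required")
    n, d = X.shape
    means = np.zeros((len(classes), d))
    scatters = np.zeros((len(classes), d, d))
    counts = np.zeros(len(classes))
    for i, c in enumerate(classes):
        Xi = X[labels == c]
        if Xi.shape[0] < 2:
            raise ValidationError(f"class {c!r} needs >= 2 windows")
        counts[i] = Xi.shape[0]
        means[i] = Xi.mean(axis=0)
        centered = Xi - means[i]
        scatters[i] = centered.T @ centered
    pooled = scatters.sum(axis=0)
    # maximum-likelihood class covariances (scatter / n_j) for the rho default
    class_covs = scatters / counts[:, None, None]
    if rho is None:
        rho = default_rho(class_covs, n, d)
    if not (0.0 <= rho <= 1.0):
        raise ValidationError("rho must be in [0, 1]")

    reg = np.zeros_like(scatters)
    eye = np.eye(d)
    for i in range(len(classes)):
        denom = (1.0 - gamma) * counts[i] + gamma * n
        s_gamma = ((1.0 - gamma) * scatters[i] + gamma * pooled) / denom
        reg[i] = (1.0 - rho) * s_gamma + (rho / d) * np.trace(s_gamma) * eye
        if rho == 0.0:
            if np.linalg.matrix_rank(reg[i]) < d:
                raise ValidationError(
                    f"regularized covariance of class {classes[i]!r} is singular at rho=0; "
                    "use rho > 0"
                )
    priors = counts / n
    return DiscriminantModel(classes, means, reg, priors, float(gamma), float(rho))


def mahalanobis_classify(x, model: DiscriminantModel):
    """Classify by regularized Mahalanobis score; returns (labels, scores).

    ``x`` may be a single vector or a batch; scores h_j are returned per
    class (lower is better) and the argmin class label(s) are returned.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    d = model.class_means.shape[1]
    if x.shape[1] != d:
        raise ValidationError(f"input dimension {x.shape[1]} != model dimension {d}")
    n_cls = len(model.classes)
    scores = np.zeros((x.shape[0], n_cls))
    for j in range(n_cls):
        cov = model.reg_covariances[j]
        sign, logdet = np.linalg.slogdet(cov)
        if sign <= 0:
            raise NumericalErrorLDA(f"covariance of class {model.classes[j]!r} is not invertible")
        diff = x - model.class_means[j]
        sol = np.linalg.solve(cov, diff.T).T
        maha = np.einsum("ij,ij->i", diff, sol)
        scores[:, j] = maha + logdet - 2.0 * np.log(model.priors[j])
    winners = model.classes[np.argmin(scores, axis=1)]
    if winners.shape[0] == 1:
        return winners[0], scores[0]
    return winners, scores


class NumericalErrorLDA(RuntimeError):
    pass
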