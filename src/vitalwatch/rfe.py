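"""Recursive feature elimination with adaptive rank-weighted relevance.

Each round trains a linear max-margin classifier, converts its nonnegative
dual coefficients into per-feature relevance weights

    |Z_i| = |sum_j beta_j x_j y_ji|        (beta_j dual coefficient,
                                            x_j in {-1,+1} the label,
                                            y_ji the feature value)

ranks the features (rank 1 = most relevant, ties broken toward the lower
feature index), discounts each weight by its rank through the adaptive
learning function  phi_j = Z_j / rank_j,  and eliminates the feature with
the lowest phi.  Cross-validated accuracy is recorded per round so the
"ideal feature count" (the round with the best mean CV accuracy, ties to
fewer features) can be read off the history.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dpca import FeatureMatrix
from .frames import ValidationError

__all__ = [
    "RankedFeatures",
    "LinearMaxMargin",
    "feature_weights",
    "rank_features",
    "adaptive_weight",
    "rfe_select",
    "stratified_folds",
]


# ------------------------------------------------------- base classifier


class LinearMaxMargin:
    """Linear SVM trained by projected-gradient ascent on the dual.

    Maximises  sum(a) - a' Q a / 2  over 0 <= a <= C with
    Q = (y y') * (X~ X~'), X~ the data augmented with a constant column for
    the bias.  Deterministic; the fitted nonnegative duals feed Eq-style
    relevance weights directly.
    """

    def __init__(self, C: float = 1.0, iters: int = 300):
        self.C = float(C)
        self.iters = int(iters)
        self.dual_coef_: np.ndarray | None = None
        self.weights_: np.ndarray | None = None  # includes bias as last entry

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LinearMaxMargin":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if set(np.unique(y)) - {-1.0, 1.0}:
            raise ValidationError("labels must be in {-1, +1}")
        Xa = np.hstack([X, np.ones((X.shape[0], 1))])
        K = Xa @ Xa.T
        Q = (y[:, None] * y[None, :]) * K
        # Lipschitz constant of the dual gradient
        L = max(float(np.linalg.norm(Q, 2)), 1e-12)
        a = np.zeros(X.shape[0])
        for _ in range(self.iters):
            grad = 1.0 - Q @ a
            a = np.clip(a + grad / L, 0.0, self.C)
        self.dual_coef_ = a
        self.weights_ = Xa.T @ (a * y)
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        Xa = np.hstack([np.asarray(X, dtype=float), np.ones((len(X), 1))])
        return Xa @ self.weights_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision_function(X) >= 0, 1.0, -1.0)


# --------------------------------------------------------- core formulas


def feature_weights(coefficients, labels, features) -> np.ndarray:
    """Per-feature relevance |Z_i| from duals, labels and feature values."""
    beta = np.asarray(coefficients, dtype=float)
    y = np.asarray(labels, dtype=float)
    Y = np.atleast_2d(np.asarray(features, dtype=float))
    if beta.shape[0] != y.shape[0] or Y.shape[0] != beta.shape[0]:
        raise ValidationError("coefficients, labels and feature rows must align")
    if set(np.unique(y)) - {-1.0, 1.0}:
        raise ValidationError("labels must be in {-1, +1}")
    if np.any(beta < 0):
        raise ValidationError("dual coefficients must be nonnegative")
    return np.abs((beta * y) @ Y)


def rank_features(d) -> np.ndarray:
    """Rank relevance values: 1 = highest, ties broken by lower index."""
    d = np.asarray(d, dtype=float)
    if d.size == 0:
        raise ValidationError("cannot rank an empty relevance vector")
    if not np.all(np.isfinite(d)):
        raise ValidationError("relevance values must be finite")
    order = np.argsort(-d, kind="stable")
    ranks = np.empty(len(d), dtype=int)
    ranks[order] = np.arange(1, len(d) + 1)
    return ranks


def adaptive_weight(Z, ranks) -> np.ndarray:
    """Rank-discounted relevance phi = Z / rank."""
    Z = np.asarray(Z, dtype=float)
    ranks = np.asarray(ranks, dtype=float)
    if Z.shape != ranks.shape:
        raise ValidationError("weights and ranks must have the same length")
    if np.any(ranks < 1):
        raise ValidationError("ranks must be >= 1")
    return Z / ranks


# ------------------------------------------------------------- selection


def stratified_folds(labels: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    """Seeded stratified fold assignment; returns per-fold index arrays."""
    labels = np.asarray(labels)
    if k < 2:
        raise ValidationError("folds must be >= 2")
    rng = np.random.default_rng([int(seed), 32_452_843])
    folds: list[list[int]] = [[] for _ in range(k)]
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        for pos, i in enumerate(idx):
            folds[pos % k].append(int(i))
    out = [np.sort(np.asarray(f, dtype=int)) for f in folds]
    for i, f in enumerate(out):
        if len(f) == 0:
            raise ValidationError(f"fold {i} is empty; reduce k")
    return out


@dataclass
class RankedFeatures:
    """Outcome of the elimination loop."""

    selected: list[str]
    elimination_order: list[str]
    weights: np.ndarray                 # |Z| for the surviving features (final round)
    ranks: np.ndarray
    adaptive_weights: np.ndarray
    cv_history: list[dict] = field(default_factory=list)
    ideal_count: int | None = None
    elimination_records: list[dict] = field(default_factory=list)

    def rank_table(self) -> pd.DataFrame:
        """Feature, elimination round (0 = retained), weight/rank/phi at that round."""
        rows = list(self.elimination_records)
        for i, name in enumerate(self.selected):
            rows.append({
                "feature": name,
                "round_eliminated": 0,
                "weight": self.weights[i],
                "rank": int(self.ranks[i]),
                "adaptive_weight": self.adaptive_weights[i],
            })
        return pd.DataFrame(rows)


def _to_pm1(labels: np.ndarray) -> np.ndarray:
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValidationError("RFE requires exactly two classes")
    return np.where(labels == classes[1], 1.0, -1.0)


def rfe_select(
    X: FeatureMatrix,
    target: int,
    folds: int = 5,
    seed: int = 0,
    C: float = 1.0,
    batch: int = 1,
) -> RankedFeatures:
    """Eliminate features one per round down to ``target`` survivors.

    Per round: stratified CV accuracy of the base classifier is recorded,
    relevance weights are computed from a fit on all rows, and the lowest
    adaptive weight phi is dropped.  ``batch > 1`` removes that many of the
    lowest-phi features per round instead.
    """
    if X.labels is None:
        raise ValidationError("rfe_select requires labelled windows")
    p = X.n_features
    if not (1 <= target <= p):
        raise ValidationError(f"target must be in [1, {p}]")
    if batch < 1:
        raise ValidationError("batch must be >= 1")
    y = _to_pm1(X.labels)
    fold_idx = stratified_folds(X.labels, folds, seed)
    for i, f in enumerate(fold_idx):
        if len(np.unique(X.labels[f])) < 2:
            raise ValidationError(f"fold {i} is degenerate (single class)")

    active = list(range(p))
    names = list(X.feature_names)
    # standardize so relevance ranking is invariant to feature units
    mu = X.values.mean(axis=0)
    sd = X.values.std(axis=0)
    sd[sd < 1e-12] = 1.0
    values = (X.values - mu) / sd
    eliminated: list[str] = []
    records: list[dict] = []
    history: list[dict] = []
    weights = ranks = phi = None
    round_no = 0

    while True:
        cols = values[:, active]
        accs = []
        for i, val_idx in enumerate(fold_idx):
            train_mask = np.ones(len(y), dtype=bool)
            train_mask[val_idx] = False
            clf = LinearMaxMargin(C=C).fit(cols[train_mask], y[train_mask])
            accs.append(float(np.mean(clf.predict(cols[val_idx]) == y[val_idx])))
        clf_all = LinearMaxMargin(C=C).fit(cols, y)
        Z = feature_weights(clf_all.dual_coef_, y, cols)
        ranks = rank_features(Z)
        phi = adaptive_weight(Z, ranks)
        weights = Z
        history.append({
            "n_features": len(active),
            "cv_accuracy": float(np.mean(accs)),
            "cv_accuracy_per_fold": accs,
        })
        if len(active) <= target:
            break
        round_no += 1
        n_drop = min(batch, len(active) - target)
        drop_local = np.argsort(phi, kind="stable")[:n_drop]
        # remove highest-index first so local indices stay valid
        for j in sorted(drop_local.tolist(), reverse=True):
            eliminated.append(names[active[j]])
            records.append({
                "feature": names[active[j]],
                "round_eliminated": round_no,
                "weight": float(weights[j]),
                "rank": int(ranks[j]),
                "adaptive_weight": float(phi[j]),
            })
            del active[j]

    best = max(history, key=lambda h: (h["cv_accuracy"], -h["n_features"]))
    return RankedFeatures(
        selected=[names[i] for i in active],
        elimination_order=eliminated,
        weights=weights,
        ranks=ranks,
        adaptive_weights=phi,
        cv_history=history,
        ideal_count=best["n_features"],
        elimination_records=records,
    )
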