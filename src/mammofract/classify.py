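"""Cross-validated normal/abnormal classification of ROI feature vectors.

Thin, reproducible wrappers around scikit-learn: stratified k-fold
splitting, train-fold-only standardization (median imputation of flagged
NaN features, then z-scoring), three classifier families (degree-2
polynomial-kernel SVM, k-nearest neighbors on standardized features,
decision tree), and confusion-count metrics reported as percentages.
The positive class is ``abnormal`` (microcalcification) throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "FoldAssignment",
    "Metrics",
    "CVReport",
    "stratified_kfold",
    "standardize",
    "train_predict",
    "confusion_metrics",
    "evaluate_cv",
]

POSITIVE_LABEL = "abnormal"
MODEL_KINDS = ("svm_poly2", "knn", "dtree")


@dataclass(frozen=True)
class FoldAssignment:
    """Stratified fold membership: sample index -> fold id."""

    k: int
    fold_of: np.ndarray
    seed: int


@dataclass(frozen=True)
class Metrics:
    """Confusion counts and the derived percentage metrics.

    Zero-denominator metrics are NaN rather than raised.
    """

    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    @property
    def sensitivity(self) -> float:
        d = self.TP + self.FN
        return 100.0 * self.TP / d if d else float("nan")

    @property
    def specificity(self) -> float:
        d = self.TN + self.FP
        return 100.0 * self.TN / d if d else float("nan")

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.TP + self.TN) / self.total if self.total else float("nan")

    @property
    def precision(self) -> float:
        d = self.TP + self.FP
        return 100.0 * self.TP / d if d else float("nan")

    def as_dict(self) -> dict:
        return {
            "TP": self.TP,
            "FP": self.FP,
            "TN": self.TN,
            "FN": self.FN,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "precision": self.precision,
        }


@dataclass(frozen=True)
class CVReport:
    """Per-fold and pooled confusion metrics of one cross-validation run."""

    model: str
    folds: tuple[Metrics, ...]
    pooled: Metrics
    k: int
    seed: int
    params: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "model": self.model,
            "k": self.k,
            "seed": self.seed,
            "params": self.params,
            "pooled": self.pooled.as_dict(),
            "folds": [m.as_dict() for m in self.folds],
        }

    def to_json(self, path) -> None:
        from pathlib import Path

        Path(path).write_text(json.dumps(self.as_dict(), indent=2))

    def to_text(self) -> str:
        """Human-readable per-fold and pooled metric table."""
        header = f"{'fold':>6} {'TP':>5} {'FP':>5} {'TN':>5} {'FN':>5} {'sens%':>7} {'spec%':>7} {'acc%':>7} {'prec%':>7}"
        lines = [f"model: {self.model}  k={self.k}  seed={self.seed}", header]
        rows = [*((str(i), m) for i, m in enumerate(self.folds)), ("pooled", self.pooled)]
        for name, m in rows:
            lines.append(
                f"{name:>6} {m.TP:>5} {m.FP:>5} {m.TN:>5} {m.FN:>5} "
                f"{m.sensitivity:>7.2f} {m.specificity:>7.2f} {m.accuracy:>7.2f} {m.precision:>7.2f}"
            )
        return "\n".join(lines)


def stratified_kfold(labels: Sequence[str], k: int, seed: int = 0) -> FoldAssignment:
    """Stratified shuffled k-fold assignment; every class needs >= k members."""
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        small = classes[np.argmin(counts)]
        raise ValueError(f"class {small!r} has {counts.min()} members, fewer than k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of = np.empty(y.size, dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros_like(y), y)):
        fold_of[test_idx] = fold
    return FoldAssignment(k, fold_of, seed)


def standardize(
    train: np.ndarray, other: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None, dict]:
    """z-score features with train-fold statistics only.

    NaN entries (flagged-undefined features) are imputed with the
    train-fold median before scaling; zero-variance columns pass through
    unscaled and are flagged in the returned params.
    """
    train = np.asarray(train, dtype=float)
    if train.size == 0:
        raise ValueError("train set must be non-empty")
    med = np.nanmedian(train, axis=0)
    med = np.where(np.isfinite(med), med, 0.0)
    tr = np.where(np.isnan(train), med, train)
    mean = tr.mean(axis=0)
    sd = tr.std(axis=0, ddof=0)
    constant = sd == 0
    scale = np.where(constant, 1.0, sd)
    params = {
        "median": med,
        "mean": np.where(constant, 0.0, mean),
        "scale": scale,
        "constant_columns": np.nonzero(constant)[0],
    }
    tr_out = (tr - params["mean"]) / scale
    if other is None:
        return tr_out, None, params
    other = np.asarray(other, dtype=float)
    ot = np.where(np.isnan(other), med, other)
    return tr_out, (ot - params["mean"]) / scale, params


def _make_model(kind: str, params: dict, seed: int):
    if kind == "svm_poly2":
        return SVC(
            kernel="poly",
            degree=2,
            gamma=params.get("gamma", "scale"),
            coef0=params.get("coef0", 1.0),
            C=params.get("C", 1.0),
            random_state=seed,
        )
    if kind == "knn":
        return KNeighborsClassifier(n_neighbors=params.get("k_neighbors", 5), metric="euclidean")
    if kind == "dtree":
        return DecisionTreeClassifier(random_state=seed, **params)
    raise ValueError(f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}")


def train_predict(
    model: str,
    train: np.ndarray,
    train_labels: Sequence[str],
    test: np.ndarray,
    params: dict | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Fit one classifier on (already standardized) train data, predict test.

    Deterministic given seed and params.  Exactly two classes must be
    present in the training labels.
    """
    y = np.asarray(train_labels)
    if np.unique(y).size != 2:
        raise ValueError("binary labels required: training folds must contain both classes")
    clf = _make_model(model, params or {}, seed)
    clf.fit(np.asarray(train, dtype=float), y)
    return clf.predict(np.asarray(test, dtype=float))


def confusion_metrics(
    y_true: Sequence[str], y_pred: Sequence[str], positive_label: str = POSITIVE_LABEL
) -> Metrics:
    """Confusion counts with ``positive_label`` as the positive class."""
    yt, yp = np.asarray(y_true), np.asarray(y_pred)
    if yt.shape != yp.shape:
        raise ValueError("label arrays must have equal length")
    labels = set(np.unique(yt)) | set(np.unique(yp))
    if len(labels - {positive_label}) > 1:
        raise ValueError(f"labels {sorted(labels)} are not binary with positive {positive_label!r}")
    pos_t, pos_p = yt == positive_label, yp == positive_label
    return Metrics(
        TP=int(np.sum(pos_t & pos_p)),
        FP=int(np.sum(~pos_t & pos_p)),
        TN=int(np.sum(~pos_t & ~pos_p)),
        FN=int(np.sum(pos_t & ~pos_p)),
    )


def evaluate_cv(
    features: np.ndarray,
    labels: Sequence[str],
    model: str = "svm_poly2",
    k: int = 5,
    seed: int = 0,
    params: dict | None = None,
) -> CVReport:
    """Stratified k-fold cross-validation with leakage-free standardization.

    For every fold: impute + z-score with train statistics only, fit,
    predict the held-out fold.  Confusion counts are pooled across folds
    (every sample predicted exactly once); per-fold metrics are also
    reported.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    assignment = stratified_kfold(y, k, seed)
    fold_metrics = []
    pooled = np.zeros(4, dtype=int)  # TP FP TN FN
    for fold in range(k):
        test_mask = assignment.fold_of == fold
        tr, te, _ = standardize(X[~test_mask], X[test_mask])
        pred = train_predict(model, tr, y[~test_mask], te, params, seed)
        m = confusion_metrics(y[test_mask], pred)
        fold_metrics.append(m)
        pooled += np.array([m.TP, m.FP, m.TN, m.FN])
    return CVReport(
        model, tuple(fold_metrics), Metrics(*map(int, pooled)), k, seed, dict(params or {})
    )
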