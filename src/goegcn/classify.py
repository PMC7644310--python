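"""Imbalanced binary-classification harness for validating gene signatures.

Repeated stratified k-fold cross-validation over any classifier exposing
the ``fit`` / ``predict`` / ``score_samples`` contract, with SMOTE
oversampling of the minority class applied to the training portion of
each fold only — synthetic samples never reach a held-out fold. Metrics
are the usual confusion-matrix five (sensitivity, specificity,
accuracy, precision, F1) plus the rank-based AUC.

A Gaussian naive-Bayes reference classifier is built in; scikit-learn
estimators plug in directly (``predict_proba`` is used for scores).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold


@dataclass
class ConfusionMatrix:
    """2x2 counts with the positive label recorded."""

    tp: int
    fp: int
    fn: int
    tn: int
    positive_label: str = "experiment"

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be >= 0")
        if self.total == 0:
            raise ValueError("confusion matrix must contain at least one sample")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn,
                               self.positive_label)


@dataclass
class MetricsReport:
    """Mean metrics over folds x repeats, with the per-fold trail kept."""

    sensitivity: float
    specificity: float
    accuracy: float
    precision: float
    f1: float
    auc: float
    per_fold: dict[str, list[float]] = field(default_factory=dict)
    confusion: ConfusionMatrix | None = None

    def to_dict(self) -> dict:
        d = {
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "accuracy": self.accuracy, "precision": self.precision,
            "f1": self.f1, "auc": self.auc,
            "per_fold": self.per_fold,
        }
        if self.confusion is not None:
            d["confusion"] = {"tp": self.confusion.tp, "fp": self.confusion.fp,
                              "fn": self.confusion.fn, "tn": self.confusion.tn,
                              "positive_label": self.confusion.positive_label}
        return d


def metrics_from_confusion(cm: ConfusionMatrix) -> dict[str, float]:
    """Sensitivity, specificity, accuracy, precision and F1 from 2x2 counts.

    A metric whose denominator is zero is reported as NaN (flagged
    undefined) rather than silently zeroed.
    """
    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else math.nan

    sens = ratio(cm.tp, cm.tp + cm.fn)
    spec = ratio(cm.tn, cm.tn + cm.fp)
    acc = ratio(cm.tp + cm.tn, cm.total)
    prec = ratio(cm.tp, cm.tp + cm.fp)
    if math.isnan(prec) or math.isnan(sens) or prec + sens == 0:
        f1 = math.nan
    else:
        f1 = 2.0 * prec * sens / (prec + sens)
    return {"sensitivity": sens, "specificity": spec, "accuracy": acc,
            "precision": prec, "f1": f1}


def auc_mann_whitney(scores, y) -> float:
    """Rank-based AUC: P(score_pos > score_neg) with half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    pos = scores[y == 1]
    neg = scores[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)  # average ranks handle ties
    u = ranks[y == 1].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def smote(minority: np.ndarray, k: int, n_new: int,
          rng: np.random.Generator | int) -> np.ndarray:
    """Synthetic minority oversampling by segment interpolation.

    Each synthetic row is x + u * (x_nn - x) for a uniformly chosen
    minority row x, one of its k nearest minority neighbours x_nn
    (Euclidean; k is capped at |minority| - 1) and u ~ Uniform(0, 1).
    """
    minority = np.asarray(minority, dtype=float)
    if minority.ndim != 2 or minority.shape[0] < 2:
        raise ValueError("SMOTE needs >= 2 minority samples")
    if k < 1:
        raise ValueError("k must be >= 1")
    if n_new == 0:
        return np.empty((0, minority.shape[1]))
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    m = minority.shape[0]
    k = min(k, m - 1)
    d2 = ((minority[:, None, :] - minority[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    nn = np.argsort(d2, axis=1, kind="stable")[:, :k]

    base = rng.integers(0, m, size=n_new)
    pick = rng.integers(0, k, size=n_new)
    u = rng.uniform(0.0, 1.0, size=n_new)
    x = minority[base]
    x_nn = minority[nn[base, pick]]
    return x + u[:, None] * (x_nn - x)


class GaussianNBClassifier:
    """Gaussian naive Bayes, the built-in reference classifier.

    ``fit`` estimates per-class feature means and variances (variance
    floor 1e-9); ``score_samples`` returns the posterior log-odds of the
    positive class and ``predict`` its argmax.
    """

    def __init__(self, var_floor: float = 1e-9) -> None:
        self.var_floor = var_floor

    def fit(self, X, y) -> "GaussianNBClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError(f"need exactly 2 classes to fit, got {len(classes)}")
        self.classes_ = classes
        self.theta_, self.var_, self.log_prior_ = [], [], []
        for c in classes:
            xc = X[y == c]
            self.theta_.append(xc.mean(axis=0))
            self.var_.append(np.maximum(xc.var(axis=0), self.var_floor))
            self.log_prior_.append(np.log(len(xc) / len(X)))
        return self

    def _joint_log_likelihood(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        jll = np.empty((X.shape[0], 2))
        for i in range(2):
            mu, var = self.theta_[i], self.var_[i]
            jll[:, i] = self.log_prior_[i] - 0.5 * np.sum(
                np.log(2.0 * np.pi * var) + (X - mu) ** 2 / var, axis=1)
        return jll

    def score_samples(self, X) -> np.ndarray:
        jll = self._joint_log_likelihood(X)
        return jll[:, 1] - jll[:, 0]  # log-odds of classes_[1]

    def predict(self, X) -> np.ndarray:
        jll = self._joint_log_likelihood(X)
        return self.classes_[np.argmax(jll, axis=1)]


def _scores(clf, X) -> np.ndarray:
    if hasattr(clf, "score_samples"):
        return np.asarray(clf.score_samples(X), dtype=float)
    if hasattr(clf, "predict_proba"):
        return np.asarray(clf.predict_proba(X), dtype=float)[:, 1]
    if hasattr(clf, "decision_function"):
        return np.asarray(clf.decision_function(X), dtype=float)
    raise TypeError("classifier exposes neither score_samples, predict_proba "
                    "nor decision_function")


def repeated_stratified_cv(X, y, classifier_factory=GaussianNBClassifier,
                           folds: int = 5, repeats: int = 100,
                           use_smote: bool = True, smote_k: int = 5,
                           rng_seed: int = 1) -> MetricsReport:
    """Repeated stratified k-fold CV with in-fold SMOTE.

    ``y`` is binary with 1 the positive (experiment) class. Per fold the
    classifier is trained on the training portion — after SMOTE brings
    the minority class to parity when ``use_smote`` — and evaluated on
    the untouched held-out fold. Metrics are averaged over all folds of
    all repeats (undefined folds are skipped per metric); confusion
    counts are summed within each repeat and reported as the per-repeat
    mean, rounded to the aggregate over one repeat.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("y must contain both classes, coded 0/1")
    class_counts = np.bincount(y, minlength=2)
    if class_counts.min() < folds:
        raise ValueError(
            f"cannot stratify {folds} folds: minority class has {class_counts.min()} samples")
    rng = np.random.default_rng(rng_seed)

    metric_names = ("sensitivity", "specificity", "accuracy", "precision", "f1", "auc")
    per_fold: dict[str, list[float]] = {m: [] for m in metric_names}
    total_cm: ConfusionMatrix | None = None

    for _ in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=int(rng.integers(0, 2**31 - 1)))
        repeat_cm: ConfusionMatrix | None = None
        for train_idx, test_idx in skf.split(X, y):
            X_tr, y_tr = X[train_idx], y[train_idx]
            if use_smote:
                n_pos, n_neg = int((y_tr == 1).sum()), int((y_tr == 0).sum())
                if n_pos != n_neg:
                    min_lab = 1 if n_pos < n_neg else 0
                    deficit = abs(n_neg - n_pos)
                    synth = smote(X_tr[y_tr == min_lab], smote_k, deficit, rng)
                    X_tr = np.vstack([X_tr, synth])
                    y_tr = np.concatenate([y_tr, np.full(deficit, min_lab)])
            clf = classifier_factory()
            clf.fit(X_tr, y_tr)
            y_te = y[test_idx]
            pred = np.asarray(clf.predict(X[test_idx]), dtype=int)
            cm = ConfusionMatrix(
                tp=int(((pred == 1) & (y_te == 1)).sum()),
                fp=int(((pred == 1) & (y_te == 0)).sum()),
                fn=int(((pred == 0) & (y_te == 1)).sum()),
                tn=int(((pred == 0) & (y_te == 0)).sum()),
            )
            repeat_cm = cm if repeat_cm is None else repeat_cm + cm
            fold_metrics = metrics_from_confusion(cm)
            for m in ("sensitivity", "specificity", "accuracy", "precision", "f1"):
                per_fold[m].append(fold_metrics[m])
            scores = _scores(clf, X[test_idx])
            if len(np.unique(y_te)) == 2:
                per_fold["auc"].append(auc_mann_whitney(scores, y_te))
            else:
                per_fold["auc"].append(math.nan)
        total_cm = repeat_cm if total_cm is None else total_cm + repeat_cm

    means = {m: float(np.nanmean(per_fold[m])) if np.isfinite(per_fold[m]).any()
             else math.nan for m in metric_names}
    return MetricsReport(confusion=total_cm, per_fold=per_fold, **means)
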