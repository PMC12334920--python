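"""Train/test split, the four reference classifiers, and evaluation metrics.

The verification task is a binary pair classification: label 1 (identical
twins) is the positive class, label 0 (same person) the negative.  Four
model families sit behind one fit/predict/score contract -- an RBF-kernel
support vector machine, two gradient-boosted tree ensembles (LightGBM and
XGBoost), and a nearest-centroid classifier -- all fed standardized features
(train-set mean/SD) and library-default hyperparameters with a fixed seed
(no tuning).  Metrics follow the standard confusion-matrix formulas:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    precision   = TP / (TP + FP)
    recall      = TP / (TP + FN)          (sensitivity, TPR)
    specificity = TN / (TN + FP)          (TNR)
    F1          = 2 TP / (2 TP + FP + FN)

and AUC is the trapezoidal area under the ROC curve swept over all score
thresholds, with tied scores grouped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler

from .config import MODEL_KINDS
from .errors import (
    SingleClassTraining,
    TooFewRows,
    UndefinedMetricWarning,
)
from .pipeline import BOOKKEEPING_COLUMNS, FeatureTable


@dataclass(frozen=True)
class ConfusionMatrix:
    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion-matrix cells must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    auc: float | None = None

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "specificity": self.specificity,
            "f1": self.f1, "auc": self.auc,
        }


@dataclass(frozen=True)
class SplitConfig:
    test_fraction: float = 0.20
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")


def _frame_of(table) -> pd.DataFrame:
    return table.frame if isinstance(table, FeatureTable) else table


def split_train_test(table, cfg: SplitConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic (optionally stratified) train/test split.

    The test set has round(test_fraction * n) rows; stratification preserves
    class proportions within one row.
    """
    frame = _frame_of(table)
    n = len(frame)
    n_test = int(round(cfg.test_fraction * n))
    if n_test < 1 or n - n_test < 1:
        raise TooFewRows(f"cannot split {n} rows at fraction {cfg.test_fraction}")
    strat = None
    if cfg.stratified:
        counts = frame["label"].value_counts()
        if (counts < 2).any():
            raise TooFewRows("stratified split needs >= 2 rows per class")
        strat = frame["label"]
    train, test = train_test_split(
        frame, test_size=n_test, random_state=cfg.seed, stratify=strat, shuffle=True
    )
    return train.reset_index(drop=True), test.reset_index(drop=True)


def _feature_matrix(frame: pd.DataFrame) -> np.ndarray:
    cols = [c for c in frame.columns if c not in BOOKKEEPING_COLUMNS]
    return frame[cols].to_numpy(dtype=float)


class PairClassifier:
    """Uniform fit/predict/score wrapper over the four reference model kinds.

    ``score`` returns a real-valued twin-likelihood: the SVM's decision
    function, the tree ensembles' positive-class probability, and for the
    nearest-centroid model the difference of distances to the two class
    centroids (distance-to-0 minus distance-to-1, higher = more twin-like).
    """

    def __init__(self, model_kind: str = "MAX_MARGIN_KERNEL", seed: int = 0) -> None:
        if model_kind not in MODEL_KINDS:
            raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
        self.model_kind = model_kind
        self.seed = seed
        self.scaler = StandardScaler()
        self._model = self._build()

    def _build(self):
        if self.model_kind == "MAX_MARGIN_KERNEL":
            from sklearn.svm import SVC

            return SVC(kernel="rbf", random_state=self.seed)
        if self.model_kind == "GRADIENT_BOOSTED_TREES_A":
            from lightgbm import LGBMClassifier

            return LGBMClassifier(random_state=self.seed, verbose=-1)
        if self.model_kind == "GRADIENT_BOOSTED_TREES_B":
            from xgboost import XGBClassifier

            return XGBClassifier(random_state=self.seed, verbosity=0)
        self._centroids = None
        return None  # nearest centroid is computed directly

    def fit(self, table) -> "PairClassifier":
        frame = _frame_of(table)
        y = frame["label"].to_numpy(dtype=int)
        if len(np.unique(y)) < 2:
            raise SingleClassTraining("training data contains a single class")
        X = self.scaler.fit_transform(_feature_matrix(frame))
        if self.model_kind == "NEAREST_CENTROID":
            self._centroids = {c: X[y == c].mean(axis=0) for c in (0, 1)}
        else:
            self._model.fit(X, y)
        return self

    def _transformed(self, table) -> np.ndarray:
        return self.scaler.transform(_feature_matrix(_frame_of(table)))

    def score(self, table) -> np.ndarray:
        """Real-valued scores; higher means more twin-like (class 1)."""
        X = self._transformed(table)
        if self.model_kind == "NEAREST_CENTROID":
            d0 = np.linalg.norm(X - self._centroids[0], axis=1)
            d1 = np.linalg.norm(X - self._centroids[1], axis=1)
            return d0 - d1
        if self.model_kind == "MAX_MARGIN_KERNEL":
            return self._model.decision_function(X)
        return self._model.predict_proba(X)[:, 1]

    def predict(self, table) -> np.ndarray:
        X = self._transformed(table)
        if self.model_kind == "NEAREST_CENTROID":
            return (self.score(_frame_of(table)) > 0).astype(int)
        return self._model.predict(X).astype(int)


def train_classifier(train, model_kind: str = "MAX_MARGIN_KERNEL",
                     seed: int = 0) -> PairClassifier:
    return PairClassifier(model_kind=model_kind, seed=seed).fit(train)


def predict(model: PairClassifier, rows) -> np.ndarray:
    return model.predict(rows)


def score(model: PairClassifier, rows) -> np.ndarray:
    return model.score(rows)


# -- metrics ------------------------------------------------------------------

def confusion(labels_true, labels_pred) -> ConfusionMatrix:
    """Confusion matrix with label 1 (twin pair) as the positive class."""
    yt = np.asarray(labels_true, dtype=int)
    yp = np.asarray(labels_pred, dtype=int)
    if yt.shape != yp.shape:
        raise ValueError("label vectors must have equal length")
    if not set(np.unique(np.concatenate([yt, yp]))) <= {0, 1}:
        raise ValueError("labels must be 0 or 1")
    return ConfusionMatrix(
        TP=int(np.sum((yt == 1) & (yp == 1))),
        FP=int(np.sum((yt == 0) & (yp == 1))),
        FN=int(np.sum((yt == 1) & (yp == 0))),
        TN=int(np.sum((yt == 0) & (yp == 0))),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reported as NaN",
                      UndefinedMetricWarning, stacklevel=3)
        return float("nan")
    return num / den


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, precision, recall, specificity, F1 from a confusion matrix.

    Zero-denominator metrics are reported as NaN with a warning, never
    silently as 0.
    """
    return MetricsReport(
        accuracy=_ratio(cm.TP + cm.TN, cm.total, "accuracy"),
        precision=_ratio(cm.TP, cm.TP + cm.FP, "precision"),
        recall=_ratio(cm.TP, cm.TP + cm.FN, "recall"),
        specificity=_ratio(cm.TN, cm.TN + cm.FP, "specificity"),
        f1=_ratio(2 * cm.TP, 2 * cm.TP + cm.FP + cm.FN, "f1"),
    )


def roc_curve_points(labels_true, scores) -> tuple[np.ndarray, np.ndarray]:
    """ROC curve (FPR, TPR) swept over all thresholds, tied scores grouped."""
    yt = np.asarray(labels_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    if yt.shape != s.shape:
        raise ValueError("labels and scores must have equal length")
    P = int(np.sum(yt == 1))
    N = int(np.sum(yt == 0))
    if P == 0 or N == 0:
        warnings.warn("ROC undefined with a single class; reported as NaN",
                      UndefinedMetricWarning, stacklevel=2)
        return np.array([np.nan]), np.array([np.nan])
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = yt[order]
    tp = np.cumsum(y_sorted == 1)
    fp = np.cumsum(y_sorted == 0)
    # keep only the last index of each tied-score run
    last_of_tie = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tpr = np.r_[0.0, tp[last_of_tie] / P]
    fpr = np.r_[0.0, fp[last_of_tie] / N]
    return fpr, tpr


def roc_auc(labels_true, scores) -> tuple[tuple[np.ndarray, np.ndarray], float]:
    """ROC curve and its trapezoidal area."""
    fpr, tpr = roc_curve_points(labels_true, scores)
    if np.isnan(fpr).any():
        return (fpr, tpr), float("nan")
    auc = float(np.trapezoid(tpr, fpr))
    return (fpr, tpr), auc


def evaluate(model: PairClassifier, test) -> tuple[ConfusionMatrix, MetricsReport]:
    """Confusion matrix and full metrics report (including AUC) on a test set."""
    frame = _frame_of(test)
    yt = frame["label"].to_numpy(dtype=int)
    cm = confusion(yt, model.predict(frame))
    base = metrics(cm)
    _, auc = roc_auc(yt, model.score(frame))
    return cm, MetricsReport(accuracy=base.accuracy, precision=base.precision,
                             recall=base.recall, specificity=base.specificity,
                             f1=base.f1, auc=auc)
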