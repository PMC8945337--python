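"""Leave-one-out discrimination of caffeine vs. placebo energy points.

The classifier bank mirrors the eleven-model comparison used for
group-level energy profiles: two decision trees (both capped at 150
splits), three polynomial-kernel SVMs (box constraints 5/3/2 for degrees
1/2/3), cosine and cubic-Minkowski 3-NN, linear and quadratic discriminant
analysis, logistic regression, and an ROC-threshold classifier ("X-ROC")
reconstructed as the training-accuracy-optimal scalar threshold
(equivalently the Youden-J point of the empirical ROC), with ties broken
by the largest margin to the nearest training points, then by the smaller
threshold.

All models are evaluated with leave-one-out cross-validation: n folds,
each training on n−1 points and predicting the held-out one. Accuracy is
the percentage of correctly predicted folds. A training fold that contains
a single class predicts that class (logged, never a crash).

Notes on degenerate geometry: with one-dimensional features the cosine
distance collapses to sign (dis)agreement, and the "fine" and "medium"
trees coincide because both carry the same split cap. Both facts are
inherited from the comparison being reconstructed and are documented
rather than patched.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassifierSpec:
    """A named classifier family plus its fixed hyperparameters."""

    family: str
    hyperparameters: dict = field(default_factory=dict)
    display_name: str = ""
    display_params: str = ""


#: The fixed bank, in its canonical reporting order.
CLASSIFIER_BANK: tuple[ClassifierSpec, ...] = (
    ClassifierSpec("fine_tree", {"max_splits": 150}, "Fine Tree",
                   "Maximum number of splits = 150"),
    ClassifierSpec("medium_tree", {"max_splits": 150}, "Medium Tree",
                   "Maximum number of splits = 150"),
    ClassifierSpec("svm_linear", {"box_constraint": 5.0}, "SVM Linear Kernel",
                   "Box constraint level = 5"),
    ClassifierSpec("svm_quadratic", {"box_constraint": 3.0}, "SVM Quadratic Kernel",
                   "Box constraint level = 3"),
    ClassifierSpec("svm_cubic", {"box_constraint": 2.0}, "SVM Cubic Kernel",
                   "Box constraint level = 2"),
    ClassifierSpec("knn_cosine", {"n_neighbors": 3}, "Cosine KNN",
                   "Number of neighbors = 3"),
    ClassifierSpec("knn_cubic", {"n_neighbors": 3}, "Cubic KNN",
                   "Number of neighbors = 3"),
    ClassifierSpec("lda", {}, "Discriminant Linear", "Covariance structure: Full"),
    ClassifierSpec("logistic", {}, "Logistic", "Covariance structure: Full"),
    ClassifierSpec("qda", {}, "Discriminant Quadratic", "Covariance structure: Full"),
    ClassifierSpec("xroc", {}, "XROC", "-"),
)


class XROCClassifier(BaseEstimator, ClassifierMixin):
    """ROC-optimal scalar-threshold binary classifier.

    Sweeps every midpoint of adjacent sorted training values in both
    polarities and keeps the pair maximizing training accuracy; ties are
    broken by the largest margin to the nearest training value, then by
    the smaller threshold. If all feature values coincide there is no
    separating threshold and the classifier predicts the training
    majority (lexicographically smaller label on a tie).
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 1:
            if X.ndim != 2 or X.shape[1] != 1:
                raise ValueError("X-ROC is defined for scalar (1-D) features only")
            X = X[:, 0]
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size > 2:
            raise ValueError("X-ROC is a binary classifier")

        # majority fallback; np.unique sorts, so ties pick the smaller label
        counts = np.array([np.sum(y == c) for c in self.classes_])
        self.majority_ = self.classes_[int(np.argmax(counts))]
        self.threshold_ = None
        if self.classes_.size == 1:
            return self

        values = np.sort(np.unique(X))
        if values.size == 1:
            return self  # degenerate: constant feature, majority prediction

        best = None  # key = (accuracy, margin, -threshold)
        for thr in (values[:-1] + values[1:]) / 2.0:
            margin = float(np.min(np.abs(X - thr)))
            for hi_idx in (0, 1):
                high, low = self.classes_[hi_idx], self.classes_[1 - hi_idx]
                pred = np.where(X >= thr, high, low)
                acc = float(np.mean(pred == y))
                key = (acc, margin, -thr)
                if best is None or key > best[0]:
                    best = (key, float(thr), high)
        self.threshold_ = best[1]
        self.high_class_ = best[2]
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 2:
            X = X[:, 0]
        if self.threshold_ is None or self.classes_.size == 1:
            return np.full(X.shape[0], self.majority_)
        low = [c for c in self.classes_ if c != self.high_class_][0]
        return np.where(X >= self.threshold_, self.high_class_, low)


def train_xroc(X, y) -> tuple[float | None, object]:
    """Fit the X-ROC rule and return ``(threshold, class_predicted_at_or_above)``.

    A ``None`` threshold marks the degenerate constant-feature case, where
    the rule falls back to majority prediction.
    """
    model = XROCClassifier().fit(X, y)
    if model.threshold_ is None:
        return None, model.majority_
    return model.threshold_, model.high_class_


def make_classifier(spec: ClassifierSpec, seed: int = 0):
    """Instantiate the scikit-learn (or in-package) estimator for a spec."""
    hp = spec.hyperparameters
    family = spec.family
    if family in ("fine_tree", "medium_tree"):
        # a cap of k splits bounds the tree at k+1 leaves
        return DecisionTreeClassifier(
            max_leaf_nodes=hp.get("max_splits", 150) + 1, random_state=seed
        )
    if family == "svm_linear":
        return SVC(kernel="linear", C=hp.get("box_constraint", 1.0))
    if family == "svm_quadratic":
        return SVC(kernel="poly", degree=2, gamma=1.0, coef0=1.0,
                   C=hp.get("box_constraint", 1.0))
    if family == "svm_cubic":
        return SVC(kernel="poly", degree=3, gamma=1.0, coef0=1.0,
                   C=hp.get("box_constraint", 1.0))
    if family == "knn_cosine":
        return KNeighborsClassifier(
            n_neighbors=hp.get("n_neighbors", 3), metric="cosine", algorithm="brute"
        )
    if family == "knn_cubic":
        return KNeighborsClassifier(
            n_neighbors=hp.get("n_neighbors", 3), metric="minkowski", p=3
        )
    if family == "lda":
        return LinearDiscriminantAnalysis()
    if family == "qda":
        return QuadraticDiscriminantAnalysis()
    if family == "logistic":
        return LogisticRegression(max_iter=1000)
    if family == "xroc":
        return XROCClassifier()
    raise ValueError(f"unknown classifier family {family!r}")


@dataclass
class LabeledPoints:
    """Feature matrix (points × dimensions) with binary group labels."""

    features: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.ndim == 1:
            self.features = self.features[:, np.newaxis]
        self.labels = np.asarray(self.labels)
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("features and labels disagree in length")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features must be finite")
        classes, counts = np.unique(self.labels, return_counts=True)
        if classes.size != 2 or counts.min() < 2:
            raise ValueError("need two classes with at least 2 points each for LOOCV")


@dataclass
class LoocvResult:
    """Outcome of one leave-one-out evaluation."""

    accuracy: float  # percent
    per_fold_predictions: np.ndarray
    classifier: ClassifierSpec


def loocv(data: LabeledPoints, spec: ClassifierSpec, seed: int = 0) -> LoocvResult:
    """Leave-one-out cross-validation of one classifier spec.

    Deterministic given data, spec and seed. A single-class training fold
    predicts its sole class.
    """
    X, y = data.features, data.labels
    n = X.shape[0]
    base = make_classifier(spec, seed=seed)
    preds = np.empty(n, dtype=y.dtype)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        y_train = y[mask]
        classes = np.unique(y_train)
        if classes.size == 1:
            logger.warning("fold %d has a single training class; predicting it", i)
            preds[i] = classes[0]
            continue
        model = clone(base)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # QDA collinearity on tiny folds
                model.fit(X[mask], y_train)
                preds[i] = model.predict(X[i : i + 1])[0]
        except (ValueError, np.linalg.LinAlgError) as exc:
            # degenerate fold (e.g. one sample left in a class for QDA):
            # fall back to the training majority, like the single-class policy
            logger.warning("fold %d: %s; predicting training majority", i, exc)
            values, counts = np.unique(y_train, return_counts=True)
            preds[i] = values[int(np.argmax(counts))]
    accuracy = 100.0 * float(np.mean(preds == y))
    return LoocvResult(accuracy=accuracy, per_fold_predictions=preds, classifier=spec)


def run_classifier_bank(
    data_per_modality: dict[str, LabeledPoints], seed: int = 0
) -> pd.DataFrame:
    """LOOCV accuracy of the full bank on each modality's labeled points.

    Returns a table with one row per classifier (bank order) and one
    accuracy column per modality, mirroring the canonical comparison
    layout.
    """
    rows = []
    for spec in CLASSIFIER_BANK:
        row: dict[str, object] = {
            "classifier": spec.display_name,
            "optimal_parameters": spec.display_params,
        }
        for modality, data in data_per_modality.items():
            row[f"acc_{modality.lower()}"] = loocv(data, spec, seed=seed).accuracy
        rows.append(row)
    return pd.DataFrame(rows)


def bank_mean_accuracy(table: pd.DataFrame) -> dict[str, float]:
    """Mean accuracy over the bank for each modality column of a results table."""
    return {
        col[len("acc_") :].upper(): float(table[col].mean())
        for col in table.columns
        if col.startswith("acc_")
    }
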