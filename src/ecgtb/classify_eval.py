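"""Training and evaluation of the study's five classifiers on one scalar feature.

Each evaluated cell trains k-nearest neighbours (k=10), a one-hidden-layer
(10-neuron) feedforward neural net, a quadratic-kernel SVM, a Gini decision
tree capped at 100 splits, and a Gaussian-kernel-density naive Bayes on a
single feature column, and reports

* the mean F1 over 10 stratified cross-validation folds of the 70% training
  split, and
* the F1 on the 30% held-out test split from a model refit on the full
  training split,

with the abnormal class (AF/PVC/APB) as the F1 positive class.  Features are
not standardized by default (a first-class switch, since it materially
affects KNN and the SVM).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.stats import gaussian_kde
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "CLASSIFIER_KINDS",
    "ClassifierSpec",
    "EvalResult",
    "f1_score",
    "f1_from_predictions",
    "stratified_split",
    "make_classifier",
    "train_eval",
    "best_threshold_f1",
]

#: Canonical classifier order (used for tie-breaking in reports).
CLASSIFIER_KINDS = ("knn", "neural_net", "svm_quadratic", "tree", "naive_bayes_kernel")


@dataclass(frozen=True)
class ClassifierSpec:
    """One of the five study classifiers with its fixed hyperparameters."""

    kind: str
    knn_k: int = 10
    hidden_neurons: int = 10
    svm_degree: int = 2
    tree_max_splits: int = 100
    standardize: bool = False

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"kind must be one of {CLASSIFIER_KINDS}")


@dataclass
class EvalResult:
    """F1 outcomes of one (trial, variant, feature, transform, classifier) cell."""

    classifier: str
    cv_f1_mean: float
    test_f1: float
    n_train: int
    n_test: int
    retained_fraction: float = 1.0
    degenerate: bool = False
    extra: dict[str, Any] = field(default_factory=dict)


def f1_score(tp: int, fp: int, fn: int) -> float:
    """Harmonic mean of precision and recall from confusion counts.

    0 when TP = 0 with errors present; NaN when all three counts are 0.
    """
    if tp < 0 or fp < 0 or fn < 0:
        raise ValueError("confusion counts must be non-negative")
    if tp == 0:
        return float("nan") if fp == 0 and fn == 0 else 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2.0 * recall * precision / (recall + precision)


def f1_from_predictions(y_true: np.ndarray, y_pred: np.ndarray, positive) -> float:
    tp = int(np.sum((y_pred == positive) & (y_true == positive)))
    fp = int(np.sum((y_pred == positive) & (y_true != positive)))
    fn = int(np.sum((y_pred != positive) & (y_true == positive)))
    return f1_score(tp, fp, fn)


def stratified_split(
    values, labels, test_fraction: float = 0.30, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic stratified 70/30 split; returns (train_idx, test_idx).

    Per-class test counts are rounded half-up, so 135 samples contribute 41
    test rows.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie strictly between 0 and 1")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 members")
        idx = rng.permutation(idx)
        n_test = int(np.floor(test_fraction * len(idx) + 0.5))  # round half-up
        n_test = min(max(n_test, 1), len(idx) - 1)
        test_idx.append(idx[:n_test])
        train_idx.append(idx[n_test:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


class KernelDensityNB(BaseEstimator, ClassifierMixin):
    """Naive Bayes with Gaussian kernel-density class conditionals.

    Unbounded support, Scott's-rule bandwidth; a zero-variance class falls
    back to a narrow Gaussian around its single support point.
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self._kdes = {}
        self._priors = {}
        scale = np.std(X) or 1.0
        for cls in self.classes_:
            vals = X[y == cls].ravel()
            self._priors[cls] = len(vals) / len(y)
            if len(vals) < 2 or np.std(vals) == 0:
                center = vals.mean() if len(vals) else 0.0
                self._kdes[cls] = ("degenerate", center, 1e-3 * scale)
            else:
                self._kdes[cls] = ("kde", gaussian_kde(vals), None)
        return self

    def _log_density(self, cls, x: np.ndarray) -> np.ndarray:
        kind, obj, width = self._kdes[cls]
        if kind == "degenerate":
            return -0.5 * ((x - obj) / width) ** 2 - np.log(width)
        with np.errstate(divide="ignore"):
            return np.log(np.maximum(obj(x), 1e-300))

    def predict(self, X):
        x = np.asarray(X, dtype=float).ravel()
        scores = np.stack(
            [self._log_density(c, x) + np.log(self._priors[c]) for c in self.classes_]
        )
        return self.classes_[np.argmax(scores, axis=0)]


def make_classifier(spec: ClassifierSpec, seed: int = 0):
    """Instantiate the sklearn (or in-package) estimator for ``spec``."""
    if spec.kind == "knn":
        return KNeighborsClassifier(n_neighbors=spec.knn_k)
    if spec.kind == "neural_net":
        # lbfgs: full-batch quasi-Newton, converges reliably on these tiny
        # 1-D problems where first-order stochastic training underfits
        return MLPClassifier(
            hidden_layer_sizes=(spec.hidden_neurons,),
            activation="logistic",
            solver="lbfgs",
            max_iter=500,
            random_state=seed,
        )
    if spec.kind == "svm_quadratic":
        # iteration cap: heavily overlapping 1-D cells otherwise stall libsvm
        return SVC(
            kernel="poly",
            degree=spec.svm_degree,
            coef0=1.0,
            gamma="scale",
            max_iter=100_000,
        )
    if spec.kind == "tree":
        # max_leaf_nodes = splits + 1 caps the number of decision splits
        return DecisionTreeClassifier(
            criterion="gini", max_leaf_nodes=spec.tree_max_splits + 1, random_state=seed
        )
    if spec.kind == "naive_bayes_kernel":
        return KernelDensityNB()
    raise ValueError(f"unknown classifier kind {spec.kind!r}")


def _fit_predict(spec: ClassifierSpec, seed, X_tr, y_tr, X_te) -> np.ndarray:
    """Fit and predict; numerically unfittable cells fall back to majority vote.

    Extreme transformed features (e.g. cubes spanning ~1e12) can make the
    SVM's dual problem non-finite; that cell degrades to the majority rule
    rather than aborting the study grid.
    """
    clf = make_classifier(spec, seed)
    mu, sd = 0.0, 1.0
    if spec.standardize:
        mu = X_tr.mean()
        sd = X_tr.std() or 1.0
    Xt = ((X_tr - mu) / sd).reshape(-1, 1)
    Xe = ((X_te - mu) / sd).reshape(-1, 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            clf.fit(Xt, y_tr)
            return np.asarray(clf.predict(Xe))
        except (ValueError, FloatingPointError, np.linalg.LinAlgError):
            return _majority_predict(y_tr, len(X_te))


def _majority_predict(y_tr: np.ndarray, n: int) -> np.ndarray:
    vals, cnt = np.unique(y_tr, return_counts=True)
    return np.full(n, vals[np.argmax(cnt)])


def train_eval(
    train: tuple[np.ndarray, np.ndarray],
    test: tuple[np.ndarray, np.ndarray],
    spec: ClassifierSpec,
    positive_class,
    cv_folds: int = 10,
    seed: int = 0,
) -> EvalResult:
    """Cross-validated and held-out F1 for one classifier on one feature.

    Degenerate training data (a single class, or a constant feature) yields a
    majority-vote fallback flagged ``degenerate`` rather than an exception.
    """
    X_tr, y_tr = np.asarray(train[0], float), np.asarray(train[1])
    X_te, y_te = np.asarray(test[0], float), np.asarray(test[1])
    n_classes = len(np.unique(y_tr))
    degenerate = n_classes < 2 or np.std(X_tr) == 0

    if degenerate:
        pred_te = _majority_predict(y_tr, len(y_te))
        return EvalResult(
            classifier=spec.kind,
            cv_f1_mean=float("nan"),
            test_f1=f1_from_predictions(y_te, pred_te, positive_class),
            n_train=len(y_tr),
            n_test=len(y_te),
            degenerate=True,
        )

    min_class = np.unique(y_tr, return_counts=True)[1].min()
    n_splits = int(min(cv_folds, min_class))
    fold_f1: list[float] = []
    if n_splits >= 2:
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        for fold, (tr, va) in enumerate(skf.split(X_tr.reshape(-1, 1), y_tr)):
            pred = _fit_predict(spec, seed + fold, X_tr[tr], y_tr[tr], X_tr[va])
            fold_f1.append(f1_from_predictions(y_tr[va], pred, positive_class))
    cv_mean = float(np.nanmean(fold_f1)) if fold_f1 else float("nan")

    pred_te = _fit_predict(spec, seed, X_tr, y_tr, X_te)
    return EvalResult(
        classifier=spec.kind,
        cv_f1_mean=cv_mean,
        test_f1=f1_from_predictions(y_te, pred_te, positive_class),
        n_train=len(y_tr),
        n_test=len(y_te),
        extra={"cv_folds_used": n_splits if n_splits >= 2 else 0},
    )


def best_threshold_f1(values: np.ndarray, labels: np.ndarray, positive) -> float:
    """Best achievable F1 of a single-threshold rule (both directions).

    Brute-force sweep over all sample midpoints; the oracle for
    monotone-transform sanity checks (rank-preserving transforms leave this
    quantity unchanged).
    """
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    order = np.argsort(values, kind="stable")
    v, y = values[order], labels[order]
    candidates = np.concatenate(([v[0] - 1.0], (v[1:] + v[:-1]) / 2.0, [v[-1] + 1.0]))
    best = 0.0
    for thr in candidates:
        for direction in (1, -1):
            pred_pos = (v > thr) if direction == 1 else (v <= thr)
            tp = int(np.sum(pred_pos & (y == positive)))
            fp = int(np.sum(pred_pos & (y != positive)))
            fn = int(np.sum(~pred_pos & (y == positive)))
            f1 = f1_score(tp, fp, fn)
            if not np.isnan(f1):
                best = max(best, f1)
    return best
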