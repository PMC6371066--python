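"""Cross-validated risk stratification of participant-days.

The protocol mirrors a train-validate-test design: complete-case
assembly over the 53-variable registry, a stratified 90:10 split,
stratified 10-fold cross-validation of five classifier families (RBF
SVM, decision tree, random forest, AdaBoost, XGBoost) plus a 3-of-5
majority-vote ensemble, and confusion-matrix metric reporting with the
positive class D-ML (imputed PHQ-9 >= 5).

Hyperparameters are library defaults with a fixed seed; the
cross-validation interval is mean +/- 1.96 * SD of the fold accuracies
(configurable), which reproduces the width scale of fold-dispersion
intervals commonly reported alongside a CV mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from daysense.registry import DEFAULT_REGISTRY

logger = logging.getLogger(__name__)

POSITIVE_LABEL = "D-ML"
NEGATIVE_LABEL = "ND-ML"

BASE_METHODS = ("svm_rbf", "decision_tree", "random_forest", "xgboost", "adaboost")
ALL_METHODS = BASE_METHODS + ("voting_ensemble",)


@dataclass
class ConfusionMatrix:
    """Binary confusion counts with positive class D-ML."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class Metrics:
    """Percent metrics derived from a confusion matrix."""

    accuracy: float
    precision: float
    recall: float
    specificity: float


@dataclass
class ClassifierReport:
    """Cross-validation and held-out-test results for one method."""

    method: str
    fold_accuracies: list[float]
    cv_mean: float
    cv_ci: tuple[float, float]
    test_confusion: ConfusionMatrix
    metrics: Metrics
    train_confusion_refit: ConfusionMatrix | None = None
    train_confusion_cv: ConfusionMatrix | None = None

    def to_dict(self) -> dict:
        out = {
            "method": self.method,
            "fold_accuracies": [round(a, 4) for a in self.fold_accuracies],
            "cv_mean": round(self.cv_mean, 4),
            "cv_ci": [round(self.cv_ci[0], 4), round(self.cv_ci[1], 4)],
            "test_confusion": vars(self.test_confusion),
            "metrics": {k: (None if np.isnan(v) else round(v, 4)) for k, v in vars(self.metrics).items()},
        }
        if self.train_confusion_refit is not None:
            out["train_confusion_refit"] = vars(self.train_confusion_refit)
        if self.train_confusion_cv is not None:
            out["train_confusion_cv"] = vars(self.train_confusion_cv)
        return out


def make_classifier(method: str, seed: int):
    """A freshly constructed estimator with library-default hyperparameters."""
    if method == "svm_rbf":
        return SVC(kernel="rbf", random_state=seed)
    if method == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if method == "random_forest":
        return RandomForestClassifier(random_state=seed)
    if method == "adaboost":
        return AdaBoostClassifier(random_state=seed)
    if method == "xgboost":
        return XGBClassifier(random_state=seed, eval_metric="logloss")
    raise ValueError(f"unknown method {method!r}; supported: {ALL_METHODS}")


def assemble_dataset(
    instances: pd.DataFrame, registry=DEFAULT_REGISTRY
) -> tuple[pd.DataFrame, np.ndarray]:
    """Complete-case feature matrix and 0/1 labels (1 = D-ML).

    An instance missing *any* registered variable, or its label, is
    dropped entirely; no imputation is performed.
    """
    registry = list(registry)
    labeled = instances[instances["ml_class"].isin([POSITIVE_LABEL, NEGATIVE_LABEL])]
    X = labeled[registry].astype(float)
    complete = ~X.isna().any(axis=1)
    X = X.loc[complete].reset_index(drop=True)
    y = (labeled.loc[complete.to_numpy(), "ml_class"] == POSITIVE_LABEL).to_numpy().astype(int)
    if len(X) == 0:
        raise ValueError("no complete-case instances remain after filtering")
    logger.info(
        "assembled %d complete-case instances of %d (%d positive)",
        len(X), len(instances), int(y.sum()),
    )
    return X, y


def stratified_split(
    X: pd.DataFrame, y: np.ndarray, test_fraction: float = 0.10, seed: int = 0
):
    """Stratified train/test split preserving class proportions.

    Returns (X_train, X_test, y_train, y_test); deterministic under
    ``seed``.  Requires at least 2 instances of each class.
    """
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present to stratify")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 instances to stratify")
    n_test = int(round(len(y) * test_fraction))  # test size = round(N * fraction)
    return train_test_split(
        X, y, test_size=n_test, stratify=y, random_state=seed, shuffle=True
    )


def _accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    return 100.0 * float(np.mean(y_true == y_pred))


def _fit_predict(method: str, X_tr, y_tr, X_va, seed: int) -> np.ndarray:
    if method == "voting_ensemble":
        preds = [_fit_predict(m, X_tr, y_tr, X_va, seed) for m in BASE_METHODS]
        return majority_vote(preds)
    clf = make_classifier(method, seed)
    clf.fit(np.asarray(X_tr, dtype=float), y_tr)
    return clf.predict(np.asarray(X_va, dtype=float))


def stratified_kfold_cv(
    X: pd.DataFrame, y: np.ndarray, method: str, k: int = 10, seed: int = 0,
    return_predictions: bool = False,
):
    """Fold accuracies (%) of a stratified K-fold cross-validation.

    Every instance validates exactly once; each fold's class ratio
    stays within one instance of the overall ratio.  With
    ``return_predictions`` the pooled out-of-fold predictions are also
    returned (aligned with ``y``).
    """
    _, counts = np.unique(y, return_counts=True)
    if len(counts) < 2 or counts.min() < k:
        raise ValueError(f"each class needs at least k={k} instances for stratified {k}-fold CV")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    Xa = np.asarray(X, dtype=float)
    accuracies = []
    oof = np.full(len(y), -1, dtype=int)
    for train_idx, val_idx in skf.split(Xa, y):
        pred = _fit_predict(method, Xa[train_idx], y[train_idx], Xa[val_idx], seed)
        oof[val_idx] = pred
        accuracies.append(_accuracy(y[val_idx], pred))
    folds = np.array(accuracies)
    if return_predictions:
        return folds, oof
    return folds


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return ConfusionMatrix(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def train_and_test(method: str, X_train, y_train, X_test, y_test, seed: int = 0) -> ConfusionMatrix:
    """Fit on the full training set, evaluate once on the held-out test set."""
    if method not in ALL_METHODS:
        raise ValueError(f"unknown method {method!r}; supported: {ALL_METHODS}")
    pred = _fit_predict(method, X_train, y_train, X_test, seed)
    return _confusion(y_test, pred)


def majority_vote(predictions) -> np.ndarray:
    """Per-instance majority label across exactly five aligned prediction vectors."""
    preds = [np.asarray(p) for p in predictions]
    if len(preds) != 5:
        raise ValueError("majority vote requires exactly 5 prediction sequences")
    lengths = {len(p) for p in preds}
    if len(lengths) != 1:
        raise ValueError("prediction sequences must be aligned (equal lengths)")
    stacked = np.stack(preds)
    if stacked.dtype.kind in "iub":
        return (stacked.sum(axis=0) >= 3).astype(stacked.dtype)
    # generic labels: column-wise mode (majority of 5 is unique for binary labels)
    out = []
    for col in stacked.T:
        labels, counts = np.unique(col, return_counts=True)
        out.append(labels[np.argmax(counts)])
    return np.array(out)


def metrics_from_confusion(cm: ConfusionMatrix) -> Metrics:
    """Accuracy, precision, recall and specificity in percent.

    Ratios with a zero denominator are returned as missing (NaN); an
    all-zero matrix is an error.
    """
    if cm.total == 0:
        raise ValueError("confusion matrix has no evaluated instances")

    def ratio(num: int, den: int) -> float:
        return 100.0 * num / den if den else np.nan

    return Metrics(
        accuracy=ratio(cm.tp + cm.tn, cm.total),
        precision=ratio(cm.tp, cm.tp + cm.fp),
        recall=ratio(cm.tp, cm.tp + cm.fn),
        specificity=ratio(cm.tn, cm.tn + cm.fp),
    )


def ci_from_folds(fold_accuracies, z: float = 1.96) -> tuple[float, float]:
    """Fold-dispersion interval: mean +/- z * SD of fold accuracies, clipped to [0, 100]."""
    folds = np.asarray(fold_accuracies, dtype=float)
    if len(folds) < 2:
        raise ValueError("at least 2 folds are required")
    mean = folds.mean()
    sd = folds.std(ddof=1)
    return (float(max(mean - z * sd, 0.0)), float(min(mean + z * sd, 100.0)))


def run_classification(
    instances: pd.DataFrame,
    registry=DEFAULT_REGISTRY,
    seed: int = 0,
    methods=ALL_METHODS,
    k: int = 10,
    test_fraction: float = 0.10,
) -> dict[str, ClassifierReport]:
    """The full train-validate-test protocol for every requested method.

    Training confusion counts are reported in both of the two natural
    readings: refit on the whole training set and predicted back on it
    (``train_confusion_refit``), and pooled out-of-fold CV predictions
    (``train_confusion_cv``).
    """
    X, y = assemble_dataset(instances, registry)
    X_train, X_test, y_train, y_test = stratified_split(X, y, test_fraction, seed)
    logger.info("split: %d training / %d test instances", len(X_train), len(X_test))
    reports: dict[str, ClassifierReport] = {}
    for method in methods:
        folds, oof = stratified_kfold_cv(X_train, y_train, method, k=k, seed=seed, return_predictions=True)
        test_cm = train_and_test(method, X_train, y_train, X_test, y_test, seed)
        refit_pred = _fit_predict(method, X_train, y_train, X_train, seed)
        reports[method] = ClassifierReport(
            method=method,
            fold_accuracies=list(folds),
            cv_mean=float(folds.mean()),
            cv_ci=ci_from_folds(folds),
            test_confusion=test_cm,
            metrics=metrics_from_confusion(test_cm),
            train_confusion_refit=_confusion(y_train, refit_pred),
            train_confusion_cv=_confusion(y_train, oof),
        )
        logger.info(
            "%s: CV %.1f%%, test accuracy %.1f%%",
            method, reports[method].cv_mean, reports[method].metrics.accuracy,
        )
    return reports


def report_table(reports: dict[str, ClassifierReport]) -> pd.DataFrame:
    """Human-readable comparison table, metrics to one decimal."""
    rows = []
    for method, rep in reports.items():
        m = rep.metrics
        rows.append(
            {
                "method": method,
                "cv_accuracy_pct": round(rep.cv_mean, 1),
                "cv_ci_low_pct": round(rep.cv_ci[0], 1),
                "cv_ci_high_pct": round(rep.cv_ci[1], 1),
                "test_accuracy_pct": round(m.accuracy, 1),
                "precision_pct": round(m.precision, 1) if not np.isnan(m.precision) else np.nan,
                "recall_pct": round(m.recall, 1) if not np.isnan(m.recall) else np.nan,
                "specificity_pct": round(m.specificity, 1) if not np.isnan(m.specificity) else np.nan,
                "test_tp": rep.test_confusion.tp,
                "test_tn": rep.test_confusion.tn,
                "test_fp": rep.test_confusion.fp,
                "test_fn": rep.test_confusion.fn,
            }
        )
    return pd.DataFrame(rows)
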