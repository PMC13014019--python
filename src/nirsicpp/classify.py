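"""Dataset splitting, classifier tuning and the study's evaluation metrics.

Five classical families are tuned by exhaustive grid search with 10-fold
cross-validation on the training split: max-margin (SVM), decision tree,
random forest, linear discriminant analysis, and k-nearest neighbors.
Evaluation reports the confusion matrix with ICPP (label 1) as the
positive class, accuracy, specificity (TN-based, for the normal class) and
class-weighted precision/recall/F1, all as percentages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "SplitSpec",
    "EvalReport",
    "FAMILIES",
    "DEFAULT_GRIDS",
    "split_dataset",
    "tune_and_train",
    "evaluate",
    "weighted_metrics",
]

POSITIVE_LABEL = 1  # ICPP
FAMILIES = ("max-margin", "tree", "forest", "discriminant", "nearest-neighbor")

# The study reports no grids; these are conventional search spaces for the
# five families at this feature dimensionality.
DEFAULT_GRIDS = {
    "max-margin": {"clf__C": [0.1, 1.0, 10.0], "clf__kernel": ["linear", "rbf"],
                   "clf__gamma": ["scale"]},
    "tree": {"clf__max_depth": [2, 3, 5, None], "clf__min_samples_leaf": [1, 3, 5]},
    "forest": {"clf__n_estimators": [50, 100], "clf__max_depth": [3, 5, None]},
    "discriminant": {"clf__shrinkage": [None, "auto"], "clf__solver": ["lsqr"]},
    "nearest-neighbor": {"clf__n_neighbors": [3, 5, 7], "clf__weights": ["uniform", "distance"]},
}


@dataclass(frozen=True)
class SplitSpec:
    """Train/test partition policy.

    ``unit='subject'`` keeps a subject's trials together (the default, to
    prevent within-subject leakage across the two trials); ``unit='trial'``
    mirrors the study's trial-level 8:2 division.
    """

    train_fraction: float = 0.8
    seed: int = 0
    unit: str = "subject"

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.unit not in ("trial", "subject"):
            raise ValueError("unit must be 'trial' or 'subject'")


def split_dataset(
    X: np.ndarray,
    y: np.ndarray,
    spec: SplitSpec,
    subject_ids: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded shuffle-and-partition returning (train_idx, test_idx).

    Train size is ⌊train_fraction·n⌋ (of trials, or of subjects for the
    subject unit); the remainder is the test set. If a plain shuffle
    strands a class in one partition, the draw is redone with per-class
    stratification.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 samples to split")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(spec.seed)
    if spec.unit == "subject":
        if subject_ids is None:
            raise ValueError("subject-unit split requires subject_ids")
        subject_ids = np.asarray(subject_ids)
        subjects = np.unique(subject_ids)
        subj_label = {s: y[subject_ids == s][0] for s in subjects}
        units = subjects
        unit_labels = np.array([subj_label[s] for s in subjects])
    else:
        units = np.arange(n)
        unit_labels = y

    def expand(chosen_units: np.ndarray) -> np.ndarray:
        if spec.unit == "subject":
            mask = np.isin(subject_ids, chosen_units)
            return np.flatnonzero(mask)
        return np.asarray(chosen_units)

    n_units = len(units)
    n_train = int(np.floor(spec.train_fraction * n_units))
    perm = rng.permutation(n_units)
    train_units, test_units = units[perm[:n_train]], units[perm[n_train:]]

    def ok(u_train, u_test) -> bool:
        lt = unit_labels[np.isin(units, u_train)]
        le = unit_labels[np.isin(units, u_test)]
        return len(np.unique(lt)) == 2 and len(np.unique(le)) == 2

    if not ok(train_units, test_units):
        # stratified redraw: split each class's units at the same fraction
        train_list, test_list = [], []
        for cls in np.unique(unit_labels):
            cls_units = units[unit_labels == cls]
            k = int(np.floor(spec.train_fraction * len(cls_units)))
            k = min(max(k, 1), len(cls_units) - 1)
            p = rng.permutation(len(cls_units))
            train_list.append(cls_units[p[:k]])
            test_list.append(cls_units[p[k:]])
        train_units = np.concatenate(train_list)
        test_units = np.concatenate(test_list)
    return expand(train_units), expand(test_units)


def _make_estimator(family: str, seed: int) -> Pipeline:
    if family == "max-margin":
        clf = SVC(random_state=seed)
    elif family == "tree":
        clf = DecisionTreeClassifier(random_state=seed)
    elif family == "forest":
        clf = RandomForestClassifier(random_state=seed)
    elif family == "discriminant":
        clf = LinearDiscriminantAnalysis()
    elif family == "nearest-neighbor":
        clf = KNeighborsClassifier()
    else:
        raise ValueError(f"unknown classifier family {family!r}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def tune_and_train(
    X_train: np.ndarray,
    y_train: np.ndarray,
    family: str,
    grid: Optional[dict] = None,
    n_folds: int = 10,
    seed: int = 0,
):
    """Exhaustive grid search scored by mean CV accuracy, refit on all data.

    Folds are stratified; if the training set cannot support the requested
    fold count the count is reduced with a warning. Ties keep the first
    configuration in grid order. Returns (fitted model, best params, best
    CV accuracy).
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train)
    grid = DEFAULT_GRIDS[family] if grid is None else grid
    if not grid:
        raise ValueError("empty hyperparameter grid")
    min_class = int(np.bincount(y_train.astype(int)).min())
    folds = min(n_folds, min_class, len(y_train))
    if folds < n_folds:
        warnings.warn(f"reducing CV folds from {n_folds} to {folds} (small training set)")
    if folds < 2:
        raise ValueError("training set too small for cross-validation")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    search = GridSearchCV(
        _make_estimator(family, seed), param_grid=grid, scoring="accuracy",
        cv=cv, n_jobs=1, refit=True,
    )
    search.fit(X_train, y_train)
    return search.best_estimator_, search.best_params_, float(search.best_score_)


@dataclass(frozen=True)
class EvalReport:
    """Test-set confusion counts and percentage metrics (ICPP positive)."""

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    precision_weighted: float
    recall_weighted: float
    f1_weighted: float
    specificity: float
    model_id: str = ""
    feature_set: str = ""

    @property
    def n_test(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def weighted_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    """Confusion counts plus the study's percentage metrics.

    Accuracy = (TP+TN)/n; specificity = TN/(TN+FP) for the normal class;
    precision/recall/F1 are computed per class and averaged with weights
    equal to the true class counts. All values are percentages.
    """
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValueError("prediction/label length mismatch")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    n = len(y_true)
    if tn + fp == 0 or tp + fn == 0:
        raise ValueError("single-class test set: specificity/recall undefined")
    accuracy = (tp + tn) / n

    def per_class(cls: int) -> tuple[float, float, float]:
        tpos = int(np.sum((y_true == cls) & (y_pred == cls)))
        ppos = int(np.sum(y_pred == cls))
        apos = int(np.sum(y_true == cls))
        prec = tpos / ppos if ppos else 0.0
        rec = tpos / apos if apos else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        return prec, rec, f1

    weights = {cls: np.sum(y_true == cls) / n for cls in (0, 1)}
    prec_w = rec_w = f1_w = 0.0
    for cls in (0, 1):
        p, r, f = per_class(cls)
        prec_w += weights[cls] * p
        rec_w += weights[cls] * r
        f1_w += weights[cls] * f
    return {
        "tp": tp, "tn": tn, "fp": fp, "fn": fn,
        "accuracy": 100.0 * accuracy,
        "precision_weighted": 100.0 * prec_w,
        "recall_weighted": 100.0 * rec_w,
        "f1_weighted": 100.0 * f1_w,
        "specificity": 100.0 * tn / (tn + fp),
    }


def evaluate(model, X_test: np.ndarray, y_test: np.ndarray,
             model_id: str = "", feature_set: str = "") -> EvalReport:
    """Score a fitted model on the held-out test set."""
    y_pred = model.predict(np.asarray(X_test, dtype=float))
    m = weighted_metrics(y_test, y_pred)
    return EvalReport(model_id=model_id, feature_set=feature_set, **m)
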