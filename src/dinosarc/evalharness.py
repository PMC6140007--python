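"""Evaluation protocol: detector metrics and cross-validated classification.

Detector metrics follow the tuning criterion used for the salient point
detector: an abnormal image counts as a *false-negative image* when no
detected point falls inside any of its lesion masks; the *true-positive
point fraction* is the percentage of detected points lying inside lesion
masks, pooled over all abnormal images.

Classification uses stratified k-fold cross-validation with an RBF-kernel
SVM.  Hyperparameters (C, gamma) default to a nested grid search inside
each training fold, so no information leaks from held-out folds; decision
scores are pooled over the held-out folds and summarized by ROC analysis
(AUC) plus accuracy/sensitivity/specificity at decision threshold 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .detector import SalientPoint
from .errors import DataError, DomainError, ParameterError

__all__ = ["DetectorMetrics", "ClassificationReport", "detector_metrics", "crossval_classify"]

#: Default nested hyperparameter grid for the RBF-SVM.
DEFAULT_C_GRID = tuple(2.0 ** np.arange(-3, 6))
DEFAULT_GAMMA_GRID = tuple(2.0 ** np.arange(-7, 2))


@dataclass(frozen=True)
class DetectorMetrics:
    """Point-detector performance against ground-truth lesion masks."""

    n_images: int
    n_abnormal: int
    false_negative_images: int
    tp_point_fraction: float  # percent, pooled over abnormal images
    avg_points_per_image: float


@dataclass(frozen=True)
class ClassificationReport:
    """Pooled cross-validation results of the RBF-SVM classifier."""

    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    roc_points: tuple  # ordered (FPR, TPR) pairs
    fold_assignments: np.ndarray
    scores: np.ndarray = field(repr=False)
    confusion: dict = field(default_factory=dict)  # tp/fp/tn/fn at threshold 0
    seed: int = 0


def _is_abnormal(label) -> bool:
    if isinstance(label, str):
        return label == "abnormal"
    return bool(label)


def detector_metrics(
    points_per_image: Sequence[Sequence[SalientPoint]],
    masks: Sequence[Optional[np.ndarray]],
    labels: Sequence,
) -> DetectorMetrics:
    """Count false-negative images and true-positive points.

    Parameters
    ----------
    points_per_image
        Detected points for each image.
    masks
        Binary lesion masks aligned with the images (None allowed for
        normal images; required for abnormal ones).
    labels
        Per-image 'normal'/'abnormal' strings (or booleans, True=abnormal).
    """
    if not (len(points_per_image) == len(masks) == len(labels)):
        raise DataError("points, masks and labels must have equal length")
    n_images = len(labels)
    fn_images = 0
    n_abnormal = 0
    tp_points = 0
    abnormal_points = 0
    total_points = 0
    for points, mask, label in zip(points_per_image, masks, labels):
        total_points += len(points)
        if not _is_abnormal(label):
            continue
        n_abnormal += 1
        if mask is None:
            raise DataError("abnormal image without a lesion mask")
        in_mask = sum(1 for p in points if mask[p.row, p.col])
        tp_points += in_mask
        abnormal_points += len(points)
        if in_mask == 0:
            fn_images += 1
    if abnormal_points == 0:
        if n_abnormal:
            warnings.warn(
                "no points detected on any abnormal image; "
                "tp_point_fraction reported as 0",
                stacklevel=2,
            )
        tp_fraction = 0.0
    else:
        tp_fraction = 100.0 * tp_points / abnormal_points
    return DetectorMetrics(
        n_images=n_images,
        n_abnormal=n_abnormal,
        false_negative_images=fn_images,
        tp_point_fraction=tp_fraction,
        avg_points_per_image=total_points / n_images if n_images else 0.0,
    )


def _make_estimator(svm_params, standardize: bool):
    if svm_params is not None:
        c, gamma = svm_params
        clf = SVC(kernel="rbf", C=c, gamma=gamma)
    else:
        clf = GridSearchCV(
            SVC(kernel="rbf"),
            param_grid={"C": list(DEFAULT_C_GRID), "gamma": list(DEFAULT_GAMMA_GRID)},
            cv=3,
            scoring="roc_auc",
            n_jobs=1,
        )
    steps = ([("scale", StandardScaler())] if standardize else []) + [("svm", clf)]
    return Pipeline(steps)


def crossval_classify(
    features: np.ndarray,
    labels: Sequence,
    folds: int = 10,
    seed: int = 0,
    svm_params: Optional[tuple[float, float]] = None,
    standardize: bool = False,
) -> ClassificationReport:
    """Stratified k-fold RBF-SVM classification with pooled ROC analysis.

    ``svm_params=(C, gamma)`` skips the nested grid search.  Any
    standardization is fitted on training folds only.  Deterministic for a
    fixed (seed, data, params).
    """
    X = np.asarray(features, dtype=float)
    y = np.array([1 if _is_abnormal(l) else 0 for l in labels], dtype=int)
    if folds < 2:
        raise ParameterError("folds must be >= 2")
    classes = np.unique(y)
    if classes.size != 2:
        raise DomainError("both classes must be present")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = np.empty(len(y), dtype=float)
    fold_ids = np.empty(len(y), dtype=int)
    for fold, (train, test) in enumerate(skf.split(X, y)):
        est = _make_estimator(svm_params, standardize)
        est.fit(X[train], y[train])
        scores[test] = est.decision_function(X[test])
        fold_ids[test] = fold
    fpr, tpr, _ = roc_curve(y, scores)
    auc_value = float(_trapezoid_auc(fpr, tpr))
    pred = (scores >= 0.0).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    return ClassificationReport(
        auc=auc_value,
        accuracy=(tp + tn) / len(y),
        sensitivity=tp / (tp + fn) if (tp + fn) else 0.0,
        specificity=tn / (tn + fp) if (tn + fp) else 0.0,
        roc_points=tuple(zip(fpr.tolist(), tpr.tolist())),
        fold_assignments=fold_ids,
        scores=scores,
        confusion={"tp": tp, "fp": fp, "tn": tn, "fn": fn},
        seed=seed,
    )
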