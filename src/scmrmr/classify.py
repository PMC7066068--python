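"""Cross-validated margin classification and confusion-matrix metrics.

The classifier contract mirrors the default configuration of the classical
SVM implementations: radial-basis kernel, cost 1, kernel width equal to the
reciprocal of the number of features, and features standardized on the
training fold only.  Leave-one-out cross-validation (LOOCV) predicts every
cell exactly once with a model that never saw it; seeded stratified k-fold
is offered as a scalable stand-in on large matrices.

Panel quality is summarized by the Matthews correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

which stays informative under the strong class imbalance typical of
tumor-core vs periphery designs; the convention MCC := 0 applies when any
factor under the root is zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import LeaveOneOut, StratifiedKFold, cross_val_predict
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io import ExpressionMatrix, LabelVector

RECIPROCAL_N_FEATURES = "reciprocal_n_features"


@dataclass(frozen=True)
class ClassifierSpec:
    kernel: str = "rbf"
    cost: float = 1.0
    gamma: float | str = RECIPROCAL_N_FEATURES
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.kernel not in ("rbf", "linear"):
            raise ValueError(f"unsupported kernel {self.kernel!r}")
        if self.cost <= 0:
            raise ValueError("cost must be positive")
        if isinstance(self.gamma, str):
            if self.gamma != RECIPROCAL_N_FEATURES:
                raise ValueError(f"unknown gamma setting {self.gamma!r}")
        elif self.gamma <= 0:
            raise ValueError("gamma must be positive")

    def build(self):
        gamma = "auto" if self.gamma == RECIPROCAL_N_FEATURES else self.gamma
        svc = SVC(kernel=self.kernel, C=self.cost, gamma=gamma)
        if self.standardize:
            return Pipeline([("scale", StandardScaler()), ("svm", svc)])
        return svc


@dataclass(frozen=True)
class CVScheme:
    """LOOCV or seeded stratified k-fold; LOOCV is k-fold with k = N."""

    kind: str = "loocv"
    k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("loocv", "stratified_kfold"):
            raise ValueError(f"unknown CV kind {self.kind!r}")
        if self.kind == "stratified_kfold" and self.k < 2:
            raise ValueError("k must be >= 2")

    def splitter(self):
        if self.kind == "loocv":
            return LeaveOneOut()
        return StratifiedKFold(n_splits=self.k, shuffle=True, random_state=self.seed)


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def cross_validated_predictions(
    matrix: ExpressionMatrix,
    labels: LabelVector,
    gene_ids: list[str],
    spec: ClassifierSpec = ClassifierSpec(),
    cv: CVScheme = CVScheme(),
) -> np.ndarray:
    """Out-of-fold predicted labels (boolean, True = positive) per cell.

    Each cell is predicted exactly once by a model trained without it;
    standardization parameters are fitted on the training fold only.
    """
    if not gene_ids:
        raise ValueError("gene set must be non-empty")
    labels.require_both_classes()
    min_class = min(labels.n_positive, labels.n_negative)
    needed = 2 if cv.kind == "loocv" else cv.k
    if min_class < needed:
        raise ValueError(
            f"smallest class has {min_class} cells; {cv.kind} needs at least "
            f"{needed} — use stratified_kfold with smaller k or more data"
        )
    X = matrix.subset_genes(gene_ids).values.T  # cells x genes
    y = labels.labels.astype(int)
    pred = cross_val_predict(spec.build(), X, y, cv=cv.splitter(), n_jobs=None)
    return pred.astype(bool)


def confusion(
    predicted: np.ndarray, actual: np.ndarray, positive=True, negative=None
) -> ConfusionMatrix:
    """Tally a confusion matrix from predicted and actual label vectors.

    Any label other than ``positive`` counts as negative; if ``negative``
    is given, a value outside the pair is an error.  The default boolean
    convention (True = positive) matches the predictions returned by
    :func:`cross_validated_predictions`.
    """
    predicted = np.asarray(predicted)
    actual = np.asarray(actual)
    if predicted.shape != actual.shape:
        raise ValueError(f"length mismatch: {predicted.shape} vs {actual.shape}")
    if negative is None and isinstance(positive, (bool, np.bool_)):
        negative = not positive
    if negative is not None:
        seen = set(np.unique(predicted)) | set(np.unique(actual))
        extra = seen - {positive, negative}
        if extra:
            raise ValueError(
                f"labels outside {{{positive!r}, {negative!r}}}: {sorted(map(repr, extra))}"
            )
    p = predicted == positive
    a = actual == positive
    return ConfusionMatrix(
        tp=int((p & a).sum()),
        fp=int((p & ~a).sum()),
        tn=int((~p & ~a).sum()),
        fn=int((~p & a).sum()),
    )


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient in [-1, 1]; 0 on degenerate margins.

    The numerator and the product under the root are computed in exact
    integer arithmetic before the final division, so large confusion
    matrices lose no precision.
    """
    tp, fp, tn, fn = cm.tp, cm.fp, cm.tn, cm.fn
    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom2 == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom2)


def sensitivity(cm: ConfusionMatrix) -> float:
    """TP / (TP + FN) — the fraction of actual positives recovered."""
    if cm.tp + cm.fn == 0:
        raise ValueError("no actual positives: sensitivity undefined")
    return cm.tp / (cm.tp + cm.fn)


def specificity(cm: ConfusionMatrix) -> float:
    """TN / (TN + FP) — the fraction of actual negatives recovered."""
    if cm.tn + cm.fp == 0:
        raise ValueError("no actual negatives: specificity undefined")
    return cm.tn / (cm.tn + cm.fp)


def accuracy(cm: ConfusionMatrix) -> float:
    """(TP + TN) / N."""
    if cm.n == 0:
        raise ValueError("empty confusion matrix: accuracy undefined")
    return (cm.tp + cm.tn) / cm.n
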