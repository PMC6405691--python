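"""Binary-classifier evaluation: confusion statistics, ROC/AUC, 5-fold CV.

The six summary statistics are computed from the 2x2 confusion counts:

    accuracy    = (TP + TN) / (TP + FP + TN + FN)
    specificity = TN / (TN + FP)              (true negative rate)
    precision   = TP / (TP + FP)              (positive predictive value)
    recall      = TP / (TP + FN)              (sensitivity, TPR)
    F1          = 2 * precision * recall / (precision + recall)
                = 2 TP / (2 TP + FP + FN)
    MCC         = (TP*TN - FP*FN) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN))

Any statistic whose denominator is zero is reported as 0 with a warning,
so a degenerate fold does not abort a cross-validation run.  ROC curves
use the standard convention (x = false positive rate, y = true positive
rate); the trapezoid-rule AUC equals the Mann-Whitney pairwise
concordance probability with half-credit for ties.

:func:`cross_validate` implements the evaluation protocol used for the
deep-forest pipeline: split into five non-overlapping, size-balanced
random parts; per fold, optionally fit PCA on the training part only
(``pca_scope="global"`` reproduces whole-dataset fitting at the cost of
information leakage), fit the deep forest on four parts and score the
held-out part.  Both per-fold and pooled statistics are reported, since
either convention may be wanted.  A radial-basis-kernel SVM (default
C = 0.3, gamma = 1000) is provided as the comparison baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass

import numpy as np
from sklearn import metrics as _skm
from sklearn.svm import SVC

from .features import apply_pca, fit_pca
from .gcforest import CascadeSpec, DeepForestClassifier, ScannerSpec

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "FoldAssignment",
    "confusion",
    "metrics",
    "roc_auc",
    "five_fold_split",
    "CrossValResult",
    "cross_validate",
    "svm_baseline",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 cross-tabulation of binary truth vs prediction."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn < 1:
            raise ValueError("confusion counts must cover at least one sample")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            tp=self.tp + other.tp,
            fp=self.fp + other.fp,
            tn=self.tn + other.tn,
            fn=self.fn + other.fn,
        )


@dataclass(frozen=True)
class MetricSet:
    """The six derived statistics; all but MCC lie in [0, 1], MCC in [-1, 1]."""

    accuracy: float
    specificity: float
    precision: float
    recall: float
    f1: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


@dataclass(frozen=True)
class FoldAssignment:
    """Mapping sample index -> fold id for a balanced k-fold partition."""

    fold_of: np.ndarray
    n_folds: int

    def indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == fold)


def _check_binary(y: np.ndarray, name: str) -> np.ndarray:
    y = np.asarray(y)
    if not np.isin(y, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 labels")
    return y.astype(int)


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Count TP/FP/TN/FN for binary labels (1 = positive)."""
    y_true = _check_binary(y_true, "y_true")
    y_pred = _check_binary(y_pred, "y_pred")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what}: zero denominator, reporting 0", RuntimeWarning, stacklevel=3)
        return 0.0
    return num / den


def metrics(c: ConfusionCounts) -> MetricSet:
    """The six statistics from confusion counts (zero denominators -> 0)."""
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    accuracy = _safe_div(tp + tn, tp + fp + tn + fn, "accuracy")
    specificity = _safe_div(tn, tn + fp, "specificity")
    precision = _safe_div(tp, tp + fp, "precision")
    recall = _safe_div(tp, tp + fn, "recall")
    f1 = _safe_div(2 * tp, 2 * tp + fp + fn, "f1")
    mcc_den = float(tp + fn) * (tn + fp) * (tp + fp) * (tn + fn)
    mcc = _safe_div(tp * tn - fp * fn, float(np.sqrt(mcc_den)), "mcc")
    return MetricSet(
        accuracy=accuracy,
        specificity=specificity,
        precision=precision,
        recall=recall,
        f1=f1,
        mcc=mcc,
    )


def roc_auc(y_true, scores) -> tuple[np.ndarray, float]:
    """ROC curve points and trapezoid AUC from a threshold sweep.

    Returns an ``(n_points, 2)`` array of (FPR, TPR) pairs and the AUC.
    Tied scores contribute half credit, so the value coincides with the
    Mann-Whitney concordance probability.
    """
    y_true = _check_binary(y_true, "y_true")
    scores = np.asarray(scores, dtype=float)
    if np.unique(y_true).size < 2:
        raise ValueError("roc_auc requires both classes present")
    fpr, tpr, _ = _skm.roc_curve(y_true, scores)
    auc = float(_skm.auc(fpr, tpr))
    return np.column_stack([fpr, tpr]), auc


def five_fold_split(n: int, seed: int = 0, n_folds: int = 5) -> FoldAssignment:
    """Random partition into ``n_folds`` non-overlapping near-equal parts."""
    if n < n_folds:
        raise ValueError(f"need n >= {n_folds}, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    for fold, chunk in enumerate(np.array_split(perm, n_folds)):
        fold_of[chunk] = fold
    return FoldAssignment(fold_of=fold_of, n_folds=n_folds)


@dataclass(frozen=True)
class CrossValResult:
    """Per-fold and pooled statistics of one cross-validation run."""

    fold_metrics: tuple[MetricSet, ...]
    pooled: MetricSet
    pooled_counts: ConfusionCounts
    auc: float
    fold_assignment: FoldAssignment
    y_true: np.ndarray
    scores: np.ndarray  # pooled held-out P(class 1); NaN for skipped folds

    def as_dict(self) -> dict:
        return {
            "pooled": self.pooled.as_dict(),
            "auc": self.auc,
            "per_fold": [m.as_dict() for m in self.fold_metrics],
        }


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    scanner_spec: ScannerSpec | None = None,
    cascade_spec: CascadeSpec | None = None,
    n_folds: int = 5,
    seed: int = 0,
    pca_components: int | None = None,
    pca_scope: str = "train_only",
) -> CrossValResult:
    """K-fold protocol for the deep-forest pipeline.

    For each fold the remaining folds train the model (and, when
    ``pca_components`` is set, the PCA projection — on the training part
    only by default, or once on the whole dataset with
    ``pca_scope="global"``); the held-out fold is scored.  A training fold
    that degenerates to a single class is skipped with a warning.
    """
    if pca_scope not in ("train_only", "global"):
        raise ValueError(f"unknown pca_scope: {pca_scope!r}")
    X = np.asarray(X, dtype=float)
    y = _check_binary(y, "y")
    folds = five_fold_split(X.shape[0], seed=seed, n_folds=n_folds)
    rng = np.random.default_rng(seed)
    fold_seeds = rng.integers(0, 2**31 - 1, n_folds)

    if pca_components is not None and pca_scope == "global":
        model = fit_pca(X, n_components=pca_components)
        X_global = apply_pca(model, X)
    else:
        X_global = None

    fold_sets: list[MetricSet] = []
    pooled_counts: ConfusionCounts | None = None
    all_scores = np.full(X.shape[0], np.nan)
    for fold in range(n_folds):
        test_idx = folds.indices(fold)
        train_idx = np.flatnonzero(folds.fold_of != fold)
        if np.unique(y[train_idx]).size < 2:
            warnings.warn(f"fold {fold}: single-class training set, skipped", RuntimeWarning)
            continue
        if X_global is not None:
            Xtr, Xte = X_global[train_idx], X_global[test_idx]
        elif pca_components is not None:
            pca = fit_pca(X[train_idx], n_components=pca_components)
            Xtr, Xte = apply_pca(pca, X[train_idx]), apply_pca(pca, X[test_idx])
        else:
            Xtr, Xte = X[train_idx], X[test_idx]
        clf = DeepForestClassifier(scanner_spec, cascade_spec, seed=int(fold_seeds[fold]))
        clf.fit(Xtr, y[train_idx])
        proba = clf.predict_proba(Xte)
        pred = clf.cascade_.classes_[np.argmax(proba, axis=1)]
        all_scores[test_idx] = proba[:, int(np.flatnonzero(clf.cascade_.classes_ == 1)[0])]
        counts = confusion(y[test_idx], pred)
        fold_sets.append(metrics(counts))
        pooled_counts = counts if pooled_counts is None else pooled_counts + counts

    if pooled_counts is None:
        raise ValueError("all folds were degenerate; nothing evaluated")
    scored = ~np.isnan(all_scores)
    _, auc = roc_auc(y[scored], all_scores[scored])
    return CrossValResult(
        fold_metrics=tuple(fold_sets),
        pooled=metrics(pooled_counts),
        pooled_counts=pooled_counts,
        auc=auc,
        fold_assignment=folds,
        y_true=y,
        scores=all_scores,
    )


def svm_baseline(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    c: float = 0.3,
    g: float = 1000.0,
) -> tuple[MetricSet, np.ndarray]:
    """RBF-kernel SVM comparison baseline (default C = 0.3, gamma = 1000).

    Returns the test-set metrics and the predicted labels.
    """
    y_train = _check_binary(y_train, "y_train")
    if np.unique(y_train).size < 2:
        raise ValueError("svm_baseline requires both classes in the training set")
    clf = SVC(C=c, gamma=g, kernel="rbf")
    clf.fit(X_train, y_train)
    pred = clf.predict(X_test)
    return metrics(confusion(y_test, pred)), pred
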