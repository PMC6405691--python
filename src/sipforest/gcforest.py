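"""Deep-forest (cascade forest + multi-grained scanning) classifier.

The architecture is a tree-ensemble alternative to deep neural networks,
built from two stages:

* **Multi-grained scanning**: a sliding window cuts each feature vector
  into overlapping sub-vectors; every sub-vector inherits its sample's
  label and the pooled window instances train a small bank of forests.
  At transform time each window's class-probability vector, from each
  scanning forest, is concatenated into an augmented representation —
  for a 300-dim input, window 100 and stride 1 that is 201 windows x
  2 forests x 2 classes = 804 values.

* **Cascade forest**: an ordered stack of levels, each holding (by
  default) two Gini random forests and two complete-random tree forests.
  Each forest's per-sample class vector is estimated out-of-fold by
  k-fold cross-validation to limit over-fitting; the level's class
  vectors are appended to the augmented features to form the next
  level's input.  The cascade grows until a new level fails to improve
  the cross-validated accuracy over the best level so far by more than
  ``tolerance`` percentage points, and the best-scoring prefix of levels
  is retained.

A *complete-random tree* splits every internal node on a uniformly random
feature at a uniformly random cut between that feature's observed minimum
and maximum in the node, and grows until leaves are class-pure or hold at
most ``leaf_purity_stop`` instances; leaves store class-frequency vectors.
The Gini random forests delegate to scikit-learn with the candidate
feature count pinned to ``ceil(sqrt(d))``.

All randomness flows from explicit seeds, so fit and predict are bitwise
reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ForestSpec",
    "ScannerSpec",
    "CascadeSpec",
    "CompleteRandomTree",
    "CompleteRandomForest",
    "GiniRandomForest",
    "build_complete_random_tree",
    "FittedScanner",
    "fit_scanner",
    "scan_transform",
    "CascadeModel",
    "fit_cascade",
    "predict_cascade",
    "DeepForestClassifier",
    "make_two_class_features",
]


# --------------------------------------------------------------------------
# specs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ForestSpec:
    """Configuration of one forest in the scanner or cascade.

    ``kind`` is ``"random"`` (Gini splits over ceil(sqrt(d)) random
    candidate features) or ``"complete_random"``.  ``n_trees`` defaults to
    500; ``leaf_purity_stop`` is the largest impure leaf a complete-random
    tree may keep (default 10).
    """

    kind: str = "random"
    n_trees: int = 500
    leaf_purity_stop: int = 10

    def __post_init__(self) -> None:
        if self.kind not in ("random", "complete_random"):
            raise ValueError(f"unknown forest kind: {self.kind!r}")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.leaf_purity_stop < 1:
            raise ValueError("leaf_purity_stop must be >= 1")


@dataclass(frozen=True)
class ScannerSpec:
    """Sliding-window scanning stage: window length, stride, forest bank."""

    window: int = 100
    stride: int = 1
    forests: tuple[ForestSpec, ...] = (
        ForestSpec(kind="random"),
        ForestSpec(kind="complete_random"),
    )

    def __post_init__(self) -> None:
        if self.window < 1 or self.stride < 1:
            raise ValueError("window and stride must be >= 1")
        if not self.forests:
            raise ValueError("at least one scanning forest required")


@dataclass(frozen=True)
class CascadeSpec:
    """Cascade stage: forests per level, CV folds, growth tolerance."""

    forests_per_level: tuple[ForestSpec, ...] = (
        ForestSpec(kind="random"),
        ForestSpec(kind="random"),
        ForestSpec(kind="complete_random"),
        ForestSpec(kind="complete_random"),
    )
    cv_folds: int = 3
    tolerance: float = 5.0
    max_levels: int = 5

    def __post_init__(self) -> None:
        if not self.forests_per_level:
            raise ValueError("at least one forest per level required")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        if self.max_levels < 1:
            raise ValueError("max_levels must be >= 1")

    def with_trees(self, n_trees: int) -> "CascadeSpec":
        return replace(
            self,
            forests_per_level=tuple(replace(f, n_trees=n_trees) for f in self.forests_per_level),
        )


# --------------------------------------------------------------------------
# complete-random trees
# --------------------------------------------------------------------------

class CompleteRandomTree:
    """A single complete-random decision tree.

    Splits are entirely label-blind: a uniformly random non-constant
    feature and a uniformly random cut between its observed min and max at
    the node.  Growth stops when a node is class-pure, holds at most
    ``leaf_purity_stop`` instances, or has no non-constant feature left to
    split on.  Leaves store class-frequency vectors over ``classes_``.
    """

    def __init__(self, leaf_purity_stop: int = 10, seed: int = 0):
        self.leaf_purity_stop = leaf_purity_stop
        self.seed = seed

    def fit(self, X: np.ndarray, y: np.ndarray, classes: np.ndarray | None = None) -> "CompleteRandomTree":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one label per row")
        self.classes_ = np.asarray(classes) if classes is not None else np.unique(y)
        class_index = np.searchsorted(self.classes_, y)
        n_classes = self.classes_.size
        rng = np.random.default_rng(self.seed)

        feat: list[int] = []
        thresh: list[float] = []
        left: list[int] = []
        right: list[int] = []
        proba: list[np.ndarray | None] = []

        def new_node() -> int:
            feat.append(-1)
            thresh.append(0.0)
            left.append(-1)
            right.append(-1)
            proba.append(None)
            return len(feat) - 1

        d = X.shape[1]
        root = new_node()
        stack: list[tuple[int, np.ndarray]] = [(root, np.arange(X.shape[0]))]
        while stack:
            node, idx = stack.pop()
            counts = np.bincount(class_index[idx], minlength=n_classes)
            if idx.size <= self.leaf_purity_stop or np.count_nonzero(counts) <= 1:
                proba[node] = counts / idx.size
                continue
            split = None
            # try random features until a non-constant one is found
            for f in rng.permutation(d):
                col = X[idx, f]
                mn, mx = col.min(), col.max()
                if mn == mx:
                    continue
                cut = rng.uniform(mn, mx)
                mask = col <= cut
                if mask.all() or not mask.any():  # numerically degenerate cut
                    cut = 0.5 * (mn + mx)
                    mask = col <= cut
                    if mask.all() or not mask.any():
                        continue
                split = (int(f), float(cut), mask)
                break
            if split is None:  # all features constant in this node
                proba[node] = counts / idx.size
                continue
            f, cut, mask = split
            feat[node] = f
            thresh[node] = cut
            ln, rn = new_node(), new_node()
            left[node], right[node] = ln, rn
            stack.append((rn, idx[~mask]))
            stack.append((ln, idx[mask]))

        self.feature_ = np.asarray(feat, dtype=np.int64)
        self.threshold_ = np.asarray(thresh, dtype=float)
        self.left_ = np.asarray(left, dtype=np.int64)
        self.right_ = np.asarray(right, dtype=np.int64)
        self.proba_ = np.zeros((len(feat), n_classes))
        for i, p in enumerate(proba):
            if p is not None:
                self.proba_[i] = p
        return self

    @property
    def n_nodes(self) -> int:
        return self.feature_.size

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.empty((X.shape[0], self.proba_.shape[1]))
        # batch traversal: partition index sets down the tree
        stack = [(0, np.arange(X.shape[0]))]
        while stack:
            node, idx = stack.pop()
            if idx.size == 0:
                continue
            if self.left_[node] < 0:
                out[idx] = self.proba_[node]
                continue
            mask = X[idx, self.feature_[node]] <= self.threshold_[node]
            stack.append((self.right_[node], idx[~mask]))
            stack.append((self.left_[node], idx[mask]))
        return out


def build_complete_random_tree(
    X: np.ndarray, y: np.ndarray, spec: ForestSpec | None = None, seed: int = 0
) -> CompleteRandomTree:
    """Grow one complete-random tree per ``spec`` (leaf stop, seed)."""
    stop = spec.leaf_purity_stop if spec is not None else 10
    return CompleteRandomTree(leaf_purity_stop=stop, seed=seed).fit(X, y)


class CompleteRandomForest:
    """Average of ``n_trees`` complete-random trees (no bootstrap)."""

    def __init__(self, spec: ForestSpec, seed: int = 0):
        if spec.kind != "complete_random":
            raise ValueError("CompleteRandomForest requires kind='complete_random'")
        self.spec = spec
        self.seed = seed

    def fit(self, X: np.ndarray, y: np.ndarray) -> "CompleteRandomForest":
        self.classes_ = np.unique(y)
        tree_seeds = np.random.default_rng(self.seed).integers(0, 2**31 - 1, self.spec.n_trees)
        self.trees_ = [
            CompleteRandomTree(self.spec.leaf_purity_stop, seed=int(s)).fit(
                X, y, classes=self.classes_
            )
            for s in tree_seeds
        ]
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        acc = self.trees_[0].predict_proba(X)
        for t in self.trees_[1:]:
            acc += t.predict_proba(X)
        return acc / len(self.trees_)


class GiniRandomForest:
    """Gini random forest with ceil(sqrt(d)) candidate features per node."""

    def __init__(self, spec: ForestSpec, seed: int = 0):
        if spec.kind != "random":
            raise ValueError("GiniRandomForest requires kind='random'")
        self.spec = spec
        self.seed = seed

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GiniRandomForest":
        d = X.shape[1]
        self.max_features_ = max(1, math.ceil(math.sqrt(d)))
        self._rf = RandomForestClassifier(
            n_estimators=self.spec.n_trees,
            criterion="gini",
            max_features=self.max_features_,
            random_state=self.seed,
            n_jobs=1,
        )
        self._rf.fit(X, y)
        self.classes_ = self._rf.classes_
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self._rf.predict_proba(X)


def _make_forest(spec: ForestSpec, seed: int):
    if spec.kind == "random":
        return GiniRandomForest(spec, seed=seed)
    return CompleteRandomForest(spec, seed=seed)


# --------------------------------------------------------------------------
# multi-grained scanning
# --------------------------------------------------------------------------

def _window_instances(X: np.ndarray, window: int, stride: int) -> np.ndarray:
    """(n, d) -> (n * w, window) sliding-window instances, w windows per row."""
    views = np.lib.stride_tricks.sliding_window_view(X, window, axis=1)[:, ::stride, :]
    return np.ascontiguousarray(views).reshape(-1, window)


def n_windows(d: int, window: int, stride: int) -> int:
    return (d - window) // stride + 1


@dataclass
class FittedScanner:
    spec: ScannerSpec
    n_features_in: int
    forests: list
    classes_: np.ndarray

    @property
    def output_width(self) -> int:
        w = n_windows(self.n_features_in, self.spec.window, self.spec.stride)
        return w * len(self.forests) * self.classes_.size


def fit_scanner(
    X: np.ndarray, y: np.ndarray, spec: ScannerSpec | None = None, seed: int = 0
) -> FittedScanner:
    """Train the scanning forests on pooled sliding-window instances.

    Every window instance inherits the label of the sample it was cut
    from.  Requires both classes in ``y`` and ``window <= d``.
    """
    if spec is None:
        spec = ScannerSpec()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("scanner requires at least two classes in y")
    d = X.shape[1]
    if spec.window > d:
        raise ValueError(f"window ({spec.window}) exceeds feature length ({d})")
    instances = _window_instances(X, spec.window, spec.stride)
    w = n_windows(d, spec.window, spec.stride)
    labels = np.repeat(y, w)
    seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, len(spec.forests))
    forests = [
        _make_forest(fs, seed=int(s)).fit(instances, labels)
        for fs, s in zip(spec.forests, seeds)
    ]
    return FittedScanner(spec=spec, n_features_in=d, forests=forests, classes_=classes)


def scan_transform(scanner: FittedScanner, X: np.ndarray) -> np.ndarray:
    """Augmented representation: per-window class vectors from each forest.

    Output row layout: for each scanning forest, the class-probability
    vectors of its windows in order; total width
    ``n_windows * n_forests * n_classes``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != scanner.n_features_in:
        raise ValueError(
            f"expected {scanner.n_features_in} features, got shape {X.shape}"
        )
    spec = scanner.spec
    instances = _window_instances(X, spec.window, spec.stride)
    w = n_windows(scanner.n_features_in, spec.window, spec.stride)
    blocks = [
        f.predict_proba(instances).reshape(X.shape[0], w * scanner.classes_.size)
        for f in scanner.forests
    ]
    return np.hstack(blocks)


# --------------------------------------------------------------------------
# cascade forest
# --------------------------------------------------------------------------

@dataclass
class _CascadeLevel:
    # per forest: the cv fold-models whose test-time average is the class vector
    fold_models: list[list]
    cv_accuracy: float


@dataclass
class CascadeModel:
    """Fitted cascade: retained levels and their CV accuracies."""

    spec: CascadeSpec
    levels: list[_CascadeLevel]
    level_cv_accuracies: list[float]
    classes_: np.ndarray
    n_features_in: int

    @property
    def n_levels(self) -> int:
        return len(self.levels)


def _forest_class_vectors(level: _CascadeLevel, X: np.ndarray) -> list[np.ndarray]:
    """Per forest, average class probabilities over its CV fold-models."""
    out = []
    for models in level.fold_models:
        acc = models[0].predict_proba(X)
        for m in models[1:]:
            acc += m.predict_proba(X)
        out.append(acc / len(models))
    return out


def fit_cascade(
    X_aug: np.ndarray, y: np.ndarray, spec: CascadeSpec | None = None, seed: int = 0
) -> CascadeModel:
    """Grow cascade levels until CV accuracy stops improving.

    At level ``t`` each forest's out-of-fold class vectors (from
    ``cv_folds``-fold stratified CV) are concatenated to the original
    augmented features to form level ``t+1``'s input.  Growth stops once a
    new level fails to beat the best CV accuracy so far by more than
    ``tolerance`` percentage points (or at ``max_levels``); the
    non-improving level is discarded, so every retained level improved on
    its predecessors by more than the tolerance.
    """
    if spec is None:
        spec = CascadeSpec()
    X_aug = np.asarray(X_aug, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("cascade requires at least two classes in y")
    counts = np.bincount(np.searchsorted(classes, y))
    if counts.min() < spec.cv_folds:
        raise ValueError(
            f"each class needs >= cv_folds ({spec.cv_folds}) samples; got {counts.min()}"
        )

    ss = np.random.default_rng(seed)
    levels: list[_CascadeLevel] = []
    accs: list[float] = []
    best = -np.inf
    aug = X_aug
    for t in range(spec.max_levels):
        fold_models: list[list] = []
        oof_blocks: list[np.ndarray] = []
        kf = StratifiedKFold(
            n_splits=spec.cv_folds, shuffle=True, random_state=int(ss.integers(2**31 - 1))
        )
        splits = list(kf.split(aug, y))
        for fs in spec.forests_per_level:
            oof = np.zeros((aug.shape[0], classes.size))
            models = []
            for train_idx, test_idx in splits:
                m = _make_forest(fs, seed=int(ss.integers(2**31 - 1)))
                m.fit(aug[train_idx], y[train_idx])
                oof[test_idx] = m.predict_proba(aug[test_idx])
                models.append(m)
            fold_models.append(models)
            oof_blocks.append(oof)
        mean_oof = np.mean(oof_blocks, axis=0)
        acc = float(np.mean(classes[np.argmax(mean_oof, axis=1)] == y))
        improved = acc > best + spec.tolerance / 100.0
        if t > 0 and not improved:
            break  # discard the non-improving level; growth stops here
        levels.append(_CascadeLevel(fold_models=fold_models, cv_accuracy=acc))
        accs.append(acc)
        best = max(best, acc)
        aug = np.hstack([X_aug] + oof_blocks)

    return CascadeModel(
        spec=spec,
        levels=levels,
        level_cv_accuracies=accs,
        classes_=classes,
        n_features_in=X_aug.shape[1],
    )


def predict_cascade(model: CascadeModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities and labels from the retained cascade levels.

    The final level's per-forest class vectors are averaged; the label is
    the argmax, with ties broken toward the first (0) class.
    """
    if not getattr(model, "levels", None):
        raise RuntimeError("cascade model is not fitted")
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.n_features_in:
        raise ValueError(
            f"expected {model.n_features_in} features, got {X.shape[1]}"
        )
    aug = X
    vectors: list[np.ndarray] = []
    for level in model.levels:
        vectors = _forest_class_vectors(level, aug)
        aug = np.hstack([X] + vectors)
    proba = np.mean(vectors, axis=0)
    labels = model.classes_[np.argmax(proba, axis=1)]
    return proba, labels


# --------------------------------------------------------------------------
# end-to-end estimator
# --------------------------------------------------------------------------

class DeepForestClassifier:
    """Scanning stage + cascade stage behind a scikit-learn-like surface."""

    def __init__(
        self,
        scanner_spec: ScannerSpec | None = None,
        cascade_spec: CascadeSpec | None = None,
        seed: int = 0,
    ):
        self.scanner_spec = scanner_spec if scanner_spec is not None else ScannerSpec()
        self.cascade_spec = cascade_spec if cascade_spec is not None else CascadeSpec()
        self.seed = seed

    def fit(self, X: np.ndarray, y: np.ndarray) -> "DeepForestClassifier":
        rng = np.random.default_rng(self.seed)
        self.scanner_ = fit_scanner(X, y, self.scanner_spec, seed=int(rng.integers(2**31 - 1)))
        X_aug = scan_transform(self.scanner_, X)
        self.cascade_ = fit_cascade(X_aug, y, self.cascade_spec, seed=int(rng.integers(2**31 - 1)))
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        proba, _ = predict_cascade(self.cascade_, scan_transform(self.scanner_, X))
        return proba

    def predict(self, X: np.ndarray) -> np.ndarray:
        _, labels = predict_cascade(self.cascade_, scan_transform(self.scanner_, X))
        return labels


def make_two_class_features(
    n_per_class: int,
    n_features: int = 300,
    signal: float = 4.0,
    n_signal: int = 10,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-Gaussian synthetic feature matrix for classifier benchmarks.

    Both classes are unit-variance Gaussians; class 1's mean is shifted by
    ``signal`` on ``n_signal`` evenly spaced features, so ``signal = 0``
    gives chance-level data and ``signal = 4`` is effectively separable.
    Returns ``(X, y)`` with ``2 * n_per_class`` interleaved samples.
    """
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n_per_class, n_features))
    y = np.tile([0, 1], n_per_class)
    sig_idx = np.unique(np.linspace(0, n_features - 1, n_signal).round().astype(int))
    X[np.ix_(y == 1, sig_idx)] += signal
    return X, y
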