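"""Gini decision tree over binary in-parlour indicators, with the study's
growth, pruning, and cross-validation protocol.

The classifier predicts the three-class locomotion outcome {0, 1, >=2} from
the four binary indicators.  Training follows the protocol exactly:

1. grow the tree to maximum depth — a node stops splitting only when it is
   pure, every indicator has already been used on its path, or no split
   reduces Gini impurity (splits are chosen by maximal impurity decrease,
   ties broken by the fixed indicator order SW, AWD, SHH, OH);
2. post-prune bottom-up: an internal node may keep its split only if it
   holds strictly more than 20 observations and its split decreases Gini
   impurity by at least 0.005 (both thresholds configurable);
3. stratified 4-fold cross-validation: within each locomotion class the
   observations are shuffled and dealt round-robin into folds, so per-class
   fold counts differ by at most one; each fold serves once as the test set
   and the fold with the highest test accuracy supplies the reported
   classifier.

Implemented from scratch (exhaustive search over at most four candidate
binary splits per node); the scikit-learn estimator API is provided by
:class:`IndicatorTreeClassifier` so the model composes with sklearn tooling.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import ValidationError
from .scoring import INDICATORS, ls_class3

FEATURE_NAMES = tuple(INDICATORS)


@dataclass
class TreeNode:
    """One node of the grown/pruned tree.

    ``class_counts`` are the training observations per class reaching the
    node; ``split_feature`` is a feature index (None for leaves);
    ``absent``/``present`` are the children for indicator value 0/1.
    """

    class_counts: np.ndarray
    split_feature: int | None = None
    absent: "TreeNode | None" = None
    present: "TreeNode | None" = None

    @property
    def n(self) -> int:
        return int(self.class_counts.sum())

    @property
    def gini(self) -> float:
        return gini_impurity(self.class_counts)

    @property
    def is_leaf(self) -> bool:
        return self.split_feature is None

    @property
    def predicted_class(self) -> int:
        """Majority class; ties broken toward the lower class index."""
        return int(np.argmax(self.class_counts))

    @property
    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(self.absent.depth, self.present.depth)


@dataclass(frozen=True)
class PruningRule:
    """Post-pruning thresholds: a node may keep its split only if it holds at
    least ``min_node_size_to_split`` observations (default 21, i.e. strictly
    more than 20) and the split's Gini decrease is at least
    ``min_gini_decrease`` (default 0.005)."""

    min_node_size_to_split: int = 21
    min_gini_decrease: float = 0.005

    def __post_init__(self) -> None:
        if self.min_node_size_to_split <= 0 or self.min_gini_decrease <= 0:
            raise ValidationError("pruning thresholds must be positive")


def gini_impurity(class_counts) -> float:
    """Gini impurity 1 - sum(p_c^2); 0 for a pure node."""
    counts = np.asarray(class_counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("class counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("gini impurity undefined for an empty node")
    p = counts / total
    return float(1.0 - (p * p).sum())


def gini_decrease(parent_counts, left_counts, right_counts) -> float:
    """Impurity decrease of a split: G(parent) - weighted child impurities.

    The children must partition the parent (counts add up) and both must be
    non-empty; always >= 0 up to rounding.
    """
    parent = np.asarray(parent_counts, dtype=float)
    left = np.asarray(left_counts, dtype=float)
    right = np.asarray(right_counts, dtype=float)
    if not np.array_equal(left + right, parent):
        raise ValidationError("child class counts must sum to the parent's")
    n = parent.sum()
    n_l, n_r = left.sum(), right.sum()
    if n_l == 0 or n_r == 0:
        raise ValidationError("a split may not produce an empty branch")
    return float(
        gini_impurity(parent)
        - (n_l / n) * gini_impurity(left)
        - (n_r / n) * gini_impurity(right)
    )


def _counts(y: np.ndarray, n_classes: int) -> np.ndarray:
    return np.bincount(y, minlength=n_classes)


def best_split(X: np.ndarray, y: np.ndarray, available, n_classes: int = 3):
    """Best available binary feature to split on, by maximal Gini decrease.

    Evaluates every feature index in ``available`` (in order; the first
    maximiser wins ties), skipping features that would produce an empty
    branch.  Returns ``(feature, decrease)`` or ``None`` when no split gives
    a positive decrease.
    """
    parent = _counts(y, n_classes)
    best = None
    best_dec = 0.0
    for f in available:
        mask = X[:, f] == 1
        n_present = int(mask.sum())
        if n_present == 0 or n_present == len(y):
            continue
        dec = gini_decrease(parent, _counts(y[~mask], n_classes), _counts(y[mask], n_classes))
        if dec > best_dec:
            best, best_dec = f, dec
    return None if best is None else (best, best_dec)


def grow_tree(X, y, n_classes: int = 3, rule: PruningRule | None = None) -> TreeNode:
    """Grow a tree to maximum depth (or under ``rule`` constraints if given).

    Growth stops at a node when it is pure, all features on the path are
    used, or no remaining split yields a positive Gini decrease.  With a
    ``rule``, the size and decrease thresholds are additionally enforced
    during growth (constrained mode) rather than by post-pruning.
    """
    X = np.asarray(X, dtype=int)
    y = np.asarray(y, dtype=int)
    if len(y) == 0:
        raise ValidationError("cannot grow a tree on an empty training set")

    def build(idx: np.ndarray, available: tuple[int, ...]) -> TreeNode:
        counts = _counts(y[idx], n_classes)
        node = TreeNode(class_counts=counts)
        if (counts > 0).sum() <= 1 or not available:
            return node
        if rule is not None and counts.sum() < rule.min_node_size_to_split:
            return node
        found = best_split(X[idx], y[idx], available, n_classes)
        if found is None:
            return node
        feat, dec = found
        if rule is not None and dec < rule.min_gini_decrease - 1e-12:
            return node
        remaining = tuple(f for f in available if f != feat)
        mask = X[idx, feat] == 1
        node.split_feature = feat
        node.absent = build(idx[~mask], remaining)
        node.present = build(idx[mask], remaining)
        return node

    return build(np.arange(len(y)), tuple(range(X.shape[1])))


def realized_decrease(node: TreeNode) -> float:
    """Gini decrease actually achieved by an internal node's split."""
    if node.is_leaf:
        raise ValueError("leaf nodes have no split")
    return gini_decrease(node.class_counts, node.absent.class_counts, node.present.class_counts)


def prune_tree(tree: TreeNode, rule: PruningRule = PruningRule()) -> TreeNode:
    """Bottom-up post-pruning under the study's two criteria.

    Children are pruned first; then any internal node holding fewer than
    ``min_node_size_to_split`` observations, or whose split decreases Gini
    by less than ``min_gini_decrease``, is collapsed to a leaf.  The input
    tree is not modified.
    """

    def walk(node: TreeNode) -> TreeNode:
        if node.is_leaf:
            return TreeNode(class_counts=node.class_counts.copy())
        pruned = TreeNode(
            class_counts=node.class_counts.copy(),
            split_feature=node.split_feature,
            absent=walk(node.absent),
            present=walk(node.present),
        )
        if (
            pruned.n < rule.min_node_size_to_split
            or realized_decrease(pruned) < rule.min_gini_decrease - 1e-12
        ):
            return TreeNode(class_counts=node.class_counts.copy())
        return pruned

    return walk(tree)


def predict_one(tree: TreeNode, x) -> int:
    """Route one observation (indexable by feature index) to its leaf class."""
    node = tree
    while not node.is_leaf:
        v = x[node.split_feature]
        if v not in (0, 1):
            raise ValidationError(f"indicator value must be 0 or 1, got {v!r}")
        node = node.present if v == 1 else node.absent
    return node.predicted_class


def predict(tree: TreeNode, X) -> np.ndarray:
    """Vectorised routing of many observations through the tree."""
    X = np.asarray(X, dtype=int)
    if not np.isin(X, (0, 1)).all():
        raise ValidationError("indicator matrix must be binary")
    out = np.empty(len(X), dtype=int)

    def walk(node: TreeNode, idx: np.ndarray) -> None:
        if len(idx) == 0:
            return
        if node.is_leaf:
            out[idx] = node.predicted_class
            return
        mask = X[idx, node.split_feature] == 1
        walk(node.present, idx[mask])
        walk(node.absent, idx[~mask])

    walk(tree, np.arange(len(X)))
    return out


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def tree_to_dict(node: TreeNode, feature_names=FEATURE_NAMES) -> dict:
    d = {
        "class_counts": [int(c) for c in node.class_counts],
        "gini": node.gini,
        "n": node.n,
    }
    if node.is_leaf:
        d["predicted_class"] = node.predicted_class
    else:
        d["split_feature"] = feature_names[node.split_feature]
        d["absent"] = tree_to_dict(node.absent, feature_names)
        d["present"] = tree_to_dict(node.present, feature_names)
    return d


def tree_from_dict(d: dict, feature_names=FEATURE_NAMES) -> TreeNode:
    node = TreeNode(class_counts=np.asarray(d["class_counts"], dtype=int))
    if "split_feature" in d:
        node.split_feature = feature_names.index(d["split_feature"])
        node.absent = tree_from_dict(d["absent"], feature_names)
        node.present = tree_from_dict(d["present"], feature_names)
    return node


def tree_to_json(node: TreeNode, feature_names=FEATURE_NAMES) -> str:
    return json.dumps(tree_to_dict(node, feature_names), indent=2)


def tree_to_dot(
    node: TreeNode,
    feature_names=FEATURE_NAMES,
    class_labels=("0", "1", ">=2"),
) -> str:
    """Graphviz DOT export.  Green edges mark the indicator absent, red
    edges the indicator present, mirroring the study's tree figure."""
    lines = ["digraph tree {", "  node [shape=box];"]
    counter = [0]

    def emit(n: TreeNode) -> int:
        my_id = counter[0]
        counter[0] += 1
        counts = ", ".join(
            f"{lbl}: {c}" for lbl, c in zip(class_labels, n.class_counts)
        )
        if n.is_leaf:
            label = f"predict LS {class_labels[n.predicted_class]}\\n[{counts}]\\ngini={n.gini:.3f}"
        else:
            label = f"{feature_names[n.split_feature].upper()}?\\n[{counts}]\\ngini={n.gini:.3f}"
        lines.append(f'  n{my_id} [label="{label}"];')
        if not n.is_leaf:
            a = emit(n.absent)
            p = emit(n.present)
            lines.append(f'  n{my_id} -> n{a} [label="absent", color=green];')
            lines.append(f'  n{my_id} -> n{p} [label="present", color=red];')
        return my_id

    emit(node)
    lines.append("}")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# scikit-learn estimator
# ---------------------------------------------------------------------------

from sklearn.base import BaseEstimator, ClassifierMixin  # noqa: E402


class IndicatorTreeClassifier(ClassifierMixin, BaseEstimator):
    """Gini decision tree over binary indicators with grow-then-prune training.

    Parameters
    ----------
    min_samples_split : int, default 21
        Minimum node size allowed to keep a split (strictly more than 20
        observations in the default protocol).
    min_impurity_decrease : float, default 0.005
        Minimum (unweighted) Gini decrease for a split to survive pruning.
    growth : {"prune", "constrained"}, default "prune"
        "prune": grow to maximum depth, then post-prune (the study protocol).
        "constrained": enforce both thresholds during growth; the two can
        differ when a weak split enables a strong descendant split.

    Attributes
    ----------
    tree_ : TreeNode
        The fitted (pruned) tree.
    classes_ : ndarray
        Sorted class labels seen in ``y``.
    n_features_in_ : int
    feature_names_in_ : ndarray of str, when fitted on a DataFrame.
    """

    def __init__(
        self,
        min_samples_split: int = 21,
        min_impurity_decrease: float = 0.005,
        growth: str = "prune",
    ):
        self.min_samples_split = min_samples_split
        self.min_impurity_decrease = min_impurity_decrease
        self.growth = growth

    def _validate_X(self, X, reset: bool) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if reset:
                self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            X = X.to_numpy()
        X = np.asarray(X, dtype=int)
        if X.ndim != 2:
            raise ValidationError("X must be a 2-D binary indicator matrix")
        if not np.isin(X, (0, 1)).all():
            raise ValidationError("X must contain only 0/1 indicator flags")
        if reset:
            self.n_features_in_ = X.shape[1]
        elif X.shape[1] != self.n_features_in_:
            raise ValidationError(
                f"X has {X.shape[1]} features; classifier was fitted with {self.n_features_in_}"
            )
        return X

    def fit(self, X, y):
        if self.growth not in ("prune", "constrained"):
            raise ValidationError(f"growth must be 'prune' or 'constrained', got {self.growth!r}")
        X = self._validate_X(X, reset=True)
        y = np.asarray(y)
        if len(y) != len(X):
            raise ValidationError("X and y length mismatch")
        self.classes_ = np.unique(y)
        y_idx = np.searchsorted(self.classes_, y)
        rule = PruningRule(self.min_samples_split, self.min_impurity_decrease)
        n_classes = len(self.classes_)
        if self.growth == "constrained":
            self.tree_ = grow_tree(X, y_idx, n_classes=n_classes, rule=rule)
        else:
            self.tree_ = prune_tree(grow_tree(X, y_idx, n_classes=n_classes), rule)
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "tree_"):
            raise ValidationError("classifier is not fitted")
        X = self._validate_X(X, reset=False)
        return self.classes_[predict(self.tree_, X)]


# ---------------------------------------------------------------------------
# Stratified cross-validation
# ---------------------------------------------------------------------------

def stratified_kfold(y, k: int = 4, seed: int | None = 0) -> np.ndarray:
    """Seeded stratified fold assignment over the class labels ``y``.

    Within each class the observations are shuffled and dealt round-robin
    into ``k`` folds, so per-class fold counts differ by at most one and each
    fold holds about 1/k of the data.  A class with fewer members than ``k``
    is allowed; some folds then lack it (with a warning).
    """
    y = np.asarray(y)
    if len(y) < k:
        raise ValidationError(f"need at least k={k} observations, got {len(y)}")
    rng = np.random.default_rng(seed)
    folds = np.empty(len(y), dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < k:
            warnings.warn(
                f"class {cls!r} has {len(idx)} member(s), fewer than k={k}; "
                "some folds will lack it",
                stacklevel=2,
            )
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % k
    return folds


@dataclass
class CVResult:
    """Outcome of k-fold cross-validation with best-fold selection."""

    best_fold: int
    best_model: IndicatorTreeClassifier
    fold_accuracies: list[float]
    fold_confusions: list[np.ndarray]
    fold_models: list[IndicatorTreeClassifier]
    fold_assignment: np.ndarray

    @property
    def best_confusion(self) -> np.ndarray:
        return self.fold_confusions[self.best_fold]

    @property
    def best_accuracy(self) -> float:
        return self.fold_accuracies[self.best_fold]


def cross_validate_select(
    data,
    rule: PruningRule = PruningRule(),
    k: int = 4,
    seed: int | None = 0,
    growth: str = "prune",
) -> CVResult:
    """Grow-prune-evaluate one classifier per fold; select the best fold.

    ``data`` is a matched cow-visit DataFrame (or MatchedDataset); the
    outcome is the three-class locomotion label from ``ls`` and the features
    are the four indicators.  For each fold, the classifier is trained on the
    other k-1 folds and evaluated on the held-out fold; the classifier with
    the highest held-out accuracy is selected (ties broken by lowest fold
    index).
    """
    from sklearn.metrics import confusion_matrix as _sk_confusion

    frame = getattr(data, "data", data)
    X = frame[list(FEATURE_NAMES)].to_numpy(dtype=int)
    y = ls_class3(frame["ls"].to_numpy(dtype=int))
    folds = stratified_kfold(y, k=k, seed=seed)

    models, accuracies, confusions = [], [], []
    for f in range(k):
        test = folds == f
        model = IndicatorTreeClassifier(
            min_samples_split=rule.min_node_size_to_split,
            min_impurity_decrease=rule.min_gini_decrease,
            growth=growth,
        ).fit(X[~test], y[~test])
        pred = model.predict(X[test])
        cm = _sk_confusion(y[test], pred, labels=[0, 1, 2])
        models.append(model)
        confusions.append(cm)
        accuracies.append(float(np.trace(cm) / cm.sum()))
    best = int(np.argmax(accuracies))
    return CVResult(
        best_fold=best,
        best_model=models[best],
        fold_accuracies=accuracies,
        fold_confusions=confusions,
        fold_models=models,
        fold_assignment=folds,
    )
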