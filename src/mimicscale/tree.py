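"""Binary classification tree for stroke-mimic risk.

A deliberately small, fully deterministic CART-style learner: candidate
splits are scanned exhaustively, node impurity is Shannon entropy, and
overfitting is controlled by reduced-error pruning against a stratified
holdout rather than cost-complexity pruning. The default candidate
features are the four variables that separate mimics from true strokes
univariately in this setting: age, migraine, hypertension and
psychiatric history.

Conventions
-----------
* The positive class is the stroke mimic.
* Splits are (feature, threshold); a record routes right when its value
  exceeds the threshold. Booleans are treated as 0/1 with threshold 0.5,
  so "right" means "present".
* Equal-gain splits are resolved by lexicographic feature name, then the
  smaller threshold, so the grown tree is invariant to record order.
* A leaf predicts the mimic fraction of its training records; the class
  call thresholds that probability at 0.5 with ties going to stroke
  (the safer clinical default).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cohort import PatientRecord

#: Features the reference analysis found univariately significant.
DEFAULT_FEATURES = ("age", "migraine", "hypertension", "psychiatric_history")

#: Ordered (numeric-threshold) features; everything else must be boolean.
ORDERED_FEATURES = frozenset({"age", "sbp", "dbp", "nihss"})


@dataclass(frozen=True)
class TreeConfig:
    """Growth and pruning hyperparameters (all defaults are choices of
    this package, not findings of the source analysis)."""

    features: tuple[str, ...] = DEFAULT_FEATURES
    min_node_size: int = 5
    max_depth: int = 4
    prune_fraction: float = 0.3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.min_node_size < 1:
            raise ValueError("min_node_size must be >= 1")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if not 0 < self.prune_fraction < 1:
            raise ValueError("prune_fraction must be in (0, 1)")


@dataclass
class TreeNode:
    """A split node (feature/threshold/children) or a leaf.

    Every node carries the class counts of the training records routed
    to it, so any subtree can be collapsed to a majority leaf.
    """

    n_stroke: int
    n_mimic: int
    feature: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def total(self) -> int:
        return self.n_stroke + self.n_mimic

    @property
    def mimic_probability(self) -> float:
        if self.total == 0:  # unpopulated fixed-structure leaf
            return 0.0
        return self.n_mimic / self.total

    @property
    def majority_is_mimic(self) -> bool:
        # ties -> stroke
        return self.n_mimic > self.n_stroke

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(self.left.depth(), self.right.depth())  # type: ignore[union-attr]

    def n_leaves(self) -> int:
        if self.is_leaf:
            return 1
        return self.left.n_leaves() + self.right.n_leaves()  # type: ignore[union-attr]

    def to_dict(self) -> dict:
        d: dict = {"n_stroke": self.n_stroke, "n_mimic": self.n_mimic}
        if self.is_leaf:
            d.update(
                type="leaf",
                mimic_probability=self.mimic_probability,
                risk=risk_class(self.mimic_probability),
            )
        else:
            d.update(
                type="split",
                feature=self.feature,
                threshold=self.threshold,
                left=self.left.to_dict(),  # type: ignore[union-attr]
                right=self.right.to_dict(),  # type: ignore[union-attr]
            )
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def format(self, indent: int = 0) -> str:
        pad = "  " * indent
        if self.is_leaf:
            return (
                f"{pad}leaf: mimic {self.n_mimic}/{self.total} "
                f"(p={self.mimic_probability:.3f}, risk={risk_class(self.mimic_probability)})"
            )
        cond = (
            f"{self.feature} present"
            if self.feature not in ORDERED_FEATURES
            else f"{self.feature} > {self.threshold:g}"
        )
        return "\n".join(
            [
                f"{pad}if {cond}:",
                self.right.format(indent + 1),  # type: ignore[union-attr]
                f"{pad}else:",
                self.left.format(indent + 1),  # type: ignore[union-attr]
            ]
        )


def entropy(class_counts: tuple[int, int]) -> float:
    """Shannon entropy in bits of a two-class count vector."""
    n0, n1 = class_counts
    if n0 < 0 or n1 < 0:
        raise ValueError("counts must be non-negative")
    total = n0 + n1
    if total == 0:
        raise ValueError("entropy undefined for an empty node")
    h = 0.0
    for k in (n0, n1):
        if k:
            p = k / total
            h -= p * math.log2(p)
    return h


def _value(record: PatientRecord, feature: str) -> float:
    return float(getattr(record, feature))


def _counts(records: Sequence[PatientRecord]) -> tuple[int, int]:
    n_mimic = sum(r.is_mimic for r in records)
    return len(records) - n_mimic, n_mimic


@dataclass(frozen=True)
class Split:
    feature: str
    threshold: float
    weighted_entropy: float


def _entropy_vec(n1: np.ndarray, total: np.ndarray) -> np.ndarray:
    """Vectorized two-class entropy; 0 log 0 = 0; empty nodes give 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = np.where(total > 0, n1 / np.maximum(total, 1), 0.0)
        p0 = 1.0 - p1
        h = -(
            np.where(p0 > 0, p0 * np.log2(np.maximum(p0, 1e-300)), 0.0)
            + np.where(p1 > 0, p1 * np.log2(np.maximum(p1, 1e-300)), 0.0)
        )
    return h


def best_split(
    records: Sequence[PatientRecord],
    features: Sequence[str] = DEFAULT_FEATURES,
    min_node_size: int = 1,
) -> Split | None:
    """Exhaustively scan all (feature, threshold) candidates.

    Thresholds for ordered features are midpoints between consecutive
    distinct values; booleans have the single candidate 0.5. Returns the
    split minimizing the child-size-weighted entropy, or None when no
    admissible split strictly reduces the parent entropy.
    """
    n = len(records)
    parent_h = entropy(_counts(records))
    y = np.array([r.is_mimic for r in records])
    best: Split | None = None
    for feature in sorted(set(features)):
        values = np.array([_value(r, feature) for r in records])
        order = np.argsort(values, kind="stable")
        v_sorted, y_sorted = values[order], y[order]
        # boundaries after each run of equal values (last one excluded)
        boundary = np.flatnonzero(np.diff(v_sorted) > 0)
        if feature not in ORDERED_FEATURES and boundary.size:
            thresholds = np.array([0.5])
        elif boundary.size:
            thresholds = (v_sorted[boundary] + v_sorted[boundary + 1]) / 2
        else:
            continue  # constant feature
        n_left = boundary + 1
        n_right = n - n_left
        cum_mimic = np.cumsum(y_sorted)
        m_left = cum_mimic[boundary]
        m_right = int(y.sum()) - m_left
        ok = (n_left >= min_node_size) & (n_right >= min_node_size)
        if not ok.any():
            continue
        wh = (
            n_left * _entropy_vec(m_left, n_left)
            + n_right * _entropy_vec(m_right, n_right)
        ) / n
        wh = np.where(ok, wh, np.inf)
        if feature not in ORDERED_FEATURES:
            wh = wh[:1]  # single candidate at 0.5 (boundary between 0 and 1)
        i = int(np.flatnonzero(wh <= wh.min() + 1e-12)[0])  # smallest threshold wins ties
        wh_i = float(wh[i])
        if wh_i >= parent_h - 1e-12:
            continue
        if (
            best is None
            or wh_i < best.weighted_entropy - 1e-12
            or (
                abs(wh_i - best.weighted_entropy) <= 1e-12
                and (feature, float(thresholds[i])) < (best.feature, best.threshold)
            )
        ):
            best = Split(feature=feature, threshold=float(thresholds[i]), weighted_entropy=wh_i)
    return best


def grow(records: Sequence[PatientRecord], config: TreeConfig) -> TreeNode:
    """Recursively partition until purity, max depth, or minimum size."""
    if not records:
        raise ValueError("cannot grow a tree from no records")
    return _grow(records, config, depth=0)


def _grow(records: Sequence[PatientRecord], config: TreeConfig, depth: int) -> TreeNode:
    n_stroke, n_mimic = _counts(records)
    node = TreeNode(n_stroke=n_stroke, n_mimic=n_mimic)
    if depth >= config.max_depth or min(n_stroke, n_mimic) == 0 or len(records) < 2 * config.min_node_size:
        return node
    split = best_split(records, config.features, config.min_node_size)
    if split is None:
        return node
    right_mask = [_value(r, split.feature) > split.threshold for r in records]
    node.feature = split.feature
    node.threshold = split.threshold
    node.left = _grow([r for r, m in zip(records, right_mask) if not m], config, depth + 1)
    node.right = _grow([r for r, m in zip(records, right_mask) if m], config, depth + 1)
    return node


def predict(tree: TreeNode, record: PatientRecord, threshold: float = 0.5) -> tuple[float, bool]:
    """Route a record to its leaf; return (mimic probability, mimic class).

    The class is True (mimic) only when the leaf probability strictly
    exceeds the decision threshold, so a 50/50 leaf calls stroke.
    """
    node = tree
    while not node.is_leaf:
        if not hasattr(record, node.feature):  # type: ignore[arg-type]
            raise ValueError(f"record lacks feature {node.feature!r}")
        node = node.right if _value(record, node.feature) > node.threshold else node.left  # type: ignore[arg-type,union-attr]
    p = node.mimic_probability
    return p, p > threshold


def _subtree_error(node: TreeNode, records: Sequence[PatientRecord]) -> int:
    return sum(predict(node, r)[1] != r.is_mimic for r in records)


def reduced_error_prune(tree: TreeNode, pruning_records: Sequence[PatientRecord]) -> TreeNode:
    """Bottom-up reduced-error pruning against a held-out set.

    A subtree is collapsed to its majority-class leaf whenever the
    collapse does not increase the number of pruning-set errors, so the
    pruned tree's holdout error is never worse than the original's.
    Returns a new tree; the input is not modified.
    """
    if not pruning_records:
        raise ValueError("pruning set must be non-empty")
    return _prune(tree, list(pruning_records))


def _prune(node: TreeNode, records: list[PatientRecord]) -> TreeNode:
    if node.is_leaf:
        return TreeNode(n_stroke=node.n_stroke, n_mimic=node.n_mimic)
    right_records = [r for r in records if _value(r, node.feature) > node.threshold]  # type: ignore[arg-type]
    left_records = [r for r in records if _value(r, node.feature) <= node.threshold]  # type: ignore[arg-type]
    pruned = TreeNode(
        n_stroke=node.n_stroke,
        n_mimic=node.n_mimic,
        feature=node.feature,
        threshold=node.threshold,
        left=_prune(node.left, left_records),  # type: ignore[arg-type]
        right=_prune(node.right, right_records),  # type: ignore[arg-type]
    )
    as_leaf = TreeNode(n_stroke=node.n_stroke, n_mimic=node.n_mimic)
    if _subtree_error(as_leaf, records) <= _subtree_error(pruned, records):
        return as_leaf
    return pruned


def risk_class(mimic_probability: float) -> str:
    """Map a leaf's mimic probability to {high, low, uncertain}.

    high above 0.60, low below 0.05, both strict; everything else is
    uncertain.
    """
    if not 0 <= mimic_probability <= 1:
        raise ValueError(f"probability out of [0, 1]: {mimic_probability}")
    if mimic_probability > 0.60:
        return "high"
    if mimic_probability < 0.05:
        return "low"
    return "uncertain"


@dataclass
class CvReport:
    """Pooled out-of-fold performance of grow-then-prune trees.

    Sensitivity is over the true-stroke group and specificity over the
    mimics (the stroke-positive convention of the performance table).
    """

    misclassification_rate: float
    sensitivity: float
    specificity: float
    confusion: tuple[int, int, int, int]  # (tp, fn, tn, fp), stroke-positive
    fold_error_rates: list[float]

    def to_dict(self) -> dict:
        return {
            "misclassification_rate": self.misclassification_rate,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "confusion_tp_fn_tn_fp": list(self.confusion),
            "fold_error_rates": self.fold_error_rates,
        }


def _stratified_folds(
    labels: Sequence[bool], k: int, rng: np.random.Generator
) -> list[np.ndarray]:
    y = np.asarray(labels, dtype=bool)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in (False, True):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for i, j in enumerate(idx):
            folds[i % k].append(int(j))
    return [np.array(sorted(f), dtype=int) for f in folds]


def _stratified_split(
    records: Sequence[PatientRecord], fraction: float, rng: np.random.Generator
) -> tuple[list[PatientRecord], list[PatientRecord]]:
    """Split records into (main, holdout) with per-class proportions."""
    y = np.array([r.is_mimic for r in records])
    holdout_idx: set[int] = set()
    for cls in (False, True):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n_hold = max(1, round(fraction * len(idx))) if len(idx) > 1 else 0
        holdout_idx.update(int(i) for i in idx[:n_hold])
    main = [r for i, r in enumerate(records) if i not in holdout_idx]
    hold = [r for i, r in enumerate(records) if i in holdout_idx]
    return main, hold


def fit(records: Sequence[PatientRecord], config: TreeConfig) -> TreeNode:
    """Grow on a stratified subsample and reduced-error prune on the rest."""
    if config.seed is None:
        raise ValueError("TreeConfig.seed is required for fitting")
    rng = np.random.default_rng(config.seed)
    grow_set, prune_set = _stratified_split(list(records), config.prune_fraction, rng)
    tree = grow(grow_set, config)
    if prune_set:
        tree = reduced_error_prune(tree, prune_set)
    return tree


def cross_validate(records: Sequence[PatientRecord], config: TreeConfig, k: int = 10) -> CvReport:
    """Stratified k-fold cross-validation of the grow-then-prune pipeline.

    Each training fold is itself split into a growing set and a pruning
    holdout; predictions are pooled over the held-out folds into a
    single confusion matrix.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if config.seed is None:
        raise ValueError("TreeConfig.seed is required for cross-validation")
    records = list(records)
    labels = [r.is_mimic for r in records]
    n_mimic = sum(labels)
    n_stroke = len(records) - n_mimic
    if k > min(n_mimic, n_stroke):
        raise ValueError(
            f"k={k} exceeds the minority class size ({min(n_mimic, n_stroke)}); "
            "stratification impossible"
        )
    rng = np.random.default_rng(config.seed)
    folds = _stratified_folds(labels, k, rng)
    tp = fn = tn = fp = 0
    fold_rates: list[float] = []
    for fold_idx in folds:
        test = [records[i] for i in fold_idx]
        train = [records[i] for i in range(len(records)) if i not in set(fold_idx.tolist())]
        sub_seed = int(rng.integers(0, 2**31 - 1))
        tree = fit(train, TreeConfig(
            features=config.features,
            min_node_size=config.min_node_size,
            max_depth=config.max_depth,
            prune_fraction=config.prune_fraction,
            seed=sub_seed,
        ))
        errors = 0
        for r in test:
            _, is_mimic_pred = predict(tree, r)
            errors += is_mimic_pred != r.is_mimic
            if r.is_mimic and not is_mimic_pred:
                fp += 1          # mimic called stroke: false "positive test"
            elif r.is_mimic and is_mimic_pred:
                tn += 1          # mimic called mimic: true negative test
            elif not r.is_mimic and not is_mimic_pred:
                tp += 1          # stroke called stroke
            else:
                fn += 1          # stroke called mimic
        fold_rates.append(errors / len(test))
    total = tp + fn + tn + fp
    return CvReport(
        misclassification_rate=(fn + fp) / total,
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        confusion=(tp, fn, tn, fp),
        fold_error_rates=fold_rates,
    )


def published_tree(cohort_records: Sequence[PatientRecord]) -> TreeNode:
    """Evaluate the fixed published tree structure on a cohort.

    Structure: migraine at the root; among migraine-free patients, age
    above/below 45; among the older migraine-free patients, psychiatric
    history. Leaf counts and probabilities come from the supplied
    records — only the structure is fixed.
    """
    def leaf(rs: list[PatientRecord]) -> TreeNode:
        if not rs:  # empty route: uninformative leaf, called stroke
            return TreeNode(n_stroke=0, n_mimic=0)
        s, m = _counts(rs)
        return TreeNode(n_stroke=s, n_mimic=m)

    records = list(cohort_records)
    mig = [r for r in records if r.migraine]
    no_mig = [r for r in records if not r.migraine]
    young = [r for r in no_mig if r.age <= 45]
    old = [r for r in no_mig if r.age > 45]
    psych = [r for r in old if r.psychiatric_history]
    no_psych = [r for r in old if not r.psychiatric_history]

    def split(rs: list[PatientRecord], feature: str, threshold: float,
              left: TreeNode, right: TreeNode) -> TreeNode:
        s, m = _counts(rs)
        return TreeNode(n_stroke=s, n_mimic=m, feature=feature, threshold=threshold,
                        left=left, right=right)

    old_node = split(old, "psychiatric_history", 0.5, leaf(no_psych), leaf(psych))
    no_mig_node = split(no_mig, "age", 45.0, leaf(young), old_node)
    return split(records, "migraine", 0.5, no_mig_node, leaf(mig))
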