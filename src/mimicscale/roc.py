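"""ROC analysis: empirical curves, AUC, DeLong variance and paired AUC
comparison, Youden-index cutoffs, and operating-point performance rows.

The positive class for discrimination analyses is the stroke mimic; a
scale oriented "lower is mimic" (TeleStroke Mimic Score) is negated
internally so that higher score always points to the positive class.
Operating-point rows (sensitivity, specificity, PPV, NPV, likelihood
ratios) support both positive-test conventions; the reference cohort's
performance table is integer-consistent with the *stroke-positive*
convention (sensitivity over the 240 true strokes, specificity over the
17 mimics), which is therefore the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .contingency import EffectEstimate, proportion_ci
from .scales import MimicDirection

__all__ = [
    "RocCurve",
    "PerformanceRow",
    "roc_points",
    "auc",
    "delong_covariance",
    "delong_paired_test",
    "youden_cutoff",
    "performance_at_cutoff",
    "performance_from_counts",
    "performance_from_summary",
]


def _oriented(scores: Sequence[float], orientation: MimicDirection) -> np.ndarray:
    """Map scores so that higher always indicates the positive (mimic) class."""
    s = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    return s if orientation is MimicDirection.HIGHER_IS_MIMIC else -s


def _split(scores: np.ndarray, labels: Sequence[bool]) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(labels, dtype=bool)
    if y.shape != scores.shape:
        raise ValueError("scores and labels must have equal length")
    pos, neg = scores[y], scores[~y]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("degenerate input: both classes must be present")
    return pos, neg


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC curve: (cutoff, sensitivity, specificity) triples,
    ordered from the all-negative to the all-positive operating point."""

    points: tuple[tuple[float, float, float], ...]
    positive_class: str = "mimic"
    orientation: MimicDirection = MimicDirection.HIGHER_IS_MIMIC


@dataclass(frozen=True)
class PerformanceRow:
    """One scale's operating-point statistics (one performance-table row)."""

    scale: str
    cutoff: float
    sensitivity: EffectEstimate
    specificity: EffectEstimate
    ppv: EffectEstimate | None
    npv: EffectEstimate | None
    lr_pos: EffectEstimate
    lr_neg: EffectEstimate
    counts: tuple[int, int, int, int]  # (tp, fn, tn, fp)
    positive_convention: str = "stroke"
    auroc: EffectEstimate | None = None
    delong_p_vs_reference: float | None = None


def roc_points(
    scores: Sequence[float], labels: Sequence[bool], orientation: MimicDirection
) -> RocCurve:
    """Empirical ROC over all distinct observed scores.

    Positives are the mimic-labelled observations; a threshold t
    classifies an (oriented) score >= t as positive. Cutoffs are
    reported on the oriented scale, with +/-inf closing the curve at
    (sens 0, spec 1) and (sens 1, spec 0).
    """
    s = _oriented(scores, orientation)
    pos, neg = _split(s, labels)
    thresholds = np.concatenate(([np.inf], np.unique(s)[::-1], [-np.inf]))
    pts = []
    for t in thresholds:
        sens = float(np.mean(pos >= t))
        spec = float(np.mean(neg < t))
        pts.append((float(t), sens, spec))
    return RocCurve(points=tuple(pts), orientation=orientation)


def auc(
    scores: Sequence[float], labels: Sequence[bool],
    orientation: MimicDirection = MimicDirection.HIGHER_IS_MIMIC,
) -> float:
    """Empirical AUC = P(pos > neg) + 0.5 P(pos = neg) over all cross-pairs.

    Computed by midranks; identical to the trapezoidal area under the
    empirical ROC curve, ties included.
    """
    s = _oriented(scores, orientation)
    pos, neg = _split(s, labels)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    m = len(pos)
    u = ranks[:m].sum() - m * (m + 1) / 2
    return float(u / (m * len(neg)))


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong structural components: for each positive, the fraction of
    negatives it beats (ties half), and symmetrically for negatives."""
    cmp = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (pos[:, None] == neg[None, :])
    return cmp.mean(axis=1), 1.0 - cmp.mean(axis=0)


def delong_covariance(
    scores_a: Sequence[float], scores_b: Sequence[float], labels: Sequence[bool],
    orientation_a: MimicDirection = MimicDirection.HIGHER_IS_MIMIC,
    orientation_b: MimicDirection = MimicDirection.HIGHER_IS_MIMIC,
) -> np.ndarray:
    """DeLong 2x2 covariance matrix of two paired empirical AUCs.

    cov = S10 / n_pos + S01 / n_neg, where S10 (S01) is the sample
    covariance matrix of the positive-class (negative-class) placement
    values of the two scores.
    """
    y = np.asarray(labels, dtype=bool)
    sa = _oriented(scores_a, orientation_a)
    sb = _oriented(scores_b, orientation_b)
    pos_a, neg_a = _split(sa, y)
    pos_b, neg_b = _split(sb, y)
    if len(pos_a) < 2 or len(neg_a) < 2:
        raise ValueError("need at least 2 observations per class for DeLong variance")
    v10 = np.vstack(( _placements(pos_a, neg_a)[0], _placements(pos_b, neg_b)[0] ))
    v01 = np.vstack(( _placements(pos_a, neg_a)[1], _placements(pos_b, neg_b)[1] ))
    s10 = np.cov(v10, ddof=1)
    s01 = np.cov(v01, ddof=1)
    return s10 / len(pos_a) + s01 / len(neg_a)


def delong_variance(
    scores: Sequence[float], labels: Sequence[bool],
    orientation: MimicDirection = MimicDirection.HIGHER_IS_MIMIC,
) -> float:
    """DeLong variance of a single empirical AUC."""
    return float(delong_covariance(scores, scores, labels, orientation, orientation)[0, 0])


def delong_paired_test(
    scores_a: Sequence[float], scores_b: Sequence[float], labels: Sequence[bool],
    orientation_a: MimicDirection = MimicDirection.HIGHER_IS_MIMIC,
    orientation_b: MimicDirection = MimicDirection.HIGHER_IS_MIMIC,
) -> tuple[float, float]:
    """Paired DeLong z test of AUC_A - AUC_B on a common label vector.

    Returns (z, two-sided p). If the variance of the difference is zero
    (e.g. one score is a monotone transform of the other) the difference
    is degenerate: p = 1 when the AUCs are equal, else 0.
    """
    auc_a = auc(scores_a, labels, orientation_a)
    auc_b = auc(scores_b, labels, orientation_b)
    cov = delong_covariance(scores_a, scores_b, labels, orientation_a, orientation_b)
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diff = auc_a - auc_b
    if var_diff <= 1e-15:
        if math.isclose(diff, 0.0, abs_tol=1e-12):
            return 0.0, 1.0
        return math.copysign(math.inf, diff), 0.0
    z = diff / math.sqrt(var_diff)
    return float(z), float(2 * stats.norm.sf(abs(z)))


def auc_ci(
    scores: Sequence[float], labels: Sequence[bool],
    orientation: MimicDirection = MimicDirection.HIGHER_IS_MIMIC,
    alpha: float = 0.05,
) -> EffectEstimate:
    """AUC with a Wald CI from the DeLong standard error, truncated to [0, 1]."""
    a = auc(scores, labels, orientation)
    se = math.sqrt(delong_variance(scores, labels, orientation))
    z = stats.norm.ppf(1 - alpha / 2)
    return EffectEstimate(
        estimate=a,
        ci_low=max(0.0, a - z * se),
        ci_high=min(1.0, a + z * se),
        alpha=alpha,
        method="DeLong Wald",
    )


def youden_cutoff(
    scores: Sequence[float], labels: Sequence[bool], orientation: MimicDirection
) -> tuple[float, float, float, float]:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Candidates are the midpoints between consecutive distinct (oriented)
    scores plus +/-inf; the scan is exhaustive, so the returned J is the
    global optimum. Ties are broken toward higher sensitivity, then
    toward the lower cutoff. Returns (cutoff on the original scale, J,
    sensitivity, specificity); sensitivity/specificity refer to the
    mimic-positive classification "oriented score >= cutoff".
    """
    s = _oriented(scores, orientation)
    pos, neg = _split(s, labels)
    uniq = np.unique(s)
    candidates = np.concatenate(([-np.inf], (uniq[:-1] + uniq[1:]) / 2, [np.inf]))
    best: tuple[float, float, float, float] | None = None
    for t in candidates:
        sens = float(np.mean(pos >= t))
        spec = float(np.mean(neg < t))
        j = sens + spec - 1
        key = (j, sens, -t)
        if best is None or key > (best[1], best[2], -best[0]):
            best = (float(t), j, sens, spec)
    assert best is not None
    cutoff, j, sens, spec = best
    if orientation is MimicDirection.LOWER_IS_MIMIC:
        cutoff = -cutoff
    return cutoff, j, sens, spec


def _lr_ci(lr: float, num_k: int, num_n: int, den_k: int, den_n: int, alpha: float) -> EffectEstimate:
    """Log-method (Simel) CI for a likelihood ratio built from two proportions."""
    if lr == 0 or not math.isfinite(lr) or 0 in (num_k, den_k):
        return EffectEstimate(lr, 0.0 if lr == 0 else lr, math.inf if lr > 0 else 0.0,
                              alpha=alpha, method="log LR (degenerate)")
    se = math.sqrt(1 / num_k - 1 / num_n + 1 / den_k - 1 / den_n)
    z = stats.norm.ppf(1 - alpha / 2)
    return EffectEstimate(lr, lr * math.exp(-z * se), lr * math.exp(z * se),
                          alpha=alpha, method="log LR")


def performance_from_counts(
    tp: int, fn: int, tn: int, fp: int,
    scale: str = "", cutoff: float = math.nan,
    positive_convention: str = "stroke", alpha: float = 0.05,
) -> PerformanceRow:
    """Operating-point statistics from an explicit 2x2.

    tp/fn count the positive-condition group (true strokes under the
    default convention), tn/fp the other. PPV or NPV is None — flagged,
    not fabricated — when its margin is empty.
    """
    n1, n2 = tp + fn, tn + fp
    if n1 == 0 or n2 == 0:
        raise ValueError("both condition groups must be non-empty")
    sens = proportion_ci(tp, n1, alpha)
    spec = proportion_ci(tn, n2, alpha)
    ppv = proportion_ci(tp, tp + fp, alpha) if tp + fp > 0 else None
    npv = proportion_ci(tn, tn + fn, alpha) if tn + fn > 0 else None
    lr_pos = (sens.estimate / (1 - spec.estimate)) if spec.estimate < 1 else math.inf
    lr_neg = ((1 - sens.estimate) / spec.estimate) if spec.estimate > 0 else math.inf
    return PerformanceRow(
        scale=scale,
        cutoff=cutoff,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        lr_pos=_lr_ci(lr_pos, tp, n1, fp, n2, alpha),
        lr_neg=_lr_ci(lr_neg, fn, n1, tn, n2, alpha),
        counts=(tp, fn, tn, fp),
        positive_convention=positive_convention,
    )


def performance_at_cutoff(
    scores: Sequence[float], labels: Sequence[bool], cutoff: float,
    orientation: MimicDirection = MimicDirection.HIGHER_IS_MIMIC,
    positive_convention: str = "stroke", scale: str = "", alpha: float = 0.05,
) -> PerformanceRow:
    """Dichotomize at a cutoff and compute the full performance row.

    The mimic-indicating side is oriented score >= cutoff. Under the
    default stroke-positive convention the "positive test" is the
    complementary (stroke-indicating) side, so sensitivity is measured
    over the true-stroke group and specificity over the mimics.
    """
    if not math.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    s = _oriented(scores, orientation)
    t = cutoff if orientation is MimicDirection.HIGHER_IS_MIMIC else -cutoff
    y = np.asarray(labels, dtype=bool)
    mimic_side = s >= t
    if positive_convention == "stroke":
        test_pos, condition_pos = ~mimic_side, ~y
    elif positive_convention == "mimic":
        test_pos, condition_pos = mimic_side, y
    else:
        raise ValueError("positive_convention must be 'stroke' or 'mimic'")
    tp = int(np.sum(test_pos & condition_pos))
    fn = int(np.sum(~test_pos & condition_pos))
    tn = int(np.sum(~test_pos & ~condition_pos))
    fp = int(np.sum(test_pos & ~condition_pos))
    return performance_from_counts(
        tp, fn, tn, fp, scale=scale, cutoff=cutoff,
        positive_convention=positive_convention, alpha=alpha,
    )


def performance_from_summary(
    sens: float, spec: float, n_group1: int, n_group2: int,
    scale: str = "", cutoff: float = math.nan, alpha: float = 0.05,
) -> PerformanceRow:
    """Reconstruct the integer 2x2 from summary sensitivity/specificity.

    tp = round(sens * n_group1), tn = round(spec * n_group2); useful for
    checking a published row's internal consistency.
    """
    if not (0 <= sens <= 1 and 0 <= spec <= 1):
        raise ValueError("sens and spec must be fractions in [0, 1]")
    tp = round(sens * n_group1)
    tn = round(spec * n_group2)
    return performance_from_counts(
        tp, n_group1 - tp, tn, n_group2 - tn, scale=scale, cutoff=cutoff, alpha=alpha
    )
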