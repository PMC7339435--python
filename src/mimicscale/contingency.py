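"""2x2 contingency statistics for mimic-vs-stroke group comparisons.

Convention throughout: group 1 is the stroke mimics, group 2 the pooled
ischemic-stroke/TIA ("true stroke") patients, so odds ratios read as the
odds of mimic status given the factor. Odds ratios use the
Haldane–Anscombe continuity correction (add 0.5 to every cell) by
default, which keeps zero-cell rows estimable and matches the corrected
cross-product ratio convention for every row of the reference cohort's
characteristics table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import stats

from .cohort import BOOL_FIELDS, Cohort


class Correction(Enum):
    ALWAYS_HALF = "always_half"   # Haldane–Anscombe: +0.5 to all four cells
    ONLY_IF_ZERO = "only_if_zero"  # +0.5 to all cells only when some cell is 0
    NONE = "none"


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: a/b = group-1 factor present/absent, c/d = group 2."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("table must have at least one observation")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class EffectEstimate:
    """A point estimate with a two-sided confidence interval."""

    estimate: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05
    method: str = ""

    def __post_init__(self) -> None:
        if not self.ci_low <= self.estimate <= self.ci_high:
            raise ValueError(
                f"interval ({self.ci_low}, {self.ci_high}) does not bracket {self.estimate}"
            )


def round_sig(x: float, digits: int = 3) -> float:
    """Round to ``digits`` significant figures (reporting convention)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, digits - 1 - math.floor(math.log10(abs(x))))


def crosstab(cohort: Cohort, factor: str) -> ContingencyTable:
    """Cross-tabulate a boolean factor against mimic vs true-stroke status."""
    if factor not in BOOL_FIELDS:
        raise ValueError(f"{factor!r} is not a boolean patient field")
    a = b = c = d = 0
    for r in cohort.records:
        present = getattr(r, factor)
        if r.is_mimic:
            a, b = a + present, b + (not present)
        else:
            c, d = c + present, d + (not present)
    return ContingencyTable(a=a, b=b, c=c, d=d)


def odds_ratio(
    table: ContingencyTable,
    correction: Correction = Correction.ALWAYS_HALF,
    alpha: float = 0.05,
) -> EffectEstimate:
    """Odds ratio (ad)/(bc) with optional continuity correction.

    The CI is Wald on the log scale with the cell-reciprocal variance,
    computed on the corrected cells when a correction applies.
    """
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    has_zero = min(a, b, c, d) == 0
    if correction is Correction.ALWAYS_HALF or (
        correction is Correction.ONLY_IF_ZERO and has_zero
    ):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    elif has_zero:
        if b == 0 or c == 0:
            cell = "b" if b == 0 else "c"
            raise ZeroDivisionError(
                f"cell {cell!r} is zero: odds ratio undefined without correction"
            )
        if a == 0 and d == 0:
            raise ZeroDivisionError(
                "cells 'a' and 'd' both zero: odds ratio undefined without correction"
            )
    orr = (a * d) / (b * c)
    # a or d may still be 0 under correction=none (OR estimate 0); the
    # log-scale variance is then infinite and the CI degenerates to (0, inf).
    se = math.sqrt(sum(1 / x if x > 0 else math.inf for x in (a, b, c, d)))
    z = stats.norm.ppf(1 - alpha / 2)
    return EffectEstimate(
        estimate=orr,
        ci_low=orr * math.exp(-z * se) if math.isfinite(se) else 0.0,
        ci_high=orr * math.exp(z * se) if math.isfinite(se) else math.inf,
        alpha=alpha,
        method=f"cross-product OR, correction={correction.value}, Wald log-scale CI",
    )


def chi_square(table: ContingencyTable, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square on 1 df; Yates continuity correction optional.

    chi2 = N (|ad - bc| - [N/2])^2 / ((a+b)(c+d)(a+c)(b+d)), the
    bracketed N/2 subtracted (floored at zero) only under Yates.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.total
    margins = (a + b, c + d, a + c, b + d)
    if 0 in margins:
        raise ValueError("degenerate table: a zero marginal")
    diff = abs(a * d - b * c)
    if yates:
        diff = max(diff - n / 2, 0.0)
    chi2 = n * diff**2 / math.prod(margins)
    return chi2, float(stats.chi2.sf(chi2, df=1))


def fisher_exact(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value (hypergeometric tail sum)."""
    return float(stats.fisher_exact(table.as_array(), alternative="two-sided")[1])


def mann_whitney(
    values_group1: Sequence[float], values_group2: Sequence[float]
) -> tuple[float, float]:
    """Mann–Whitney U (group 1's U, midrank ties) and the two-sided p from
    the tie-corrected normal approximation."""
    if len(values_group1) == 0 or len(values_group2) == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(
        values_group1, values_group2, alternative="two-sided", method="asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


def proportion_ci(k: int, n: int, alpha: float = 0.05) -> EffectEstimate:
    """Clopper–Pearson exact interval for a binomial proportion k/n."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return EffectEstimate(
        estimate=k / n, ci_low=lo, ci_high=hi, alpha=alpha, method="Clopper-Pearson"
    )


#: Table-2-style factor list, in reporting order (boolean factors only;
#: age/SBP/DBP/NIHSS are continuous and summarised separately).
CATEGORICAL_FACTORS: tuple[str, ...] = (
    "migraine",
    "psychiatric_history",
    "seizure_history",
    "hypertension",
    "hyperlipidemia",
    "diabetes",
    "atrial_fibrillation",
    "facial_droop",
    "isolated_sensory_deficit",
)


@dataclass
class FactorRow:
    """One factor's row of the characteristics table."""

    factor: str
    table: ContingencyTable
    odds_ratio: EffectEstimate
    chi2: float
    p_chi2: float
    p_fisher: float


def characteristics_table(cohort: Cohort, factors: Sequence[str] = CATEGORICAL_FACTORS) -> list[FactorRow]:
    """Per-factor 2x2, Haldane–Anscombe OR, chi-square and Fisher p-values."""
    rows = []
    for f in factors:
        t = crosstab(cohort, f)
        try:
            chi2, p = chi_square(t)
        except ValueError:  # zero marginal (e.g. factor absent everywhere)
            chi2, p = float("nan"), float("nan")
        rows.append(
            FactorRow(
                factor=f,
                table=t,
                odds_ratio=odds_ratio(t),
                chi2=chi2,
                p_chi2=p,
                p_fisher=fisher_exact(t),
            )
        )
    return rows
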