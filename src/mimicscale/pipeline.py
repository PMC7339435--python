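"""End-to-end validation pipeline.

Runs the full study replica on a cohort: score the four scales, build
the clinical-characteristics (Table-2-style) summary, the per-scale
operating-point performance (Table-3-style) rows with paired DeLong
comparisons against a reference scale, and the decision tree with
cross-validation — consolidated into one deterministic, serializable
report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from . import contingency, roc, scales, tree as tree_mod
from .cohort import Cohort, group_sizes
from .contingency import ContingencyTable, EffectEstimate, round_sig
from .scales import ORIENTATIONS

logger = logging.getLogger(__name__)

#: Published operating cutoffs of the four scales.
PUBLISHED_CUTOFFS: dict[str, float] = {"fabs": 2, "sfabs": 2, "tms": 13.6, "khan": 2}

#: Continuous variables summarised (median/range + rank test) in the
#: characteristics table.
CONTINUOUS_VARS = ("age", "sbp", "dbp", "nihss")


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one validation run."""

    reference_scale: str = "tms"
    cutoffs: str = "auto"  # "auto" (Youden) or "published"
    tree: tree_mod.TreeConfig = field(default_factory=tree_mod.TreeConfig)
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reference_scale not in ORIENTATIONS:
            raise ValueError(f"unknown reference scale {self.reference_scale!r}")
        if self.cutoffs not in ("auto", "published"):
            raise ValueError("cutoffs must be 'auto' or 'published'")

    def hash(self) -> str:
        blob = json.dumps(
            {**asdict(self), "tree": asdict(self.tree)}, sort_keys=True, default=str
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _ee(e: EffectEstimate | None) -> dict | None:
    if e is None:
        return None
    return {"estimate": e.estimate, "ci_low": e.ci_low, "ci_high": e.ci_high}


def _derived_factor_table(cohort: Cohort, predicate) -> ContingencyTable:
    a = b = c = d = 0
    for r in cohort.records:
        present = predicate(r)
        if r.is_mimic:
            a, b = a + present, b + (not present)
        else:
            c, d = c + present, d + (not present)
    return ContingencyTable(a=a, b=b, c=c, d=d)


def characteristics_rows(cohort: Cohort) -> list[dict]:
    """Table-2-style rows: continuous summaries with rank-test p-values,
    plus per-factor 2x2s with Haldane–Anscombe ORs and chi-square p."""
    mimics = [r for r in cohort.records if r.is_mimic]
    strokes = [r for r in cohort.records if not r.is_mimic]
    rows: list[dict] = []
    for var in CONTINUOUS_VARS:
        v_m = [getattr(r, var) for r in mimics]
        v_s = [getattr(r, var) for r in strokes]
        u, p = contingency.mann_whitney(v_m, v_s)
        rows.append(
            {
                "variable": var, "kind": "continuous",
                "stroke_mean": float(np.mean(v_s)), "stroke_sd": float(np.std(v_s, ddof=1)),
                "mimic_mean": float(np.mean(v_m)), "mimic_sd": float(np.std(v_m, ddof=1)),
                "stroke_median": float(np.median(v_s)), "mimic_median": float(np.median(v_m)),
                "p_mann_whitney": p,
            }
        )
    factor_tables: list[tuple[str, ContingencyTable]] = [
        ("female", _derived_factor_table(cohort, lambda r: r.sex == "female")),
        ("age_lt_50", _derived_factor_table(cohort, lambda r: r.age < 50)),
    ]
    factor_tables += [
        (f, contingency.crosstab(cohort, f)) for f in contingency.CATEGORICAL_FACTORS
    ]
    for name, t in factor_tables:
        est = contingency.odds_ratio(t)
        try:
            chi2, p = contingency.chi_square(t)
        except ValueError:
            chi2, p = math.nan, math.nan
        rows.append(
            {
                "variable": name, "kind": "categorical",
                "counts": {"a": t.a, "b": t.b, "c": t.c, "d": t.d},
                "mimic_pct": 100 * t.a / (t.a + t.b) if t.a + t.b else math.nan,
                "stroke_pct": 100 * t.c / (t.c + t.d) if t.c + t.d else math.nan,
                "odds_ratio": round_sig(est.estimate, 3),
                "or_ci_low": est.ci_low, "or_ci_high": est.ci_high,
                "p_chi2": p, "p_fisher": contingency.fisher_exact(t),
            }
        )
    return rows


def performance_rows(cohort: Cohort, config: PipelineConfig) -> list[dict]:
    """Table-3-style rows: AUC with DeLong CI, DeLong p vs the reference
    scale, cutoff (Youden-optimal or published) and operating-point stats."""
    labels = [r.is_mimic for r in cohort.records]
    results = scales.score_cohort(cohort)
    score_vectors = {name: [getattr(s, name) for s in results] for name in ORIENTATIONS}
    ref = config.reference_scale
    rows = []
    for name, orientation in ORIENTATIONS.items():
        sc = score_vectors[name]
        if len(set(sc)) == 1:
            logger.warning("scale %s is constant on this cohort; AUROC = 0.5", name)
            auc_est = EffectEstimate(0.5, 0.0, 1.0, method="degenerate (constant scale)")
        else:
            auc_est = roc.auc_ci(sc, labels, orientation)
        if name == ref:
            delong_p = None
        else:
            _, delong_p = roc.delong_paired_test(
                sc, score_vectors[ref], labels, orientation, ORIENTATIONS[ref]
            )
        if config.cutoffs == "published":
            cutoff = PUBLISHED_CUTOFFS[name]
        else:
            cutoff, _, _, _ = roc.youden_cutoff(sc, labels, orientation)
            if not math.isfinite(cutoff):  # degenerate: fall back to published
                cutoff = PUBLISHED_CUTOFFS[name]
        perf = roc.performance_at_cutoff(sc, labels, cutoff, orientation, scale=name)
        rows.append(
            {
                "scale": name,
                "auroc": _ee(auc_est),
                "delong_p_vs_reference": delong_p,
                "cutoff": cutoff,
                "sensitivity": _ee(perf.sensitivity),
                "specificity": _ee(perf.specificity),
                "ppv": _ee(perf.ppv),
                "npv": _ee(perf.npv),
                "lr_pos": _ee(perf.lr_pos),
                "lr_neg": _ee(perf.lr_neg),
                "counts_tp_fn_tn_fp": list(perf.counts),
                "positive_convention": perf.positive_convention,
            }
        )
    return rows


def run_validation(cohort: Cohort, config: PipelineConfig | None = None) -> dict:
    """Run all stages and return the consolidated report as a plain dict.

    Every number in the report is recomputed from the cohort and config;
    with a fixed seed the JSON serialization is byte-identical across
    runs (no timestamps inside the hashed payload).
    """
    config = config or PipelineConfig()
    n_stroke, n_mimic = group_sizes(cohort)
    if n_stroke == 0 or n_mimic == 0:
        raise ValueError("cohort must contain both mimics and true strokes")
    tree_config = tree_mod.TreeConfig(
        features=config.tree.features,
        min_node_size=config.tree.min_node_size,
        max_depth=config.tree.max_depth,
        prune_fraction=config.tree.prune_fraction,
        seed=config.seed if config.tree.seed is None else config.tree.seed,
    )
    fitted = tree_mod.fit(cohort.records, tree_config)
    cv = tree_mod.cross_validate(cohort.records, tree_config, k=min(config.cv_folds, n_mimic))
    return {
        "cohort": {
            "n": len(cohort.records),
            "n_true_stroke": n_stroke,
            "n_mimic": n_mimic,
            "mimic_prevalence": n_mimic / len(cohort.records),
            "excluded_count": cohort.excluded_count,
        },
        "table2": characteristics_rows(cohort),
        "table3": performance_rows(cohort, config),
        "tree": {"model": fitted.to_dict(), "cv": cv.to_dict()},
        "provenance": {"seed": config.seed, "config_hash": config.hash()},
    }


def report_to_json(report: dict, **kwargs) -> str:
    kwargs.setdefault("indent", 2)
    kwargs.setdefault("sort_keys", True)
    return json.dumps(report, **kwargs)


def _fmt_pct(x: float | None) -> str:
    return "—" if x is None else f"{100 * x:.1f}"


def report_to_markdown(report: dict) -> str:
    """Human-readable tables with paper-style rounding (ORs to 3 s.f.,
    percentages to 1 d.p.)."""
    lines = ["# Stroke-mimic scale validation report", ""]
    c = report["cohort"]
    lines += [
        f"Cohort: {c['n']} patients — {c['n_true_stroke']} true stroke/TIA, "
        f"{c['n_mimic']} mimics ({100 * c['mimic_prevalence']:.1f}%).",
        "",
        "## Clinical characteristics",
        "",
        "| Variable | True stroke | Mimic | OR (95% CI) | p |",
        "|---|---|---|---|---|",
    ]
    for row in report["table2"]:
        if row["kind"] == "continuous":
            lines.append(
                f"| {row['variable']} | {row['stroke_mean']:.0f} ({row['stroke_sd']:.0f}) "
                f"| {row['mimic_mean']:.0f} ({row['mimic_sd']:.0f}) | — "
                f"| {row['p_mann_whitney']:.3f} |"
            )
        else:
            cts = row["counts"]
            lines.append(
                f"| {row['variable']} | {cts['c']} ({row['stroke_pct']:.1f}%) "
                f"| {cts['a']} ({row['mimic_pct']:.1f}%) "
                f"| {row['odds_ratio']:g} ({round_sig(row['or_ci_low'], 3):g}–"
                f"{round_sig(row['or_ci_high'], 3):g}) | {row['p_chi2']:.3f} |"
            )
    lines += [
        "",
        "## Scale performance",
        "",
        "| Scale | AUROC (95% CI) | DeLong p | Cutoff | Sens % | Spec % | PPV % | NPV % | LR+ | LR− |",
        "|---|---|---|---|---|---|---|---|---|---|",
    ]
    for row in report["table3"]:
        a = row["auroc"]
        dp = row["delong_p_vs_reference"]
        lines.append(
            f"| {row['scale']} | {a['estimate']:.3f} ({a['ci_low']:.3f}–{a['ci_high']:.3f}) "
            f"| {'ref' if dp is None else f'{dp:.3f}'} | {row['cutoff']:g} "
            f"| {_fmt_pct(row['sensitivity']['estimate'])} "
            f"| {_fmt_pct(row['specificity']['estimate'])} "
            f"| {_fmt_pct((row['ppv'] or {}).get('estimate'))} "
            f"| {_fmt_pct((row['npv'] or {}).get('estimate'))} "
            f"| {row['lr_pos']['estimate']:.2f} | {row['lr_neg']['estimate']:.2f} |"
        )
    cv = report["tree"]["cv"]
    lines += [
        "",
        "## Decision tree",
        "",
        f"Cross-validated misclassification {100 * cv['misclassification_rate']:.1f}%, "
        f"sensitivity {100 * cv['sensitivity']:.1f}%, "
        f"specificity {100 * cv['specificity']:.1f}% (stroke-positive convention).",
        "",
    ]
    return "\n".join(lines)
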