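"""Cohort statistics: category comparisons and the burden-TMB association.

Mutation counts and TMB are compared between MSI categories with the
unpaired two-sample Wilcoxon (Mann-Whitney) rank-sum test — exact when both
groups are small and tie-free, normal approximation with tie and continuity
correction otherwise.  The burden-TMB association is summarized by the
Pearson correlation (with its t-test p-value) and an ordinary least-squares
regression of TMB on burden; both r and R² are reported.  Quartiles use
linear interpolation between order statistics (R's default type-7
convention).  Significance level alpha = 0.05, with no multiple-testing
correction across the pairwise comparisons.
"""

from __future__ import annotations

import json
import math
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_burden import CATEGORIES, BurdenRecord
from .tmb_calc import TMBResult

__all__ = [
    "quartile_summary",
    "wilcoxon_pairwise",
    "burden_tmb_association",
    "histotype_summary",
    "cohort_count_summary",
    "build_report",
    "write_report",
]

ALPHA = 0.05
#: Maximum group size for the exact Mann-Whitney null distribution.
EXACT_MAX_N = 25


def quartile_summary(values: Sequence[float]) -> tuple[int, float, float, float]:
    """(n, median, Q1, Q3) with type-7 linear interpolation."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("quartile_summary needs at least one observation")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return int(arr.size), float(med), float(q1), float(q3)


def _mannwhitney_p(x: np.ndarray, y: np.ndarray) -> float:
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) <= EXACT_MAX_N and len(y) <= EXACT_MAX_N
                         and not has_ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided",
                           method=method, use_continuity=True).pvalue
    )


def wilcoxon_pairwise(
    values_by_category: Mapping[str, Sequence[float]],
) -> dict[tuple[str, str], float | None]:
    """Two-sided rank-sum p-value for every category pair.

    Pairs involving an empty category are reported as ``None`` rather than
    raising.
    """
    if len(values_by_category) < 2:
        raise ValueError("need at least two categories")
    out: dict[tuple[str, str], float | None] = {}
    for a, b in combinations(sorted(values_by_category), 2):
        x = np.asarray(values_by_category[a], dtype=float)
        y = np.asarray(values_by_category[b], dtype=float)
        out[(a, b)] = None if (x.size == 0 or y.size == 0) else _mannwhitney_p(x, y)
    return out


def burden_tmb_association(
    burdens: Sequence[float],
    tmbs: Sequence[float],
) -> dict[str, float] | None:
    """Pearson r (with p), OLS slope/intercept of TMB on burden, and R².

    Returns ``None`` when either variable has zero variance (the correlation
    is undefined).
    """
    x = np.asarray(burdens, dtype=float)
    y = np.asarray(tmbs, dtype=float)
    if x.size != y.size:
        raise ValueError("burden and TMB vectors must be paired by sample")
    if x.size < 3:
        raise ValueError("need at least three paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in burden/TMB")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    r, p = stats.pearsonr(x, y)
    reg = stats.linregress(x, y)
    return {
        "pearson_r": float(r),
        "p_value": float(p),
        "slope": float(reg.slope),
        "intercept": float(reg.intercept),
        "r_squared": float(r) ** 2,
    }


def histotype_summary(
    burden_records: Sequence[BurdenRecord],
    tmb_results: Sequence[TMBResult] | None = None,
) -> pd.DataFrame:
    """Per-histotype table: n, MSI prevalence, median burden, event load.

    MSI prevalence is the share of samples with at least one raw unstable
    locus; the median burden is taken over the classified (MSI-H/MSI-L)
    samples.  When TMB results are supplied their sample ids must match the
    burden records exactly.
    """
    if tmb_results is not None:
        b_ids = {r.sample for r in burden_records}
        t_ids = {t.sample for t in tmb_results}
        odd = b_ids ^ t_ids
        if odd:
            raise ValueError(f"samples missing from one input: {sorted(odd)[:10]}")
        tmb_by_sample = {t.sample: t.tmb for t in tmb_results}
    rows = []
    by_hist: dict[str, list[BurdenRecord]] = {}
    for r in burden_records:
        by_hist.setdefault(r.histotype, []).append(r)
    for hist in sorted(by_hist):
        recs = by_hist[hist]
        n = len(recs)
        n_msi = sum(1 for r in recs if r.raw_event_count >= 1)
        classified = [r.burden for r in recs if r.category in ("MSI-H", "MSI-L")]
        row = {
            "histotype": hist,
            "n": n,
            "n_msi_positive": n_msi,
            "msi_prevalence_pct": 100.0 * n_msi / n,
            "median_burden_pct": (100.0 * float(np.median(classified))
                                  if classified else float("nan")),
            "mean_raw_events": float(np.mean([r.raw_event_count for r in recs])),
        }
        for c in CATEGORIES:
            row[f"n_{c}"] = sum(1 for r in recs if r.category == c)
        if tmb_results is not None:
            row["median_tmb"] = float(np.median([tmb_by_sample[r.sample] for r in recs]))
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_count_summary(
    histotype_counts: Mapping[str, int],
    n_msi_positive: int,
    n_classified: int,
) -> dict[str, int]:
    """Cohort arithmetic from printed per-histotype counts.

    Returns the cohort total, the MSI prevalence as a rounded percentage, and
    the number of samples excluded for carrying only patient-specific events
    (MSI-positive but with no recurrent-panel locus affected).
    """
    total = int(sum(histotype_counts.values()))
    if not 0 <= n_classified <= n_msi_positive <= total:
        raise ValueError("counts must satisfy classified <= MSI-positive <= total")
    prevalence_pct = int(round(100.0 * n_msi_positive / total))
    return {
        "total_samples": total,
        "n_msi_positive": n_msi_positive,
        "msi_prevalence_pct": prevalence_pct,
        "n_classified": n_classified,
        "n_patient_specific_excluded": n_msi_positive - n_classified,
    }


def _category_values(
    records: Sequence[BurdenRecord],
    values_by_sample: Mapping[str, float],
) -> dict[str, list[float]]:
    out: dict[str, list[float]] = {c: [] for c in ("MSI-H", "MSI-L", "MSS")}
    for r in records:
        if r.category in out:
            out[r.category].append(values_by_sample[r.sample])
    return out


def build_report(
    burden_records: Sequence[BurdenRecord],
    tmb_results: Sequence[TMBResult],
    mutation_counts: Mapping[str, int] | None = None,
    threshold: float | None = None,
) -> dict:
    """Assemble the full cohort statistics report.

    ``mutation_counts`` maps sample id to its consensus somatic mutation
    count (all effects); when omitted the coding count from the TMB results
    is used.  EXCLUDED samples take part in no category comparison (stated in
    the report).
    """
    tmb_by_sample = {t.sample: t.tmb for t in tmb_results}
    if mutation_counts is None:
        mutation_counts = {t.sample: t.n_coding for t in tmb_results}
    missing = {r.sample for r in burden_records} - set(tmb_by_sample)
    if missing:
        raise ValueError(f"samples without TMB: {sorted(missing)[:10]}")

    def summarize(groups: dict[str, list[float]]) -> dict:
        per_cat = {}
        for cat, vals in groups.items():
            if vals:
                n, med, q1, q3 = quartile_summary(vals)
                per_cat[cat] = {"n": n, "median": med, "q1": q1, "q3": q3}
            else:
                per_cat[cat] = {"n": 0, "median": None, "q1": None, "q3": None}
        pw = wilcoxon_pairwise(groups)
        return {
            "by_category": per_cat,
            "pairwise_wilcoxon_p": {f"{a} vs {b}": p for (a, b), p in pw.items()},
        }

    mut_groups = _category_values(burden_records, mutation_counts)
    tmb_groups = _category_values(burden_records, tmb_by_sample)

    classified = [r for r in burden_records if r.category in ("MSI-H", "MSI-L")]
    assoc = (
        burden_tmb_association(
            [r.burden for r in classified],
            [tmb_by_sample[r.sample] for r in classified],
        )
        if len(classified) >= 3
        else None
    )

    hist_table = histotype_summary(burden_records, tmb_results)
    report = {
        "alpha": ALPHA,
        "quartile_convention": "type-7 linear interpolation",
        "wilcoxon": "unpaired two-sample rank-sum, two-sided",
        "comparison_population": "EXCLUDED samples omitted from category comparisons",
        "threshold_burden_pct": None if threshold is None else 100.0 * threshold,
        "category_counts": {
            c: sum(1 for r in burden_records if r.category == c) for c in CATEGORIES
        },
        "somatic_mutations": summarize(mut_groups),
        "tmb": summarize(tmb_groups),
        "burden_tmb_association": assoc if assoc is not None else "not-computable",
        "histotypes": hist_table.to_dict(orient="records"),
    }
    return report


def write_report(report: dict, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            v = float(o)
            return None if math.isnan(v) else v
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_default)
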