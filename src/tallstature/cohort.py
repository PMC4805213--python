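"""Cohort-level summaries and two-group statistics for referral cohorts.

Thin, explicit wrappers around scipy.stats provide the tests the analysis
uses: the uncorrected Pearson chi-square for 2x2 tables (no Yates continuity
correction — the convention under which the family-history comparison prints
p=0.49), Welch's unequal-variance t-test for continuous contrasts, and the
Pearson correlation with its two-sided t-transform p-value.  All p-values
are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .auxology import AuxologyProfile, PatientRecord
from .classify import ClassificationResult, ItsSubclass
from .errors import ValidationError
from .references import Sex

__all__ = [
    "CohortSummary",
    "summarize",
    "chi_square_2x2",
    "welch_t",
    "pearson_r",
]


@dataclass
class CohortSummary:
    """Descriptives for one cohort; ``mean_sd`` maps variable -> (mean, sd, n).

    The SD is ``None`` for degenerate n=1 denominators.  Percentages are
    computed against the stated denominators and counts are conserved across
    every partition reported.
    """

    n: int
    n_by_sex: dict[str, int]
    mean_sd: dict[str, tuple[float, Optional[float], int]]
    classification_counts: dict[str, int] = field(default_factory=dict)
    classification_percent: dict[str, float] = field(default_factory=dict)
    fts_criterion_counts: dict[str, int] = field(default_factory=dict)
    n_tall: int = 0
    n_not_tall: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"variable": k, "mean": m, "sd": s, "n": n}
            for k, (m, s, n) in self.mean_sd.items()
        ]
        return pd.DataFrame(rows)


def _mean_sd(values: Sequence[Optional[float]]) -> Optional[tuple[float, Optional[float], int]]:
    arr = np.array([v for v in values if v is not None], dtype=float)
    if arr.size == 0:
        return None
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else None
    return float(np.mean(arr)), sd, int(arr.size)


def summarize(
    records: Sequence[PatientRecord],
    profiles: Sequence[AuxologyProfile],
    classifications: Optional[Sequence[ClassificationResult]] = None,
) -> CohortSummary:
    """Aggregate a cohort into descriptive statistics.

    Missing fields are excluded pairwise, with the effective n reported per
    variable.  When classifications are supplied, ITS subclass percentages
    use the idiopathic tall children (subclass != not_applicable) as the
    denominator, and the per-criterion FTS counts tally children for whom
    each criterion (and "any") holds.
    """
    if not records:
        raise ValidationError("cannot summarize an empty cohort")
    if len(records) != len(profiles):
        raise ValidationError("records and profiles must align")

    n = len(records)
    n_by_sex = {
        "male": sum(1 for r in records if r.sex is Sex.MALE),
        "female": sum(1 for r in records if r.sex is Sex.FEMALE),
    }
    variables = {
        "age": [r.ca for r in records],
        "hsds": [p.hsds for p in profiles],
        "th_sds": [p.th_tanner_sds for p in profiles],
        "dist_th": [p.dist_th for p in profiles],
        "ba_advance": [p.ba_advance_years for p in profiles],
    }
    mean_sd = {}
    for name, vals in variables.items():
        ms = _mean_sd(vals)
        if ms is not None:
            mean_sd[name] = ms

    summary = CohortSummary(n=n, n_by_sex=n_by_sex, mean_sd=mean_sd)

    if classifications is not None:
        if len(classifications) != n:
            raise ValidationError("classifications must align with records")
        summary.n_tall = sum(1 for c in classifications if c.is_tall)
        summary.n_not_tall = n - summary.n_tall
        counts: dict[str, int] = {s.value: 0 for s in ItsSubclass}
        for c in classifications:
            counts[c.its_subclass.value] += 1
        summary.classification_counts = counts
        its_n = n - counts[ItsSubclass.NOT_APPLICABLE.value]
        if its_n > 0:
            summary.classification_percent = {
                k: 100.0 * v / its_n
                for k, v in counts.items()
                if k != ItsSubclass.NOT_APPLICABLE.value
            }
        crit = {"by_th": 0, "by_cth": 0, "by_tallest_parent": 0, "any": 0}
        for c in classifications:
            trio = (c.fts_by_th, c.fts_by_cth, c.fts_by_tallest_parent)
            crit["by_th"] += trio[0] is True
            crit["by_cth"] += trio[1] is True
            crit["by_tallest_parent"] += trio[2] is True
            crit["any"] += any(x is True for x in trio)
        summary.fts_criterion_counts = crit
    return summary


def chi_square_2x2(table: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Pearson chi-square (df=1, no continuity correction) on a 2x2 table."""
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValidationError("table must be 2x2")
    if np.any(arr < 0):
        raise ValidationError("counts must be non-negative")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValidationError("all margins must be positive")
    stat, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return float(stat), float(p)


def welch_t(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Welch unequal-variance t-test, two-sided p.

    With zero variance in both groups the p-value is undefined and returned
    as NaN rather than raising.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 observations")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        return float("inf"), float("nan")
    stat, p = stats.ttest_ind(a, b, equal_var=False)
    return float(stat), float(p)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation with two-sided p via the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need matched samples of size >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("inputs must be finite")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValidationError("correlation undefined for zero-variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
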