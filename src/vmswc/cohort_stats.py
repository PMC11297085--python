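"""Descriptive and comparative cohort statistics.

Continuous variables are summarized as median (IQR), categorical variables
as n (%), at the level of the survey couplet.  Group comparisons use a
pooled-variance two-sample t test for continuous variables and a Pearson
chi-square (no continuity correction) for categorical tables, flagged
against a Bonferroni-corrected alpha = 0.05 / m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import CohortTable, INTERVENTIONS, MENOPAUSE_LEVELS
from .scoring import hfrs_score
from .weighted_change import InsufficientDataError

__all__ = ["CohortSummary", "summarize", "compare_groups"]

_CONTINUOUS = (
    ("age_years", "Age (years)"),
    ("baseline_hfrs", "Baseline HFRS"),
    ("vms_per_week", "VMS per week"),
    ("et_months", "Time on endocrine therapy (months)"),
    ("adherence_days", "Adherence (days)"),
    ("days_between", "Days between questionnaires"),
)


@dataclass
class CohortSummary:
    n_couplets: int
    n_patients: int
    continuous: dict[str, dict] = field(default_factory=dict)
    categorical: dict[str, dict] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, s in self.continuous.items():
            if s["n"] == 0:
                val = "missing"
            else:
                val = f"{s['median']:.1f} ({s['q1']:.1f}, {s['q3']:.1f})"
            rows.append({"variable": s["label"], "summary": val, "n": s["n"]})
        for name, s in self.categorical.items():
            for level, cnt in s["counts"].items():
                pct = 100.0 * cnt / self.n_couplets if self.n_couplets else 0.0
                rows.append(
                    {
                        "variable": f"{s['label']}: {level}",
                        "summary": f"{cnt} ({pct:.0f}%)",
                        "n": s["n"],
                    }
                )
        return pd.DataFrame(rows, columns=["variable", "summary", "n"])

    def render(self) -> str:
        df = self.to_frame()
        return df.to_string(index=False)


def _quantiles(values: Sequence[float]) -> dict:
    arr = np.asarray([v for v in values if v is not None], dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        return {"n": 0, "median": None, "q1": None, "q3": None}
    return {
        "n": int(arr.size),
        "median": float(np.median(arr)),
        "q1": float(np.quantile(arr, 0.25)),
        "q3": float(np.quantile(arr, 0.75)),
    }


def summarize(cohort: CohortTable) -> CohortSummary:
    """Median/IQR for continuous and n (%) for categorical cohort variables."""
    if len(cohort) == 0:
        raise InsufficientDataError("empty cohort")
    values: dict[str, list] = {k: [] for k, _ in _CONTINUOUS}
    interventions: list[str] = []
    menopause: list[Optional[str]] = []
    for c in cohort:
        base = hfrs_score(c.baseline_domains)
        values["baseline_hfrs"].append(base.value)
        values["age_years"].append(c.age_years)
        values["vms_per_week"].append(c.vms_per_week)
        values["et_months"].append(c.et_duration_months)
        values["adherence_days"].append(c.adherence_days)
        values["days_between"].append(c.days_between)
        interventions.append(c.intervention)
        menopause.append(c.menopausal_status)

    summary = CohortSummary(
        n_couplets=len(cohort),
        n_patients=len({c.patient_id for c in cohort}),
    )
    for key, label in _CONTINUOUS:
        q = _quantiles(values[key])
        q["label"] = label
        summary.continuous[key] = q
    summary.categorical["intervention"] = {
        "label": "Intervention",
        "n": len(interventions),
        "counts": {lv: interventions.count(lv) for lv in INTERVENTIONS},
    }
    present = [m for m in menopause if m is not None]
    summary.categorical["menopause"] = {
        "label": "Menopausal status",
        "n": len(present),
        "counts": {lv: present.count(lv) for lv in MENOPAUSE_LEVELS},
    }
    return summary


def compare_groups(
    a,
    b,
    kind: str = "continuous_t",
    m_comparisons: int = 1,
) -> dict:
    """Two-group comparison with a Bonferroni-corrected significance flag.

    ``kind="continuous_t"``: pooled-variance two-sample t test on two value
    vectors.  ``kind="categorical_chi2"``: Pearson chi-square on two count
    vectors over the same categories (no Yates correction).
    """
    if m_comparisons < 1:
        raise ValueError("m_comparisons must be >= 1")
    alpha = 0.05 / m_comparisons
    if kind == "continuous_t":
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        a = a[~np.isnan(a)]
        b = b[~np.isnan(b)]
        if a.size < 2 or b.size < 2:
            raise InsufficientDataError("need >= 2 observations per group")
        res = stats.ttest_ind(a, b, equal_var=True)
        stat, p = float(res.statistic), float(res.pvalue)
        df = int(a.size + b.size - 2)
        out = {"statistic": stat, "p": p, "df": df}
    elif kind == "categorical_chi2":
        table = np.asarray([list(a), list(b)], dtype=float)
        if table.min() < 0 or table.sum(axis=1).min() == 0:
            raise InsufficientDataError("degenerate contingency table")
        expected = (
            table.sum(axis=1, keepdims=True)
            * table.sum(axis=0, keepdims=True)
            / table.sum()
        )
        if expected.min() < 1:
            raise InsufficientDataError(
                "expected cell count < 1; chi-square approximation invalid"
            )
        stat, p, dof, _ = stats.chi2_contingency(table, correction=False)
        out = {"statistic": float(stat), "p": float(p), "df": int(dof)}
    else:
        raise ValueError(f"unknown comparison kind {kind!r}")
    out["alpha_corrected"] = alpha
    out["significant_after_bonferroni"] = out["p"] < alpha
    return out
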