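"""HFRS composite scoring, anchor coding, and raw change records.

The Hot Flush Rating Scale (HFRS) composite is the arithmetic mean of three
0-10 severity domains (distress, problems, disruption).  A couplet is
*complete* only when all three domains were answered at a time point; no
partial-mean imputation is performed.

The raw change score is ``C = X2 - X1`` (follow-up minus baseline), so
improvement is a negative change.  Zero change is, by definition,
non-improvement.  The five-level effectiveness Likert item is coded 1-5
with "not applicable" collapsed to neutral (3).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .data_model import LIKERT_LEVELS, SurveyCouplet, ValidationError

__all__ = [
    "IMPROVEMENT",
    "NON_IMPROVEMENT",
    "HfrsScore",
    "ChangeRecord",
    "hfrs_score",
    "code_likert",
    "change_record",
    "change_records",
]

IMPROVEMENT = "improvement"
NON_IMPROVEMENT = "non_improvement"

_LIKERT_CODES = {
    "strongly_disagree": 1,
    "disagree": 2,
    "neutral": 3,
    "agree": 4,
    "strongly_agree": 5,
    "not_applicable": 3,
}


@dataclass(frozen=True)
class HfrsScore:
    value: Optional[float]
    complete: bool


@dataclass(frozen=True)
class ChangeRecord:
    """Raw change for one couplet: C = X2 - X1, with direction stratum."""

    couplet_id: str
    X1: float
    X2: float
    C: float
    stratum: str
    anchor: Optional[int]


def hfrs_score(domains: Sequence[Optional[float]]) -> HfrsScore:
    """Composite HFRS score: the mean of three 0-10 domains.

    Complete iff all three domains are present; otherwise no value.
    """
    if len(domains) != 3:
        raise ValidationError(f"expected 3 domain scores, got {len(domains)}")
    vals = []
    for i, d in enumerate(domains):
        if d is None:
            continue
        d = float(d)
        if not (0.0 <= d <= 10.0):
            raise ValidationError(f"domain[{i}]={d} outside [0, 10]")
        vals.append(d)
    if len(vals) < 3:
        return HfrsScore(value=None, complete=False)
    return HfrsScore(value=sum(vals) / 3.0, complete=True)


def code_likert(raw: Optional[str]) -> Optional[int]:
    """Code the effectiveness Likert level to 1-5 (not_applicable -> 3)."""
    if raw is None:
        return None
    if raw not in LIKERT_LEVELS:
        raise ValidationError(f"unknown likert level {raw!r}")
    return _LIKERT_CODES[raw]


def change_record(couplet: SurveyCouplet) -> Optional[ChangeRecord]:
    """Raw change record for a couplet, or ``None`` if either HFRS composite
    is incomplete.

    Improvement is a strictly negative change; zero or positive change falls
    in the non-improvement stratum.
    """
    base = hfrs_score(couplet.baseline_domains)
    follow = hfrs_score(couplet.followup_domains)
    if not (base.complete and follow.complete):
        return None
    c = follow.value - base.value
    return ChangeRecord(
        couplet_id=couplet.couplet_id,
        X1=base.value,
        X2=follow.value,
        C=c,
        stratum=IMPROVEMENT if c < 0 else NON_IMPROVEMENT,
        anchor=code_likert(couplet.likert_raw),
    )


def change_records(couplets) -> list[ChangeRecord]:
    """Change records for every couplet with complete baseline and follow-up."""
    out = []
    for c in couplets:
        rec = change_record(c)
        if rec is not None:
            out.append(rec)
    return out
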