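"""Core record types and delimited-text I/O for survey-couplet cohorts.

A *survey couplet* is one baseline + follow-up questionnaire pair from a
single patient: three 0-10 Hot Flush Rating Scale (HFRS) severity domains
at each time point, a five-level Likert treatment-effectiveness item (the
anchor), the chosen intervention arm, and a handful of clinical covariates.
Patients may contribute more than one couplet; the analysis treats couplets
as the unit of observation and keeps ``patient_id`` for descriptive counts
only.

Cohorts are stored as UTF-8 CSV with a fixed header (:data:`CSV_COLUMNS`);
missing values are empty cells, never numeric sentinels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd

__all__ = [
    "LIKERT_LEVELS",
    "INTERVENTIONS",
    "MENOPAUSE_LEVELS",
    "CSV_COLUMNS",
    "SurveyCouplet",
    "CohortTable",
    "ValidationError",
    "FormatError",
    "read_cohort",
    "write_cohort",
]

LIKERT_LEVELS = (
    "strongly_disagree",
    "disagree",
    "neutral",
    "agree",
    "strongly_agree",
    "not_applicable",
)

INTERVENTIONS = ("lifestyle", "cam", "drug", "endocrine_modification", "control")

MENOPAUSE_LEVELS = ("pre_peri", "post")

CSV_COLUMNS = (
    "couplet_id",
    "patient_id",
    "b_dom1",
    "b_dom2",
    "b_dom3",
    "f_dom1",
    "f_dom2",
    "f_dom3",
    "likert",
    "intervention",
    "age_years",
    "menopause",
    "et_months",
    "adherence_days",
    "days_between",
    "vms_per_week",
)


class ValidationError(ValueError):
    """A field value violates a stated bound or allowed level set."""


class FormatError(ValueError):
    """A file does not conform to the canonical cohort CSV schema."""


def _check_domain(value: Optional[float], name: str, ctx: str) -> Optional[float]:
    if value is None:
        return None
    v = float(value)
    if math.isnan(v):
        return None
    if not (0.0 <= v <= 10.0):
        raise ValidationError(f"{ctx}: domain score {name}={v!r} outside [0, 10]")
    return v


def _check_nonneg(value: Optional[float], name: str, ctx: str) -> Optional[float]:
    if value is None:
        return None
    v = float(value)
    if math.isnan(v):
        return None
    if v < 0:
        raise ValidationError(f"{ctx}: {name}={v!r} must be nonnegative")
    return v


@dataclass(frozen=True)
class SurveyCouplet:
    """One baseline + follow-up questionnaire pair.

    ``baseline_domains`` / ``followup_domains`` are length-3 tuples of HFRS
    severity domain scores in [0, 10], with ``None`` marking a missing
    response.  ``likert_raw`` is the verbatim effectiveness level or ``None``.
    """

    couplet_id: str
    patient_id: str
    baseline_domains: tuple[Optional[float], Optional[float], Optional[float]]
    followup_domains: tuple[Optional[float], Optional[float], Optional[float]]
    likert_raw: Optional[str]
    intervention: str
    age_years: Optional[float] = None
    menopausal_status: Optional[str] = None
    et_duration_months: Optional[float] = None
    adherence_days: Optional[float] = None
    days_between: Optional[int] = None
    vms_per_week: Optional[float] = None

    def __post_init__(self) -> None:
        ctx = f"couplet {self.couplet_id!r}"
        for attr in ("baseline_domains", "followup_domains"):
            doms = getattr(self, attr)
            if len(doms) != 3:
                raise ValidationError(f"{ctx}: {attr} must have exactly 3 entries")
            cleaned = tuple(
                _check_domain(d, f"{attr}[{i}]", ctx) for i, d in enumerate(doms)
            )
            object.__setattr__(self, attr, cleaned)
        if self.likert_raw is not None and self.likert_raw not in LIKERT_LEVELS:
            raise ValidationError(f"{ctx}: unknown likert level {self.likert_raw!r}")
        if self.intervention not in INTERVENTIONS:
            raise ValidationError(
                f"{ctx}: unknown intervention {self.intervention!r} "
                f"(expected one of {INTERVENTIONS})"
            )
        if self.menopausal_status is not None and (
            self.menopausal_status not in MENOPAUSE_LEVELS
        ):
            raise ValidationError(
                f"{ctx}: unknown menopausal status {self.menopausal_status!r}"
            )
        object.__setattr__(
            self, "age_years", _check_nonneg(self.age_years, "age_years", ctx)
        )
        object.__setattr__(
            self,
            "et_duration_months",
            _check_nonneg(self.et_duration_months, "et_duration_months", ctx),
        )
        object.__setattr__(
            self,
            "adherence_days",
            _check_nonneg(self.adherence_days, "adherence_days", ctx),
        )
        object.__setattr__(
            self,
            "vms_per_week",
            _check_nonneg(self.vms_per_week, "vms_per_week", ctx),
        )
        if self.days_between is not None:
            db = self.days_between
            if isinstance(db, float) and math.isnan(db):
                object.__setattr__(self, "days_between", None)
            else:
                db = int(db)
                if db < 1:
                    raise ValidationError(f"{ctx}: days_between={db} must be >= 1")
                object.__setattr__(self, "days_between", db)


@dataclass
class CohortTable:
    """An ordered collection of :class:`SurveyCouplet` with unique ids."""

    couplets: list[SurveyCouplet] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [c.couplet_id for c in self.couplets]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate couplet_ids: {dupes}")

    def __len__(self) -> int:
        return len(self.couplets)

    def __iter__(self) -> Iterator[SurveyCouplet]:
        return iter(self.couplets)

    def __getitem__(self, i: int) -> SurveyCouplet:
        return self.couplets[i]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for c in self.couplets:
            rows.append(
                {
                    "couplet_id": c.couplet_id,
                    "patient_id": c.patient_id,
                    "b_dom1": c.baseline_domains[0],
                    "b_dom2": c.baseline_domains[1],
                    "b_dom3": c.baseline_domains[2],
                    "f_dom1": c.followup_domains[0],
                    "f_dom2": c.followup_domains[1],
                    "f_dom3": c.followup_domains[2],
                    "likert": c.likert_raw,
                    "intervention": c.intervention,
                    "age_years": c.age_years,
                    "menopause": c.menopausal_status,
                    "et_months": c.et_duration_months,
                    "adherence_days": c.adherence_days,
                    "days_between": c.days_between,
                    "vms_per_week": c.vms_per_week,
                }
            )
        return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


def _cell(value) -> Optional[float]:
    """Convert a pandas cell to float-or-None; blank cells are missing."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str):
        value = value.strip()
        if not value:
            return None
        return float(value)
    if pd.isna(value):
        return None
    return float(value)


def _str_cell(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if pd.isna(value):
        return None
    s = str(value).strip()
    return s or None


def couplet_from_mapping(row, ctx: str = "") -> SurveyCouplet:
    """Build a validated couplet from a mapping keyed by :data:`CSV_COLUMNS`."""
    days = _cell(row["days_between"])
    return SurveyCouplet(
        couplet_id=str(row["couplet_id"]),
        patient_id=str(row["patient_id"]),
        baseline_domains=(
            _cell(row["b_dom1"]),
            _cell(row["b_dom2"]),
            _cell(row["b_dom3"]),
        ),
        followup_domains=(
            _cell(row["f_dom1"]),
            _cell(row["f_dom2"]),
            _cell(row["f_dom3"]),
        ),
        likert_raw=_str_cell(row["likert"]),
        intervention=str(row["intervention"]).strip(),
        age_years=_cell(row["age_years"]),
        menopausal_status=_str_cell(row["menopause"]),
        et_duration_months=_cell(row["et_months"]),
        adherence_days=_cell(row["adherence_days"]),
        days_between=None if days is None else int(days),
        vms_per_week=_cell(row["vms_per_week"]),
    )


def read_cohort(path, delimiter: str = ",") -> CohortTable:
    """Read and validate a cohort CSV.

    Out-of-range domain scores and unknown intervention labels are rejected
    with a :class:`ValidationError` naming the offending row; they are never
    clamped or silently dropped.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: header is missing column(s) {missing}")
    couplets = []
    for i, row in df.iterrows():
        try:
            couplets.append(couplet_from_mapping(row))
        except ValidationError as err:
            raise ValidationError(f"{path} row {i + 2}: {err}") from err
    return CohortTable(couplets=couplets, provenance=str(path))


def write_cohort(table: CohortTable, path, delimiter: str = ",") -> None:
    """Write a cohort as canonical CSV; missing values become empty cells."""
    df = table.to_dataframe()
    # keep days_between integral in the text form
    df["days_between"] = df["days_between"].map(
        lambda v: "" if v is None or (isinstance(v, float) and math.isnan(v)) else str(int(v))
    )
    df.to_csv(path, sep=delimiter, index=False, na_rep="")
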