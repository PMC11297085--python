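"""End-to-end orchestration: cohort -> scores -> weights -> regression tree.

The pipeline mirrors the analysis order of the study design it implements:

1. ingest (or synthesize) a survey-couplet cohort and summarize it,
2. compute HFRS composites and raw change records,
3. fit the sigmoid baseline-weight parameters per change-direction stratum
   on the anchor-complete subset, and apply them to every complete couplet,
4. fit the regression tree of the weighted change on clinical predictors
   with ten-fold nested cross-validation,
5. serialize every artifact plus a manifest of seeds and settings.

Predictor coding for the tree: days between questionnaires dichotomized at
56 days (the six-week window plus the two-week reminder period), age in
three bands (<50, 50-59, >=60), endocrine-therapy duration dichotomized at
12 months (symptoms are typically worst in the first year on therapy),
adherence left continuous, menopausal status and intervention as given.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .bayes_opt import BayesOptConfig
from .cart import node_summary, render_tree, vif_check
from .cohort_stats import summarize
from .data_model import CohortTable, read_cohort, write_cohort
from .nested_cv import DEFAULT_HP_BOUNDS, run_nested_cv
from .scoring import change_records
from .synthetic_data import GeneratorConfig, generate
from .weighted_change import (
    DEFAULT_PARAM_BOUNDS,
    InsufficientDataError,
    fit_both_strata,
    weighted_change_score,
)

__all__ = ["RunConfig", "build_predictors", "run_pipeline"]

AGE_BINS = (50.0, 60.0)  # <50, 50-59, >=60
DAYS_CUT = 56  # 6-week follow-up window + 2-week reminder
ET_CUT_MONTHS = 12.0


@dataclass
class RunConfig:
    """Settings for one pipeline run.

    Exactly one of ``input_path`` / ``generator`` must be provided.
    """

    output_dir: Path
    input_path: Optional[Path] = None
    generator: Optional[GeneratorConfig] = None
    seed: int = 0
    param_bounds: dict = field(default_factory=lambda: dict(DEFAULT_PARAM_BOUNDS))
    hp_bounds: dict = field(default_factory=lambda: dict(DEFAULT_HP_BOUNDS))
    weight_opt: Optional[BayesOptConfig] = None
    tree_opt: Optional[BayesOptConfig] = None
    n_outer: int = 10
    n_inner: int = 5
    objective: str = "abs_max"

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.generator is None):
            raise ValueError("provide exactly one of input_path or generator config")


def _age_level(age: Optional[float]) -> Optional[str]:
    if age is None:
        return None
    if age < AGE_BINS[0]:
        return "<50"
    if age < AGE_BINS[1]:
        return "50-59"
    return ">=60"


def build_predictors(cohort: CohortTable, couplet_ids) -> pd.DataFrame:
    """Tree predictor table for the given couplets, in the documented coding."""
    by_id = {c.couplet_id: c for c in cohort}
    rows = []
    for cid in couplet_ids:
        c = by_id[cid]
        rows.append(
            {
                "days_between_level": (
                    None
                    if c.days_between is None
                    else ("<=56" if c.days_between <= DAYS_CUT else ">56")
                ),
                "intervention": c.intervention,
                "age_level": _age_level(c.age_years),
                "adherence_days": c.adherence_days,
                "menopause": c.menopausal_status,
                "et_duration_level": (
                    None
                    if c.et_duration_months is None
                    else ("<12" if c.et_duration_months < ET_CUT_MONTHS else ">=12")
                ),
            }
        )
    df = pd.DataFrame(rows, index=list(couplet_ids))
    df["adherence_days"] = df["adherence_days"].astype(float)
    return df


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Run the full analysis; returns the populated output directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- stage: cohort
    if config.generator is not None:
        cohort = generate(config.generator)
    else:
        cohort = read_cohort(config.input_path)
    write_cohort(cohort, out / "cohort.csv")

    # --- stage: scoring
    records = change_records(cohort)
    if len(records) == 0:
        raise InsufficientDataError(
            "scoring stage: no couplet has complete baseline and follow-up HFRS"
        )
    summary = summarize(cohort)
    summary.to_frame().to_csv(out / "cohort_summary.csv", index=False)
    pd.DataFrame(
        [
            {
                "couplet_id": r.couplet_id,
                "X1": r.X1,
                "X2": r.X2,
                "C": r.C,
                "stratum": r.stratum,
                "anchor": r.anchor,
            }
            for r in records
        ]
    ).to_csv(out / "change_records.csv", index=False)

    # --- stage: weight fitting (anchor-complete subset), then apply to all
    weight_opt = config.weight_opt or BayesOptConfig(seed=config.seed)
    params, reports = fit_both_strata(
        records, config.param_bounds, weight_opt, config.objective
    )
    (out / "weight_params.json").write_text(
        json.dumps(
            {s: json.loads(r.to_json()) for s, r in reports.items()}, indent=2
        )
    )
    weighted = [weighted_change_score(r, params) for r in records]
    pd.DataFrame(
        [
            {"couplet_id": wc.couplet_id, "w": wc.w, "C_prime": wc.C_prime}
            for wc in weighted
        ]
    ).to_csv(out / "weighted_change.csv", index=False)

    # --- stage: regression tree with nested CV
    X = build_predictors(cohort, [r.couplet_id for r in records])
    y = np.array([wc.C_prime for wc in weighted])
    vifs = vif_check(X[["intervention", "age_level", "adherence_days", "menopause"]])
    (out / "vif.json").write_text(json.dumps(vifs, indent=2))
    tree_opt = config.tree_opt or BayesOptConfig(seed=config.seed + 1)
    report = run_nested_cv(
        X,
        y,
        box=config.hp_bounds,
        opt=tree_opt,
        seed=config.seed,
        n_outer=config.n_outer,
        n_inner=config.n_inner,
    )
    node_summary(report.final_model, seed=config.seed)
    (out / "nested_cv_report.json").write_text(report.to_json(indent=2))
    (out / "tree.json").write_text(report.final_model.to_json(indent=2))
    (out / "tree.txt").write_text(render_tree(report.final_model) + "\n")

    # --- manifest
    artifacts = [
        "cohort.csv",
        "cohort_summary.csv",
        "change_records.csv",
        "weight_params.json",
        "weighted_change.csv",
        "vif.json",
        "nested_cv_report.json",
        "tree.json",
        "tree.txt",
    ]
    manifest = {
        "package": "vmswc",
        "version": __version__,
        "seed": config.seed,
        "weight_opt_seed": weight_opt.seed,
        "tree_opt_seed": tree_opt.seed,
        "n_couplets": len(cohort),
        "n_complete_records": len(records),
        "objective": config.objective,
        "files": {name: _sha256(out / name) for name in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
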