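"""Sigmoid baseline weights and the anchor-calibrated weighted change score.

The weighted change score replaces a fixed minimal-clinically-important-
difference threshold with a baseline-dependent rescaling of the raw change:

    w(X1) = 1 / (1 + exp(-(b0 + b1 * X1)))        (logistic weight)
    C'    = w(X1) * C                             (weighted change)

where ``X1`` is the baseline HFRS composite and ``C = X2 - X1`` the raw
change.  With ``b1 > 0`` the weight increases with baseline severity, so a
given raw change "counts" more for severely symptomatic patients.  The
parameters ``(b0, b1)`` are fitted separately for the improvement
(``C < 0``) and non-improvement (``C >= 0``) strata by maximizing the
Spearman correlation between ``C'`` and a five-level treatment-
effectiveness anchor, using bounded Bayesian optimization.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .bayes_opt import BayesOptConfig, SearchBox, maximize
from .data_model import ValidationError
from .scoring import IMPROVEMENT, NON_IMPROVEMENT, ChangeRecord

__all__ = [
    "WeightParams",
    "WeightedChange",
    "ValidityReport",
    "ConstantInputError",
    "InsufficientDataError",
    "DEFAULT_PARAM_BOUNDS",
    "sigmoid_weight",
    "weighted_change_score",
    "required_raw_change",
    "spearman",
    "fit_weight_params",
    "fit_both_strata",
]

# Default search box for (b0, b1); the fitted regime in practice has the
# intercept strongly negative and a nonnegative slope, so the weight rises
# with baseline severity.
DEFAULT_PARAM_BOUNDS = {"b0": (-10.0, 0.0), "b1": (0.0, 5.0)}


class ConstantInputError(ValueError):
    """Spearman correlation is undefined for a constant vector."""


class InsufficientDataError(ValueError):
    """Too few complete records to fit or correlate."""


@dataclass(frozen=True)
class WeightParams:
    """Logistic weight parameters for one change-direction stratum."""

    b0: float
    b1: float
    stratum: str

    def __post_init__(self) -> None:
        if not (math.isfinite(self.b0) and math.isfinite(self.b1)):
            raise ValidationError("weight parameters must be finite")
        if self.stratum not in (IMPROVEMENT, NON_IMPROVEMENT):
            raise ValidationError(f"unknown stratum {self.stratum!r}")


@dataclass(frozen=True)
class WeightedChange:
    couplet_id: str
    w: float
    C_prime: float


@dataclass(frozen=True)
class ValidityReport:
    """Anchor-validity summary for one stratum at fitted parameters."""

    stratum: str
    n: int
    rho_raw: float
    rho_weighted: float
    params: WeightParams

    def to_json(self) -> str:
        return json.dumps(
            {
                "stratum": self.stratum,
                "b0": self.params.b0,
                "b1": self.params.b1,
                "rho_raw": self.rho_raw,
                "rho_weighted": self.rho_weighted,
                "n": self.n,
            }
        )


def sigmoid_weight(X1: float, params: WeightParams) -> float:
    """Logistic weight w = 1/(1 + exp(-(b0 + b1*X1))), strictly in (0, 1)."""
    if not (0.0 <= X1 <= 10.0):
        raise ValidationError(f"X1={X1} outside the HFRS range [0, 10]")
    z = params.b0 + params.b1 * X1
    # guard exp overflow for extreme parameter draws during optimization
    if z >= 0:
        w = 1.0 / (1.0 + math.exp(-z))
    else:
        ez = math.exp(z)
        w = ez / (1.0 + ez)
    # the logistic is strictly inside (0, 1); keep the float there too
    return min(max(w, 5e-324), math.nextafter(1.0, 0.0))


def weighted_change_score(
    record: ChangeRecord, params_by_stratum: dict[str, WeightParams]
) -> WeightedChange:
    """C' = w(X1) * C using the parameters for the record's stratum."""
    if record.stratum not in params_by_stratum:
        raise KeyError(f"no weight parameters for stratum {record.stratum!r}")
    params = params_by_stratum[record.stratum]
    w = sigmoid_weight(record.X1, params)
    return WeightedChange(couplet_id=record.couplet_id, w=w, C_prime=w * record.C)


def required_raw_change(target_weighted: float, w: float) -> float:
    """Raw change needed to reach a target weighted change at weight ``w``."""
    if not (0.0 < w <= 1.0):
        raise ValidationError(f"weight w={w} must be in (0, 1]")
    return target_weighted / w


def spearman(a: Sequence[float], b: Sequence[float]) -> float:
    """Spearman rank correlation with mid-rank (average-rank) ties.

    Raises :class:`ConstantInputError` on a constant vector rather than
    silently returning 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    if a.size < 2:
        raise InsufficientDataError("need at least 2 observations")
    if np.unique(a).size < 2 or np.unique(b).size < 2:
        raise ConstantInputError("correlation undefined for a constant vector")
    rho = stats.spearmanr(a, b).statistic
    return float(rho)


def _stratum_arrays(records: Iterable[ChangeRecord]):
    recs = [r for r in records if r.anchor is not None]
    x1 = np.array([r.X1 for r in recs])
    c = np.array([r.C for r in recs])
    anchor = np.array([r.anchor for r in recs], dtype=float)
    return recs, x1, c, anchor


def fit_weight_params(
    records: Sequence[ChangeRecord],
    bounds: dict[str, tuple] | None = None,
    opt_config: BayesOptConfig | None = None,
    objective: str = "abs_max",
) -> tuple[WeightParams, ValidityReport]:
    """Fit (b0, b1) for one stratum by maximizing anchor correlation.

    ``objective`` is ``"abs_max"`` (maximize \\|rho(C', anchor)\\|, the
    default) or ``"signed_max"``.  All records must share one stratum and
    carry an anchor; at least 5 are required and the anchor must not be
    constant.
    """
    strata = {r.stratum for r in records}
    if len(strata) > 1:
        raise ValueError(f"records span multiple strata: {sorted(strata)}")
    recs, x1, c, anchor = _stratum_arrays(records)
    if len(recs) < 5:
        raise InsufficientDataError(
            f"need >= 5 anchored records in the stratum, got {len(recs)}"
        )
    if np.unique(anchor).size < 2:
        raise ConstantInputError("anchor is constant; correlation undefined")
    if objective not in ("abs_max", "signed_max"):
        raise ValueError(f"unknown objective {objective!r}")
    stratum = strata.pop()
    bounds = bounds or DEFAULT_PARAM_BOUNDS
    box = SearchBox.from_bounds(bounds)

    def score(b0: float, b1: float) -> float:
        w = 1.0 / (1.0 + np.exp(-np.clip(b0 + b1 * x1, -500, 500)))
        cp = w * c
        if np.unique(cp).size < 2:
            return -1.0  # degenerate weighting; cannot beat any real rho
        rho = stats.spearmanr(cp, anchor).statistic
        return abs(rho) if objective == "abs_max" else rho

    result = maximize(score, box, opt_config or BayesOptConfig())
    params = WeightParams(
        b0=result.best_point["b0"], b1=result.best_point["b1"], stratum=stratum
    )
    w = np.array([sigmoid_weight(x, params) for x in x1])
    rho_weighted = spearman(w * c, anchor)
    rho_raw = spearman(c, anchor)
    report = ValidityReport(
        stratum=stratum,
        n=len(recs),
        rho_raw=rho_raw,
        rho_weighted=rho_weighted,
        params=params,
    )
    return params, report


def fit_both_strata(
    records: Sequence[ChangeRecord],
    bounds: dict[str, tuple] | None = None,
    opt_config: BayesOptConfig | None = None,
    objective: str = "abs_max",
) -> tuple[dict[str, WeightParams], dict[str, ValidityReport]]:
    """Fit weight parameters for improvement and non-improvement strata."""
    params: dict[str, WeightParams] = {}
    reports: dict[str, ValidityReport] = {}
    for stratum in (IMPROVEMENT, NON_IMPROVEMENT):
        subset = [r for r in records if r.stratum == stratum and r.anchor is not None]
        p, rep = fit_weight_params(subset, bounds, opt_config, objective)
        params[stratum] = p
        reports[stratum] = rep
    return params, reports
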