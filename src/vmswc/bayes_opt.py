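"""Bounded Bayesian optimization with a GP-UCB acquisition rule.

A small, deterministic maximizer for black-box objectives over a box of
real and integer dimensions.  Each *repeat* is an independent restart:
``n_init_points`` quasi-random evaluations followed by ``n_iterations``
Gaussian-process-guided evaluations, each chosen to maximize the upper
confidence bound mean + kappa * sd.  The overall best *evaluated* point is
returned — never an un-evaluated GP argmax.

Integer dimensions are optimized on a continuous relaxation and rounded at
evaluation time.  The GP uses a Matérn 5/2 kernel on inputs normalized to
the unit box, with a small observation jitter.  Given a fixed seed the full
evaluation trace is reproducible bit for bit, and the trace for a larger
``n_iterations`` is a superset of the trace for a smaller one.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern

__all__ = [
    "BayesOptConfig",
    "Dimension",
    "SearchBox",
    "Evaluation",
    "OptResult",
    "EvaluationError",
    "maximize",
]


class EvaluationError(RuntimeError):
    """The objective returned a non-finite value; carries the point."""

    def __init__(self, point: dict, value: float):
        self.point = point
        self.value = value
        super().__init__(f"objective returned non-finite value {value!r} at {point}")


@dataclass(frozen=True)
class BayesOptConfig:
    """Budget and acquisition settings.

    Defaults: 20 initial design points per repeat, 10 independent repeats,
    25 GP-guided iterations per repeat, UCB exploration constant
    kappa = 2.576.
    """

    n_init_points: int = 20
    n_repeats: int = 10
    n_iterations: int = 25
    kappa: float = 2.576
    seed: int = 20210903
    n_candidates: int = 1000  # acquisition optimized over this many samples

    def __post_init__(self) -> None:
        if self.n_init_points < 1 or self.n_repeats < 1 or self.n_iterations < 0:
            raise ValueError("counts must be >= 1 (iterations >= 0)")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")


@dataclass(frozen=True)
class Dimension:
    name: str
    lower: float
    upper: float
    kind: str = "real"  # "real" | "integer"

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"dimension {self.name!r}: lower must be < upper")
        if self.kind not in ("real", "integer"):
            raise ValueError(f"dimension {self.name!r}: unknown kind {self.kind!r}")

    def snap(self, x: float) -> float:
        """Clip to bounds and round integer dimensions."""
        x = min(max(x, self.lower), self.upper)
        if self.kind == "integer":
            x = float(int(round(x)))
            x = min(max(x, math.ceil(self.lower)), math.floor(self.upper))
        return x


@dataclass(frozen=True)
class SearchBox:
    dims: tuple[Dimension, ...]

    def __post_init__(self) -> None:
        if not self.dims:
            raise ValueError("search box must have at least one dimension")
        names = [d.name for d in self.dims]
        if len(names) != len(set(names)):
            raise ValueError("dimension names must be unique")

    @classmethod
    def from_bounds(cls, bounds: dict[str, tuple]) -> "SearchBox":
        """Build from ``{name: (lower, upper)}`` or ``(lower, upper, kind)``."""
        dims = []
        for name, spec in bounds.items():
            if len(spec) == 3:
                lo, hi, kind = spec
            else:
                lo, hi = spec
                kind = "real"
            dims.append(Dimension(name, float(lo), float(hi), kind))
        return cls(tuple(dims))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.dims)

    def snap(self, x: np.ndarray) -> np.ndarray:
        return np.array([d.snap(v) for d, v in zip(self.dims, x)])

    def to_unit(self, x: np.ndarray) -> np.ndarray:
        lo = np.array([d.lower for d in self.dims])
        hi = np.array([d.upper for d in self.dims])
        return (x - lo) / (hi - lo)

    def as_dict(self, x: np.ndarray) -> dict[str, float]:
        return {
            d.name: (int(v) if d.kind == "integer" else float(v))
            for d, v in zip(self.dims, x)
        }


@dataclass(frozen=True)
class Evaluation:
    point: dict
    value: float
    repeat: int
    iteration: int  # < 0 for initial design points


@dataclass
class OptResult:
    best_point: dict
    best_value: float
    trace: list[Evaluation] = field(default_factory=list)

    def trace_frame(self):
        import pandas as pd

        rows = []
        for ev in self.trace:
            row = dict(ev.point)
            row["value"] = ev.value
            row["repeat"] = ev.repeat
            row["iteration"] = ev.iteration
            rows.append(row)
        return pd.DataFrame(rows)


def _make_gp(seed: int) -> GaussianProcessRegressor:
    kernel = 1.0 * Matern(length_scale=0.3, length_scale_bounds=(1e-2, 1e2), nu=2.5)
    return GaussianProcessRegressor(
        kernel=kernel,
        alpha=1e-6,
        normalize_y=True,
        n_restarts_optimizer=0,
        random_state=seed,
    )


def maximize(
    objective: Callable[..., float],
    box: SearchBox,
    config: BayesOptConfig | None = None,
) -> OptResult:
    """Maximize ``objective(**point)`` over ``box``.

    The objective must be deterministic for a given point (stochastic
    callers fix their own inner seeds).  Raises :class:`EvaluationError`
    if it returns a non-finite value.
    """
    config = config or BayesOptConfig()
    d = len(box.dims)
    lo = np.array([dim.lower for dim in box.dims])
    hi = np.array([dim.upper for dim in box.dims])
    span = hi - lo

    trace: list[Evaluation] = []
    cache: dict[tuple, float] = {}

    def evaluate(x: np.ndarray, repeat: int, iteration: int) -> float:
        x = box.snap(x)
        point = box.as_dict(x)
        key = tuple(point[n] for n in box.names)
        if key in cache:
            val = cache[key]
        else:
            val = float(objective(**point))
            if not math.isfinite(val):
                raise EvaluationError(point, val)
            cache[key] = val
        trace.append(Evaluation(point=point, value=val, repeat=repeat, iteration=iteration))
        return val

    root = np.random.SeedSequence(config.seed)
    repeat_seeds = root.spawn(config.n_repeats)

    for r in range(config.n_repeats):
        rng = np.random.default_rng(repeat_seeds[r])
        gp_seed = int(rng.integers(0, 2**31 - 1))

        X: list[np.ndarray] = []
        y: list[float] = []
        for _ in range(config.n_init_points):
            x = lo + span * rng.random(d)
            X.append(box.snap(x))
            y.append(evaluate(x, r, -1))

        for it in range(config.n_iterations):
            gp = _make_gp(gp_seed)
            Xu = np.array([box.to_unit(x) for x in X])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                gp.fit(Xu, np.array(y))
            cand = lo + span * rng.random((config.n_candidates, d))
            mu, sd = gp.predict(
                (cand - lo) / span, return_std=True
            )
            ucb = mu + config.kappa * sd
            x_next = cand[int(np.argmax(ucb))]
            X.append(box.snap(x_next))
            y.append(evaluate(x_next, r, it))

    best = max(trace, key=lambda ev: ev.value)
    return OptResult(best_point=dict(best.point), best_value=best.value, trace=trace)
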