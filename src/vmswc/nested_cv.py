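"""Nested cross-validation for regression-tree hyperparameter tuning.

Ten outer folds estimate out-of-sample mean-squared error; within each
outer training set a five-fold cross-validated MSE is minimized over the
hyperparameter box by Bayesian optimization (GP-UCB).  The winning
hyperparameters are refit on the full outer training set and scored on the
held-out fold, so the tuning never sees its own test rows.  The final
reported model is refit on all data with the modal (most frequently
chosen; ties broken toward the lowest complexity parameter) fold-level
hyperparameters.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .bayes_opt import BayesOptConfig, SearchBox, maximize
from .cart import TreeHyperparams, TreeModel, grow_tree, predict

__all__ = [
    "DEFAULT_HP_BOUNDS",
    "NestedCVReport",
    "run_nested_cv",
]

# Hyperparameter search bounds: minimum parent-node size 5-20, minimum
# terminal-node size 2-10, complexity parameter 0.001-0.1, depth 3-7.
DEFAULT_HP_BOUNDS = {
    "min_parent": (5, 20, "integer"),
    "min_terminal": (2, 10, "integer"),
    "cp": (0.001, 0.1, "real"),
    "max_depth": (3, 7, "integer"),
}


@dataclass
class NestedCVReport:
    outer_fold_mses: list[float]
    mean_mse: float
    mse_interval: tuple[float, float]
    chosen_hp_per_fold: list[TreeHyperparams]
    final_model: TreeModel
    final_hp: TreeHyperparams

    def to_dict(self) -> dict:
        return {
            "outer_fold_mses": [float(m) for m in self.outer_fold_mses],
            "mean_mse": float(self.mean_mse),
            "mse_interval": [float(self.mse_interval[0]), float(self.mse_interval[1])],
            "chosen_hp_per_fold": [
                {
                    "min_parent": h.min_parent,
                    "min_terminal": h.min_terminal,
                    "cp": h.cp,
                    "max_depth": h.max_depth,
                }
                for h in self.chosen_hp_per_fold
            ],
            "final_hp": {
                "min_parent": self.final_hp.min_parent,
                "min_terminal": self.final_hp.min_terminal,
                "cp": self.final_hp.cp,
                "max_depth": self.final_hp.max_depth,
            },
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _hp_from_point(min_parent, min_terminal, cp, max_depth) -> TreeHyperparams:
    # independent box dimensions can violate min_terminal <= min_parent;
    # clamp the terminal size rather than rejecting the point
    mp = int(min_parent)
    mt = min(int(min_terminal), mp)
    return TreeHyperparams(min_parent=mp, min_terminal=mt, cp=float(cp), max_depth=int(max_depth))


def _cv_mse(X: pd.DataFrame, y: np.ndarray, hp: TreeHyperparams, n_folds: int, seed: int) -> float:
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    errs = np.empty(y.size)
    for tr, te in kf.split(X):
        model = grow_tree(X.iloc[tr], y[tr], hp)
        errs[te] = predict(model, X.iloc[te]) - y[te]
    return float(np.mean(errs**2))


def run_nested_cv(
    X: pd.DataFrame,
    y,
    box: dict | SearchBox | None = None,
    opt: BayesOptConfig | None = None,
    seed: int = 0,
    n_outer: int = 10,
    n_inner: int = 5,
) -> NestedCVReport:
    """Run nested cross-validation and return the per-fold MSE report.

    ``box`` bounds the tree hyperparameters (defaults to
    :data:`DEFAULT_HP_BOUNDS`); ``opt`` controls the inner Bayesian
    optimization budget.  The MSE interval is mean +/- 1.96 * sd / sqrt(k)
    over the k outer folds.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 30:
        raise ValueError(f"need at least 30 rows for nested CV, got {n}")
    if n // n_outer < 2:
        raise ValueError(
            f"outer folds would hold < 2 rows; use fewer than {n_outer} folds"
        )
    if isinstance(box, SearchBox):
        search_box = box
    else:
        search_box = SearchBox.from_bounds(box or DEFAULT_HP_BOUNDS)
    opt = opt or BayesOptConfig()

    rng = np.random.default_rng(seed)
    outer_seed = int(rng.integers(0, 2**31 - 1))
    inner_seed = int(rng.integers(0, 2**31 - 1))
    outer = KFold(n_splits=n_outer, shuffle=True, random_state=outer_seed)

    fold_mses: list[float] = []
    fold_hps: list[TreeHyperparams] = []
    for k, (tr, te) in enumerate(outer.split(X)):
        X_tr, y_tr = X.iloc[tr], y[tr]

        def objective(**point) -> float:
            hp = _hp_from_point(**point)
            return -_cv_mse(X_tr, y_tr, hp, n_inner, inner_seed + k)

        fold_opt = BayesOptConfig(
            n_init_points=opt.n_init_points,
            n_repeats=opt.n_repeats,
            n_iterations=opt.n_iterations,
            kappa=opt.kappa,
            seed=(opt.seed + 7919 * k) % (2**31 - 1),
            n_candidates=opt.n_candidates,
        )
        result = maximize(objective, search_box, fold_opt)
        hp = _hp_from_point(**result.best_point)
        fold_hps.append(hp)
        model = grow_tree(X_tr, y_tr, hp)
        resid = predict(model, X.iloc[te]) - y[te]
        fold_mses.append(float(np.mean(resid**2)))

    mean_mse = float(np.mean(fold_mses))
    sd = float(np.std(fold_mses, ddof=1)) if len(fold_mses) > 1 else 0.0
    half = 1.96 * sd / math.sqrt(len(fold_mses))
    interval = (mean_mse - half, mean_mse + half)

    key = lambda h: (h.min_parent, h.min_terminal, round(h.cp, 12), h.max_depth)
    counts = Counter(key(h) for h in fold_hps)
    top = max(counts.values())
    modal = min(
        (h for h in fold_hps if counts[key(h)] == top),
        key=lambda h: (h.cp, key(h)),
    )
    final_model = grow_tree(X, y, modal)
    return NestedCVReport(
        outer_fold_mses=fold_mses,
        mean_mse=mean_mse,
        mse_interval=interval,
        chosen_hp_per_fold=fold_hps,
        final_model=final_model,
        final_hp=modal,
    )
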