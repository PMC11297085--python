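"""Regression-tree engine with surrogate splits and rpart-style pruning.

Recursive binary partitioning of a continuous response, minimizing
within-node sum of squares.  Features follow the rpart tradition used
throughout clinical prediction work:

* categorical predictors are searched over every binary partition of their
  levels (exhaustive; the arms variable here has at most 5 levels),
* continuous predictors over midpoints of sorted unique observed values,
* a split is kept only if its sum-of-squares reduction is at least
  ``cp`` times the root deviance (the complexity-parameter convention),
* rows missing the primary split variable are routed by *surrogate*
  splits — backup rules ranked by their agreement with the primary split
  among rows where both variables are observed — falling back to the
  majority direction, so no imputation is ever needed,
* terminal nodes report the median with a bootstrap percentile interval
  alongside the mean used for prediction.

Predictors are supplied as a :class:`pandas.DataFrame`; object or
categorical dtype columns are treated as categorical, numeric columns as
continuous, and NaN/None as missing.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TreeHyperparams",
    "Split",
    "Surrogate",
    "TreeNode",
    "TreeModel",
    "grow_tree",
    "predict",
    "node_summary",
    "vif_check",
    "render_tree",
]


@dataclass(frozen=True)
class TreeHyperparams:
    """Stopping and pruning controls (root depth = 1)."""

    min_parent: int = 20
    min_terminal: int = 7
    cp: float = 0.01
    max_depth: int = 30

    def __post_init__(self) -> None:
        if self.min_terminal > self.min_parent:
            raise ValueError("min_terminal must be <= min_parent")
        if self.cp <= 0:
            raise ValueError("cp must be > 0")
        if self.min_terminal < 1 or self.max_depth < 1:
            raise ValueError("counts must be >= 1")


@dataclass(frozen=True)
class Split:
    """Binary split rule: the 'yes' answer goes left.

    Continuous: left iff x <= threshold.  Categorical: left iff the level
    is in ``left_levels``.
    """

    var: str
    threshold: Optional[float] = None
    left_levels: Optional[tuple] = None

    @property
    def is_categorical(self) -> bool:
        return self.left_levels is not None

    def question(self) -> str:
        if self.is_categorical:
            return f"{self.var} in {{{', '.join(map(str, self.left_levels))}}}?"
        return f"{self.var} <= {self.threshold:g}?"


@dataclass(frozen=True)
class Surrogate:
    split: Split
    flipped: bool  # surrogate-left maps to primary-right
    agreement: float


@dataclass
class TreeNode:
    depth: int
    members: np.ndarray  # training row indices
    mean: float
    median: float
    interval: tuple[float, float] | None = None
    split: Split | None = None
    surrogates: list[Surrogate] = field(default_factory=list)
    majority_left: bool = True
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def n(self) -> int:
        return len(self.members)

    @property
    def is_leaf(self) -> bool:
        return self.split is None

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()


@dataclass
class TreeModel:
    root: TreeNode
    hyperparams: TreeHyperparams
    columns: tuple[str, ...]
    categorical: dict[str, tuple]
    y_train: np.ndarray

    @property
    def n_leaves(self) -> int:
        return len(self.root.leaves())

    def validate(self) -> None:
        """Walk the tree checking structural invariants; raises on breach."""
        hp = self.hyperparams

        def walk(node: TreeNode) -> None:
            if node.depth > hp.max_depth:
                raise AssertionError("node deeper than max_depth")
            if node.is_leaf:
                if node.n < hp.min_terminal and node.depth > 1:
                    raise AssertionError("leaf smaller than min_terminal")
            else:
                if node.n < hp.min_parent:
                    raise AssertionError("internal node smaller than min_parent")
                if node.left.n + node.right.n != node.n:
                    raise AssertionError("child sizes do not sum to parent")
                walk(node.left)
                walk(node.right)

        walk(self.root)

    def to_dict(self) -> dict:
        def node_dict(node: TreeNode) -> dict:
            d = {
                "n": int(node.n),
                "mean": float(node.mean),
                "median": float(node.median),
            }
            if node.interval is not None:
                d["interval"] = [float(node.interval[0]), float(node.interval[1])]
            if not node.is_leaf:
                d["split"] = {
                    "var": node.split.var,
                    "threshold": node.split.threshold,
                    "left_levels": (
                        list(node.split.left_levels)
                        if node.split.left_levels is not None
                        else None
                    ),
                }
                d["surrogates"] = [
                    {
                        "var": s.split.var,
                        "threshold": s.split.threshold,
                        "left_levels": (
                            list(s.split.left_levels)
                            if s.split.left_levels is not None
                            else None
                        ),
                        "flipped": s.flipped,
                        "agreement": s.agreement,
                    }
                    for s in node.surrogates
                ]
                d["left"] = node_dict(node.left)
                d["right"] = node_dict(node.right)
            return d

        return {
            "hyperparams": {
                "min_parent": self.hyperparams.min_parent,
                "min_terminal": self.hyperparams.min_terminal,
                "cp": self.hyperparams.cp,
                "max_depth": self.hyperparams.max_depth,
            },
            "root": node_dict(self.root),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


# ---------------------------------------------------------------------------
# column encoding


def _encode(X: pd.DataFrame):
    """Encode columns to float arrays with NaN for missing.

    Categorical columns become level codes; the level order is sorted, so
    ties and partition enumeration are deterministic.
    """
    cols = {}
    categorical = {}
    for name in X.columns:
        col = X[name]
        if col.dtype.kind in "fiub":
            vals = col.to_numpy(dtype=float, na_value=np.nan)
        else:
            levels = tuple(sorted({v for v in col.dropna().unique()}, key=str))
            categorical[name] = levels
            code = {lv: float(i) for i, lv in enumerate(levels)}
            vals = np.array(
                [np.nan if pd.isna(v) else code[v] for v in col], dtype=float
            )
        cols[name] = vals
    return cols, categorical


def _candidate_splits(name, vals, categorical):
    """All candidate splits of one variable restricted to observed values.

    Categorical partitions are canonicalized so the left side contains the
    lowest-coded observed level; each unordered partition appears once.
    """
    obs = vals[~np.isnan(vals)]
    if obs.size == 0:
        return
    if name in categorical:
        levels = categorical[name]
        present = sorted({int(v) for v in obs})
        if len(present) < 2:
            return
        first, rest = present[0], present[1:]
        # nonempty proper subsets of `rest` joined with `first` on the left
        for r in range(len(rest)):
            for combo in itertools.combinations(rest, r):
                left_codes = (first,) + combo
                yield Split(
                    var=name,
                    left_levels=tuple(levels[c] for c in left_codes),
                ), frozenset(left_codes)
    else:
        uniq = np.unique(obs)
        if uniq.size < 2:
            return
        for i in range(uniq.size - 1):
            thr = 0.5 * (uniq[i] + uniq[i + 1])
            yield Split(var=name, threshold=float(thr)), None


def _goes_left(split: Split, vals: np.ndarray, categorical, left_codes=None):
    """Boolean mask (NaN rows -> False, tracked separately by caller)."""
    if split.is_categorical:
        if left_codes is None:
            levels = categorical[split.var]
            left_codes = frozenset(levels.index(lv) for lv in split.left_levels)
        with np.errstate(invalid="ignore"):
            return np.isin(vals, list(left_codes))
    with np.errstate(invalid="ignore"):
        return vals <= split.threshold


def _best_split(cols, categorical, members, y, hp):
    """Exhaustive search for the SSE-optimal split at a node.

    Improvement is computed over the rows where the split variable is
    observed.  Ties break on lowest column index, then lowest threshold /
    lexicographically smallest left-level tuple (enumeration order).
    """
    best = None
    best_gain = 0.0
    for name in cols:
        vals = cols[name][members]
        obs_mask = ~np.isnan(vals)
        if obs_mask.sum() < 2:
            continue
        yv = y[members][obs_mask]
        vv = vals[obs_mask]
        ss_parent = float(np.sum((yv - yv.mean()) ** 2))
        for split, left_codes in _candidate_splits(name, vv, categorical):
            left = _goes_left(split, vv, categorical, left_codes)
            nl = int(left.sum())
            nr = int(left.size - nl)
            if nl == 0 or nr == 0:
                continue
            yl, yr = yv[left], yv[~left]
            ss_children = float(
                np.sum((yl - yl.mean()) ** 2) + np.sum((yr - yr.mean()) ** 2)
            )
            gain = ss_parent - ss_children
            if gain > best_gain + 1e-12:
                best = split
                best_gain = gain
    return best, best_gain


def _find_surrogates(cols, categorical, members, primary: Split, primary_left):
    """Rank backup rules by direction agreement with the primary split.

    A candidate is retained only if it beats the majority rule on the rows
    where both it and the primary variable are observed.
    """
    pvals = cols[primary.var][members]
    pobs = ~np.isnan(pvals)
    surrogates: list[Surrogate] = []
    for name in cols:
        if name == primary.var:
            continue
        vals = cols[name][members]
        both = pobs & ~np.isnan(vals)
        if both.sum() < 2:
            continue
        p_left = primary_left[both]
        majority = max(p_left.mean(), 1.0 - p_left.mean())
        vv = vals[both]
        best_agree = majority
        best_rule = None
        for split, left_codes in _candidate_splits(name, vv, categorical):
            s_left = _goes_left(split, vv, categorical, left_codes)
            agree = float((s_left == p_left).mean())
            flip = False
            if 1.0 - agree > agree:
                agree, flip = 1.0 - agree, True
            if agree > best_agree + 1e-12:
                best_agree = agree
                best_rule = Surrogate(split=split, flipped=flip, agreement=agree)
        if best_rule is not None:
            surrogates.append(best_rule)
    surrogates.sort(key=lambda s: (-s.agreement, s.split.var))
    return surrogates


def _route_left(cols, categorical, idx, node: TreeNode) -> np.ndarray:
    """Left-going mask for training rows ``idx``: primary, surrogates, majority."""
    primary = node.split
    vals = cols[primary.var][idx]
    left = _goes_left(primary, vals, categorical)
    undecided = np.isnan(vals)
    for s in node.surrogates:
        if not undecided.any():
            break
        svals = cols[s.split.var][idx]
        can = undecided & ~np.isnan(svals)
        if not can.any():
            continue
        s_left = _goes_left(s.split, svals, categorical)
        if s.flipped:
            s_left = ~s_left
        left[can] = s_left[can]
        undecided &= ~can
    left[undecided] = node.majority_left
    return left


def grow_tree(X: pd.DataFrame, y, hp: TreeHyperparams | None = None) -> TreeModel:
    """Fit a regression tree of ``y`` on the predictors in ``X``.

    Degenerate inputs (constant response, fewer than ``min_parent`` rows)
    yield a single-node tree rather than an error.
    """
    hp = hp or TreeHyperparams()
    y = np.asarray(y, dtype=float)
    if len(X) != y.size:
        raise ValueError("X and y lengths differ")
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    cols, categorical = _encode(X)
    root_dev = float(np.sum((y - y.mean()) ** 2)) if y.size else 0.0
    min_gain = hp.cp * root_dev

    def build(members: np.ndarray, depth: int) -> TreeNode:
        yv = y[members]
        node = TreeNode(
            depth=depth,
            members=members,
            mean=float(yv.mean()),
            median=float(np.median(yv)),
        )
        if (
            depth >= hp.max_depth
            or members.size < hp.min_parent
            or np.unique(yv).size < 2
            or root_dev <= 0
        ):
            return node
        split, gain = _best_split(cols, categorical, members, y, hp)
        if split is None or gain < min_gain - 1e-12:
            return node
        vals = cols[split.var][members]
        primary_left = _goes_left(split, vals, categorical)
        obs = ~np.isnan(vals)
        node.split = split
        node.majority_left = bool(primary_left[obs].mean() >= 0.5)
        node.surrogates = _find_surrogates(
            cols, categorical, members, split, primary_left
        )
        left_mask = _route_left(cols, categorical, members, node)
        left_idx = members[left_mask]
        right_idx = members[~left_mask]
        if left_idx.size < hp.min_terminal or right_idx.size < hp.min_terminal:
            node.split = None
            node.surrogates = []
            return node
        node.left = build(left_idx, depth + 1)
        node.right = build(right_idx, depth + 1)
        return node

    root = build(np.arange(y.size), 1)
    return TreeModel(
        root=root,
        hyperparams=hp,
        columns=tuple(X.columns),
        categorical=categorical,
        y_train=y,
    )


def _route_row(model: TreeModel, node: TreeNode, row: dict) -> TreeNode:
    while not node.is_leaf:
        decided = None
        rules = [(node.split, False)] + [(s.split, s.flipped) for s in node.surrogates]
        for split, flipped in rules:
            v = row.get(split.var)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                continue
            if split.is_categorical:
                go_left = v in split.left_levels
            else:
                go_left = float(v) <= split.threshold
            decided = go_left != flipped
            break
        if decided is None:
            decided = node.majority_left
        node = node.left if decided else node.right
    return node


def predict(model: TreeModel, rows: pd.DataFrame | dict) -> np.ndarray | float:
    """Leaf-mean prediction; missing values route via surrogates then majority."""
    if isinstance(rows, dict):
        return _route_row(model, model.root, rows).mean
    out = np.empty(len(rows))
    for i, (_, row) in enumerate(rows.iterrows()):
        out[i] = _route_row(model, model.root, row.to_dict()).mean
    return out


def node_summary(
    model: TreeModel, n_boot: int = 2000, seed: int = 0, level: float = 0.95
) -> list[dict]:
    """Per-leaf median with a bootstrap percentile interval of the median.

    A leaf with a single member gets the degenerate interval
    ``[median, median]``.  Intervals are also written back onto the tree
    nodes so serialized trees carry them.
    """
    rng = np.random.default_rng(seed)
    alpha = (1.0 - level) / 2.0
    out = []
    for leaf in model.root.leaves():
        yv = model.y_train[leaf.members]
        med = float(np.median(yv))
        if yv.size < 2:
            lo = hi = med
        else:
            boots = np.median(
                rng.choice(yv, size=(n_boot, yv.size), replace=True), axis=1
            )
            lo = float(np.quantile(boots, alpha))
            hi = float(np.quantile(boots, 1.0 - alpha))
        leaf.interval = (lo, hi)
        out.append(
            {
                "n": int(yv.size),
                "median": med,
                "interval_low": lo,
                "interval_high": hi,
            }
        )
    return out


def vif_check(X: pd.DataFrame) -> dict[str, float]:
    """Variance inflation factors on dummy-encoded complete cases.

    VIF_j = 1/(1 - R^2_j) from regressing each encoded column on all the
    others plus an intercept.  Perfect collinearity reports ``inf``.  An
    advisory threshold of 5 is conventional; values are reported, not
    enforced.
    """
    if X.shape[1] < 2:
        raise ValueError("need at least 2 variables for VIF")
    cc = X.dropna()
    parts = []
    names = []
    for name in cc.columns:
        col = cc[name]
        if col.dtype.kind in "fiub":
            parts.append(col.to_numpy(dtype=float))
            names.append(name)
        else:
            levels = sorted(col.unique(), key=str)
            for lv in levels[1:]:  # first level is the reference
                parts.append((col == lv).to_numpy(dtype=float))
                names.append(f"{name}[{lv}]")
    M = np.column_stack(parts)
    if M.shape[0] < M.shape[1] + 2:
        raise ValueError("too few complete cases for VIF")
    vifs: dict[str, float] = {}
    n = M.shape[0]
    ones = np.ones((n, 1))
    for j, name in enumerate(names):
        yj = M[:, j]
        Xj = np.hstack([ones, np.delete(M, j, axis=1)])
        beta, *_ = np.linalg.lstsq(Xj, yj, rcond=None)
        resid = yj - Xj @ beta
        ss_tot = float(np.sum((yj - yj.mean()) ** 2))
        if ss_tot <= 0:
            vifs[name] = float("inf")
            continue
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
        vifs[name] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return vifs


def render_tree(model: TreeModel) -> str:
    """Indented text diagram; the 'yes' branch is printed first (left)."""
    lines: list[str] = []

    def walk(node: TreeNode, indent: int, label: str) -> None:
        pad = "  " * indent
        if node.is_leaf:
            iv = node.interval
            ivtxt = f" [{iv[0]:.2f}, {iv[1]:.2f}]" if iv else ""
            lines.append(
                f"{pad}{label}n={node.n} median={node.median:.2f}{ivtxt}"
            )
        else:
            lines.append(f"{pad}{label}{node.split.question()} (n={node.n})")
            walk(node.left, indent + 1, "yes: ")
            walk(node.right, indent + 1, "no:  ")

    walk(model.root, 0, "")
    return "\n".join(lines)
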