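import itertools
import json
import math

import numpy as np
import pandas as pd
import pytest

from vmswc.cart import (
    Split,
    TreeHyperparams,
    grow_tree,
    node_summary,
    predict,
    render_tree,
    vif_check,
)


def brute_force_root_split(X: pd.DataFrame, y):
    """Exhaustive SSE-optimal split search, independent of the engine.

    Follows the documented tie rule: first variable in column order, then
    ascending threshold / enumeration order of level partitions; a
    candidate replaces the incumbent only on a strictly larger gain.
    """
    y = np.asarray(y, float)
    best, best_gain = None, 0.0

    def sse(v):
        m = sum(v) / len(v)
        return sum((x - m) ** 2 for x in v)

    for col in X.columns:
        vals = X[col]
        obs = [(v, yy) for v, yy in zip(vals, y) if not pd.isna(v)]
        if len(obs) < 2:
            continue
        parent = sse([yy for _, yy in obs])
        if vals.dtype.kind in "fiub":
            uniq = sorted({v for v, _ in obs})
            cands = [
                ("num", 0.5 * (a + b)) for a, b in zip(uniq, uniq[1:])
            ]
        else:
            levels = sorted({v for v, _ in obs}, key=str)
            cands = []
            first, rest = levels[0], levels[1:]
            for r in range(len(rest)):
                for combo in itertools.combinations(rest, r):
                    cands.append(("cat", (first,) + combo))
        for kind, rule in cands:
            if kind == "num":
                left = [yy for v, yy in obs if v <= rule]
                right = [yy for v, yy in obs if v > rule]
            else:
                left = [yy for v, yy in obs if v in rule]
                right = [yy for v, yy in obs if v not in rule]
            if not left or not right:
                continue
            gain = parent - sse(left) - sse(right)
            if gain > best_gain + 1e-12:
                best_gain = gain
                best = (col, kind, rule)
    return best, best_gain


def random_instance(rng):
    n = int(rng.integers(6, 11))
    cols = {}
    n_pred = int(rng.integers(1, 4))
    for j in range(n_pred):
        if rng.random() < 0.5:
            v = rng.normal(size=n)
        else:
            k = int(rng.integers(2, 5))
            v = rng.choice([f"L{i}" for i in range(k)], size=n)
        cols[f"v{j}"] = v
    X = pd.DataFrame(cols)
    # sprinkle missing values
    for j in range(n_pred):
        mask = rng.random(n) < 0.15
        if mask.sum() < n - 1:
            X.loc[mask, f"v{j}"] = np.nan
    y = rng.normal(size=n)
    return X, y


PERM_HP = TreeHyperparams(min_parent=2, min_terminal=1, cp=1e-9, max_depth=2)


class TestGrowTree:
    def test_perfect_binary_split(self):
        X = pd.DataFrame({"g": ["a"] * 3 + ["b"] * 3})
        y = [0, 0, 0, 10, 10, 10]
        m = grow_tree(X, y, TreeHyperparams(5, 2, 0.01, 3))
        m.validate()
        assert m.n_leaves == 2
        assert sorted(l.mean for l in m.root.leaves()) == [0.0, 10.0]

    def test_constant_response_single_node(self):
        X = pd.DataFrame({"g": list("ababab")})
        m = grow_tree(X, [2.0] * 6, TreeHyperparams(2, 1, 0.01, 5))
        assert m.n_leaves == 1
        assert predict(m, {"g": "a"}) == 2.0

    def test_too_few_rows_single_node(self):
        X = pd.DataFrame({"g": list("ab")})
        m = grow_tree(X, [0.0, 10.0], TreeHyperparams(5, 2, 0.01, 3))
        assert m.n_leaves == 1

    def test_root_split_matches_exhaustive_oracle(self):
        """On 100 random small instances, the engine's root split is the
        brute-force SSE-optimal split under the documented tie rule."""
        rng = np.random.default_rng(2024)
        checked = 0
        for _ in range(100):
            X, y = random_instance(rng)
            oracle, gain = brute_force_root_split(X, y)
            m = grow_tree(X, y, PERM_HP)
            if oracle is None:
                continue
            assert not m.root.is_leaf, (X, y)
            s = m.root.split
            col, kind, rule = oracle
            assert s.var == col
            if kind == "num":
                assert s.threshold == pytest.approx(rule)
            else:
                assert tuple(s.left_levels) == rule
            checked += 1
        assert checked >= 80

    def test_structural_invariants_on_random_fits(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = 80
            X = pd.DataFrame(
                {
                    "c": rng.normal(size=n),
                    "g": rng.choice(list("abcd"), size=n),
                }
            )
            y = rng.normal(size=n) + 2.0 * (X["g"] == "a")
            m = grow_tree(X, y, TreeHyperparams(10, 4, 0.005, 5))
            m.validate()

    def test_pruning_monotone_in_cp(self):
        rng = np.random.default_rng(5)
        n = 120
        X = pd.DataFrame(
            {"x": rng.normal(size=n), "g": rng.choice(list("abc"), size=n)}
        )
        y = rng.normal(size=n) + (X["x"] > 0) * 1.5 + (X["g"] == "b") * 1.0
        leaves = [
            grow_tree(X, y, TreeHyperparams(10, 4, cp, 6)).n_leaves
            for cp in (0.001, 0.01, 0.05, 0.1)
        ]
        assert leaves == sorted(leaves, reverse=True)

    def test_json_round_trip_serializable(self):
        X = pd.DataFrame({"g": list("aaabbb")})
        m = grow_tree(X, [0, 0, 0, 9, 9, 9.0], TreeHyperparams(4, 2, 0.01, 3))
        node_summary(m, seed=0)
        d = json.loads(m.to_json())
        assert d["root"]["split"]["var"] == "g"
        assert "interval" in d["root"]["left"]


class TestSurrogates:
    def _tree_with_surrogate(self):
        # primary variable x perfectly mirrored by surrogate s
        rng = np.random.default_rng(1)
        n = 40
        x = rng.normal(size=n)
        s = np.where(x <= 0, "lo", "hi")
        y = np.where(x <= 0, 0.0, 5.0) + rng.normal(0, 0.1, n)
        X = pd.DataFrame({"x": x, "s": s})
        return grow_tree(X, y, TreeHyperparams(5, 2, 0.01, 2))

    def test_missing_primary_routed_by_perfect_surrogate(self):
        m = self._tree_with_surrogate()
        assert not m.root.is_leaf and m.root.split.var == "x"
        assert m.root.surrogates and m.root.surrogates[0].agreement == 1.0
        via_primary = predict(m, {"x": -1.0, "s": "lo"})
        via_surrogate = predict(m, {"x": None, "s": "lo"})
        assert via_primary == via_surrogate
        assert predict(m, {"x": None, "s": "hi"}) == predict(m, {"x": 1.0, "s": "hi"})

    def test_no_missing_predictions_unchanged_without_surrogates(self):
        m = self._tree_with_surrogate()
        X = pd.DataFrame({"x": [-2.0, -0.5, 0.5, 2.0], "s": ["lo", "lo", "hi", "hi"]})
        with_surr = predict(m, X)
        for node in [m.root]:
            node.surrogates = []
        without = predict(m, X)
        assert np.array_equal(with_surr, without)

    def test_training_rows_predict_their_leaf_mean(self):
        m = self._tree_with_surrogate()
        for leaf in m.root.leaves():
            yv = m.y_train[leaf.members]
            assert leaf.mean == pytest.approx(yv.mean())


class TestNodeSummary:
    def test_leaf_median(self):
        X = pd.DataFrame({"g": list("aaa")})
        m = grow_tree(X, [1.0, 2.0, 3.0], TreeHyperparams(5, 2, 0.01, 3))
        (leaf,) = node_summary(m, seed=0)
        assert leaf["median"] == 2.0

    def test_equal_members_zero_width_interval(self):
        X = pd.DataFrame({"g": list("aaaa")})
        m = grow_tree(X, [3.0] * 4, TreeHyperparams(5, 2, 0.01, 3))
        (leaf,) = node_summary(m, seed=1)
        assert leaf["interval_low"] == leaf["interval_high"] == 3.0

    def test_bootstrap_interval_covers_sample_median(self):
        """The percentile interval contains the observed median in >= 99%
        of seeded runs on a 20-member leaf."""
        rng = np.random.default_rng(0)
        y = rng.normal(size=20)
        X = pd.DataFrame({"g": ["a"] * 20})
        m = grow_tree(X, y, TreeHyperparams(25, 10, 0.01, 3))
        med = float(np.median(y))
        hits = 0
        for seed in range(100):
            (leaf,) = node_summary(m, seed=seed)
            if leaf["interval_low"] <= med <= leaf["interval_high"]:
                hits += 1
        assert hits >= 99


class TestVif:
    def test_orthogonal_predictors_near_one(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"a": rng.normal(size=200), "b": rng.normal(size=200)})
        vifs = vif_check(X)
        assert all(v == pytest.approx(1.0, abs=0.1) for v in vifs.values())

    def test_duplicated_predictor_infinite(self):
        x = np.arange(10.0)
        vifs = vif_check(pd.DataFrame({"a": x, "b": x, "c": np.random.default_rng(1).normal(size=10)}))
        assert math.isinf(vifs["a"]) and math.isinf(vifs["b"])

    def test_matches_independent_r2_oracle(self):
        rng = np.random.default_rng(8)
        n = 150
        a = rng.normal(size=n)
        b = 0.7 * a + rng.normal(size=n)
        c = rng.normal(size=n)
        X = pd.DataFrame({"a": a, "b": b, "c": c})
        vifs = vif_check(X)
        # independent oracle via correlation algebra on each column
        M = X.to_numpy()
        for j, name in enumerate(X.columns):
            others = np.column_stack(
                [np.ones(n)] + [M[:, k] for k in range(3) if k != j]
            )
            coef, *_ = np.linalg.lstsq(others, M[:, j], rcond=None)
            pred = others @ coef
            r2 = 1 - ((M[:, j] - pred) ** 2).sum() / (
                (M[:, j] - M[:, j].mean()) ** 2
            ).sum()
            assert vifs[name] == pytest.approx(1 / (1 - r2))

    def test_single_variable_rejected(self):
        with pytest.raises(ValueError):
            vif_check(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))


def test_render_tree_lists_yes_branch_first():
    X = pd.DataFrame({"g": list("aaabbb")})
    m = grow_tree(X, [0, 0, 0, 9, 9, 9.0], TreeHyperparams(4, 2, 0.01, 3))
    node_summary(m, seed=0)
    text = render_tree(m)
    lines = text.splitlines()
    assert "?" in lines[0]
    assert lines[1].strip().startswith("yes:")
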