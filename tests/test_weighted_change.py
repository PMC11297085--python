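import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vmswc.bayes_opt import BayesOptConfig
from vmswc.data_model import ValidationError
from vmswc.scoring import IMPROVEMENT, NON_IMPROVEMENT, ChangeRecord, change_records
from vmswc.synthetic_data import GeneratorConfig, generate
from vmswc.weighted_change import (
    ConstantInputError,
    InsufficientDataError,
    WeightParams,
    fit_weight_params,
    required_raw_change,
    sigmoid_weight,
    spearman,
    weighted_change_score,
)


def brute_force_spearman(a, b):
    """Independent mid-rank oracle: Pearson correlation of average ranks."""

    def midranks(v):
        v = list(v)
        ranks = []
        for x in v:
            below = sum(1 for y in v if y < x)
            equal = sum(1 for y in v if y == x)
            ranks.append(below + (equal + 1) / 2.0)
        return ranks

    ra, rb = midranks(a), midranks(b)
    ma, mb = sum(ra) / len(ra), sum(rb) / len(rb)
    num = sum((x - ma) * (y - mb) for x, y in zip(ra, rb))
    den = math.sqrt(
        sum((x - ma) ** 2 for x in ra) * sum((y - mb) ** 2 for y in rb)
    )
    return num / den


def rec(cid, x1, x2, anchor=None):
    c = x2 - x1
    return ChangeRecord(
        couplet_id=cid,
        X1=x1,
        X2=x2,
        C=c,
        stratum=IMPROVEMENT if c < 0 else NON_IMPROVEMENT,
        anchor=anchor,
    )


finite_b = st.floats(min_value=-20, max_value=20, allow_nan=False)


class TestSigmoidWeight:
    def test_midpoint_is_half(self):
        p = WeightParams(b0=-6.0, b1=2.0, stratum=IMPROVEMENT)
        assert sigmoid_weight(3.0, p) == pytest.approx(0.5)

    def test_zero_params_identity_case(self):
        p = WeightParams(b0=0.0, b1=1.0, stratum=IMPROVEMENT)
        assert sigmoid_weight(0.0, p) == pytest.approx(0.5)

    def test_high_baseline_weight_rounds_to_one(self):
        p = WeightParams(b0=-10.0, b1=2.68, stratum=IMPROVEMENT)
        assert round(sigmoid_weight(6.0, p)) == 1

    def test_nonfinite_params_rejected(self):
        with pytest.raises(ValidationError):
            WeightParams(b0=float("nan"), b1=1.0, stratum=IMPROVEMENT)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(b0=finite_b, b1=finite_b, x=st.floats(0, 10, allow_nan=False))
    def test_weight_strictly_in_unit_interval(self, b0, b1, x):
        p = WeightParams(b0=b0, b1=b1, stratum=IMPROVEMENT)
        assert 0.0 < sigmoid_weight(x, p) < 1.0

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        b0=finite_b,
        b1=st.floats(min_value=0.01, max_value=5, allow_nan=False),
        x1=st.floats(0, 10, allow_nan=False),
        x2=st.floats(0, 10, allow_nan=False),
    )
    def test_monotone_increasing_when_slope_positive(self, b0, b1, x1, x2):
        p = WeightParams(b0=b0, b1=b1, stratum=IMPROVEMENT)
        lo, hi = sorted((x1, x2))
        assert sigmoid_weight(lo, p) <= sigmoid_weight(hi, p)

    def test_constant_when_slope_zero(self):
        p = WeightParams(b0=-1.0, b1=0.0, stratum=IMPROVEMENT)
        ws = {sigmoid_weight(x, p) for x in np.linspace(0, 10, 11)}
        assert len(ws) == 1


class TestWeightedChangeScore:
    PARAMS = {
        IMPROVEMENT: WeightParams(-10.0, 2.68, IMPROVEMENT),
        NON_IMPROVEMENT: WeightParams(-9.45, 1.27, NON_IMPROVEMENT),
    }

    def test_three_point_improvement_at_high_baseline(self):
        wc = weighted_change_score(rec("a", 6.0, 3.0, anchor=5), self.PARAMS)
        assert round(abs(wc.C_prime)) == 3

    def test_zero_change_stays_zero(self):
        wc = weighted_change_score(rec("a", 6.0, 6.0), self.PARAMS)
        assert wc.C_prime == 0.0

    def test_missing_stratum_params_is_config_error(self):
        with pytest.raises(KeyError):
            weighted_change_score(rec("a", 6.0, 3.0), {})

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        x1=st.floats(0, 10, allow_nan=False),
        x2=st.floats(0, 10, allow_nan=False),
    )
    def test_sign_preserved_and_magnitude_shrunk(self, x1, x2):
        wc = weighted_change_score(rec("a", x1, x2), self.PARAMS)
        c = x2 - x1
        assert wc.C_prime == pytest.approx(wc.w * c)
        assert math.copysign(1, wc.C_prime) == math.copysign(1, c) or c == 0
        assert abs(wc.C_prime) <= abs(c)


class TestRequiredRawChange:
    def test_two_point_target_at_weight_point_six(self):
        assert required_raw_change(2.0, 0.6) == pytest.approx(10 / 3)
        assert round(required_raw_change(2.0, 0.6), 1) == 3.3

    def test_weight_point_six_gives_1_2_for_two_points(self):
        # stated arithmetic of the worked example: C' = w * C at w = 0.6
        assert 0.6 * 2.0 == pytest.approx(1.2)

    @pytest.mark.parametrize("target, w, expected", [(0, 0.4, 0), (1, 1.0, 1)])
    def test_edge_values(self, target, w, expected):
        assert required_raw_change(target, w) == pytest.approx(expected)

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValidationError):
            required_raw_change(1.0, 0.0)


class TestSpearman:
    @pytest.mark.parametrize(
        "a, b, expected",
        [((1, 2, 3), (10, 20, 30), 1.0), ((1, 2, 3), (3, 2, 1), -1.0)],
    )
    def test_perfect_monotone(self, a, b, expected):
        assert spearman(a, b) == pytest.approx(expected)

    def test_constant_vector_raises(self):
        with pytest.raises(ConstantInputError):
            spearman((1, 1, 1), (1, 2, 3))

    def test_tied_example_matches_brute_force(self):
        a, b = (1, 2, 2, 4), (2, 1, 3, 4)
        assert spearman(a, b) == pytest.approx(brute_force_spearman(a, b))

    def test_matches_brute_force_oracle_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(3, 12))
            a = rng.integers(0, 5, n).astype(float)
            b = rng.integers(0, 5, n).astype(float)
            if len(set(a)) < 2 or len(set(b)) < 2:
                continue
            assert spearman(a, b) == pytest.approx(
                brute_force_spearman(a, b), abs=1e-12
            )


def improvement_stratum(n=300, seed=0, anchored=True):
    cohort = generate(GeneratorConfig(n_couplets=n, seed=seed))
    recs = [
        r
        for r in change_records(cohort)
        if r.stratum == IMPROVEMENT and (r.anchor is not None or not anchored)
    ]
    return recs


class TestFitWeightParams:
    def test_too_few_records_is_insufficient_data(self):
        recs = [rec(f"r{i}", 5.0, 3.0, anchor=i % 5 + 1) for i in range(3)]
        with pytest.raises(InsufficientDataError):
            fit_weight_params(recs)

    def test_constant_anchor_raises(self):
        recs = [rec(f"r{i}", 5.0 + 0.1 * i, 3.0, anchor=4) for i in range(6)]
        with pytest.raises(ConstantInputError):
            fit_weight_params(recs)

    def test_rank_preservation_at_zero_slope(self):
        """b1 = 0 makes C' a positive multiple of C: identical Spearman."""
        recs = improvement_stratum(n=200, seed=3)
        c = np.array([r.C for r in recs])
        anchor = np.array([r.anchor for r in recs], dtype=float)
        p = WeightParams(-2.0, 0.0, IMPROVEMENT)
        cp = np.array([sigmoid_weight(r.X1, p) * r.C for r in recs])
        assert spearman(cp, anchor) == pytest.approx(spearman(c, anchor), abs=1e-12)

    def test_fitted_objective_beats_true_params(self, small_opt):
        """Objective at the fitted optimum >= objective at the generating
        parameters minus optimizer tolerance."""
        recs = improvement_stratum(n=600, seed=5)
        params, report = fit_weight_params(recs, opt_config=small_opt)
        anchor = np.array([r.anchor for r in recs], dtype=float)
        true_p = WeightParams(-10.0, 2.68, IMPROVEMENT)
        cp_true = np.array([sigmoid_weight(r.X1, true_p) * r.C for r in recs])
        obj_true = abs(spearman(cp_true, anchor))
        assert abs(report.rho_weighted) >= obj_true - 0.02

    def test_independent_noise_anchor(self, small_opt):
        """With an anchor unrelated to change, the weighted correlation is
        weak but the optimum still dominates the b1=0 (raw) baseline."""
        rng = np.random.default_rng(9)
        recs = [r for r in improvement_stratum(n=300, seed=6, anchored=False)]
        recs = [
            ChangeRecord(r.couplet_id, r.X1, r.X2, r.C, r.stratum,
                         int(rng.integers(1, 6)))
            for r in recs
        ]
        params, report = fit_weight_params(recs, opt_config=small_opt)
        c = np.array([r.C for r in recs])
        anchor = np.array([r.anchor for r in recs], dtype=float)
        raw_obj = abs(spearman(c, anchor))
        assert abs(report.rho_weighted) >= raw_obj - 0.02
        assert abs(report.rho_weighted) < 0.35
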