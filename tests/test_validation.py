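import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import evtbenefit as eb
from evtbenefit.validation import (
    BootstrapFailure,
    UndefinedMetricError,
    bootstrap_order_indices,
)

from conftest import concordance_oracle


class TestConcordance:
    def test_all_tied_predictions_give_half(self):
        assert eb.c_binary([0.3] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_four_patient_example_by_enumeration(self):
        # pairs (event, non-event): (0.6,0.2)+, (0.6,0.4)+, (0.3,0.2)+, (0.3,0.4)-
        assert eb.c_binary([0.2, 0.6, 0.4, 0.3], [0, 1, 0, 1]) == 0.75

    def test_perfect_separation_gives_one(self):
        assert eb.c_binary([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_ordinal_perfectly_ordered(self):
        assert eb.c_ordinal([2.0, 1.0, -1.0], [0, 2, 6]) == 1.0

    def test_ordinal_all_score_ties(self):
        assert eb.c_ordinal([1.0, 1.0, 1.0], [0, 3, 6]) == 0.5

    def test_single_class_outcomes_undefined(self):
        with pytest.raises(UndefinedMetricError):
            eb.c_binary([0.2, 0.8], [1, 1])
        with pytest.raises(UndefinedMetricError):
            eb.c_ordinal([0.2, 0.8], [3, 3])

    def test_fast_method_equals_exhaustive_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = int(rng.integers(20, 200))
            mrs = rng.integers(0, 7, n)
            scores = np.round(rng.normal(size=n), 1)  # induce ties
            assert eb.c_ordinal(scores, mrs) == concordance_oracle(
                scores, mrs, larger_outcome_is_better=False
            )

    def test_invariance_under_increasing_transform(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=150)
        mrs = rng.integers(0, 7, 150)
        base = eb.c_ordinal(scores, mrs)
        for transform in (np.exp, np.tanh, lambda s: 3 * s - 7):
            assert eb.c_ordinal(transform(scores), mrs) == pytest.approx(base, abs=1e-12)

    def test_binary_equals_ordinal_on_dichotomized_outcomes(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0.01, 0.99, 200)
        y = rng.integers(0, 2, 200)
        # ordinal outcome 0 (good) / 6 (bad); score = any monotone transform
        mrs = np.where(y == 1, 0, 6)
        assert eb.c_binary(p, y) == pytest.approx(
            eb.c_ordinal(np.log(p), mrs), abs=1e-12
        )


class TestCalibration:
    def test_self_calibration(self):
        rng = np.random.default_rng(12)
        p = expit(rng.normal(-0.5, 1.2, 10000))
        y = (rng.uniform(size=p.size) < p).astype(int)
        res = eb.calibration_intercept_slope(p, y)
        assert res["slope"] == pytest.approx(1.0, abs=0.05)
        assert res["intercept"] == pytest.approx(0.0, abs=0.05)

    def test_overconfident_predictions_halve_the_slope(self):
        rng = np.random.default_rng(13)
        lp = rng.normal(0.0, 1.0, 10000)
        y = (rng.uniform(size=lp.size) < expit(lp)).astype(int)
        res = eb.calibration_intercept_slope(expit(2.0 * lp), y)
        assert res["slope"] == pytest.approx(0.5, abs=0.05)

    def test_event_rate_shift_moves_the_intercept(self):
        rng = np.random.default_rng(14)
        lp = rng.normal(-1.5, 1.0, 10000)
        # outcomes generated at a higher rate than predicted, logits untouched
        y = (rng.uniform(size=lp.size) < expit(lp + 1.0)).astype(int)
        res = eb.calibration_intercept_slope(expit(lp), y)
        assert res["intercept"] > 0.5

    def test_boundary_predictions_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            res = eb.calibration_intercept_slope(
                np.array([0.0, 0.4, 0.6, 1.0]), np.array([0, 0, 1, 1])
            )
        assert np.isfinite(res["slope"])

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            eb.calibration_intercept_slope([0.2, 0.4], [1, 1])


class TestBootstrap:
    @staticmethod
    def mean_metric(d):
        return float(d["x"].mean())

    def test_constant_metric_degenerate_interval(self):
        d = pd.DataFrame({"x": np.ones(50)})
        ci = eb.bootstrap_ci(self.mean_metric, d, B=100, seed=0)
        assert ci.lower == ci.point == ci.upper == 1.0

    def test_seed_determinism(self):
        d = pd.DataFrame({"x": np.random.default_rng(0).normal(size=100)})
        a = eb.bootstrap_ci(self.mean_metric, d, B=100, seed=5)
        b = eb.bootstrap_ci(self.mean_metric, d, B=100, seed=5)
        c = eb.bootstrap_ci(self.mean_metric, d, B=100, seed=6)
        assert (a.lower, a.upper) == (b.lower, b.upper)
        assert (a.lower, a.upper) != (c.lower, c.upper)

    def test_order_statistic_indices(self):
        assert bootstrap_order_indices(2000) == (49, 1949)
        assert bootstrap_order_indices(200) == (4, 194)

    def test_matches_normal_theory_for_the_mean(self):
        rng = np.random.default_rng(21)
        d = pd.DataFrame({"x": rng.normal(size=5000)})
        ci = eb.bootstrap_ci(self.mean_metric, d, B=400, seed=3)
        se = d["x"].std(ddof=1) / np.sqrt(len(d))
        lo = ci.point - 1.96 * se
        hi = ci.point + 1.96 * se
        width = hi - lo
        assert abs(ci.lower - lo) < 0.1 * width
        assert abs(ci.upper - hi) < 0.1 * width

    def test_mostly_undefined_metric_is_reported_failure(self):
        d = pd.DataFrame({"x": np.arange(5), "y": [1, 1, 1, 1, 0]})

        def fragile(df):
            return eb.c_binary(df["x"] / 10.0, df["y"])

        with pytest.raises(BootstrapFailure):
            eb.bootstrap_ci(fragile, d, B=100, seed=0)

    def test_small_b_rejected(self):
        with pytest.raises(ValueError):
            eb.bootstrap_ci(self.mean_metric, pd.DataFrame({"x": [1.0]}), B=10)


class TestValidateExternal:
    def test_report_structure_and_ci_ordering(self, fitted_updated, true_model):
        df = eb.generate_cohort(eb.CohortSpec(n=800, seed=300)).df
        rep = eb.validate_external(fitted_updated, df, B=60, seed=1)
        assert rep.n == 800
        for name in ("c_binary", "c_ordinal", "cal_intercept", "cal_slope"):
            m = getattr(rep, name)
            assert m.lower <= m.point <= m.upper
        assert 0.5 < rep.c_binary.point < 1.0
        frame = rep.to_frame()
        assert list(frame["metric"]) == ["c_binary", "c_ordinal", "cal_intercept", "cal_slope"]

    def test_report_round_trips_to_json_and_csv(self, tmp_path, fitted_updated):
        df = eb.generate_cohort(eb.CohortSpec(n=400, seed=301)).df
        rep = eb.validate_external(fitted_updated, df, B=60, seed=1)
        rep.to_json(tmp_path / "r.json")
        rep.to_csv(tmp_path / "r.csv")
        back = pd.read_csv(tmp_path / "r.csv")
        assert back.shape[0] == 4


class TestConcordanceProperties:
    from hypothesis import assume, given, settings
    from hypothesis import strategies as st

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.floats(-5, 5, allow_nan=False, allow_infinity=False),
                st.integers(0, 6),
            ),
            min_size=2,
            max_size=60,
        )
    )
    def test_bounded_and_invariant_under_monotone_transform(self, data):
        from hypothesis import assume

        scores = np.array([d[0] for d in data])
        mrs = np.array([d[1] for d in data])
        assume(len(np.unique(mrs)) >= 2)
        c = eb.c_ordinal(scores, mrs)
        assert 0.0 <= c <= 1.0
        # power-of-two scaling is exact in floats, so ties are preserved exactly
        assert eb.c_ordinal(4.0 * scores, mrs) == pytest.approx(c, abs=1e-12)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.integers(40, 5000))
    def test_percentile_indices_match_exact_rational_rule(self, B):
        import math
        from fractions import Fraction

        lo, hi = bootstrap_order_indices(B)
        assert lo == math.ceil(Fraction(1, 40) * B) - 1
        assert hi == math.floor(Fraction(39, 40) * B) - 1
        assert 0 <= lo <= hi < B


def test_calibration_curve_partitions_cohort():
    rng = np.random.default_rng(17)
    p = rng.uniform(0.05, 0.95, 1000)
    y = (rng.uniform(size=1000) < p).astype(int)
    curve = eb.calibration_curve(p, y)
    assert curve.counts.sum() == 1000
    assert np.all((curve.observed >= 0) & (curve.observed <= 1))
    # grouped observed rates should track predictions for calibrated data
    assert np.corrcoef(curve.mean_predicted, curve.observed)[0, 1] > 0.9
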