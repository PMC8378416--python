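import numpy as np
import pandas as pd
import pytest

import evtbenefit as eb
from evtbenefit.benefit import BENEFIT_CLASS_CUTS
from evtbenefit.validation import UndefinedMetricError

from conftest import concordance_oracle


def pair_cohort(benefits_t, benefits_c, y_t=None, y_c=None):
    """Small two-arm cohort with given predicted benefits per arm."""
    nt, nc = len(benefits_t), len(benefits_c)
    y_t = [0] * nt if y_t is None else y_t
    y_c = [6] * nc if y_c is None else y_c
    return pd.DataFrame(
        {
            "benefit": list(benefits_t) + list(benefits_c),
            "evt": [1] * nt + [0] * nc,
            "mrs_90d": list(y_t) + list(y_c),
        }
    )


class TestMatching:
    def test_rank_alignment_with_identical_benefit_ladders(self):
        vals = [0.05, 0.10, 0.20]
        pairs = eb.match_by_predicted_benefit(pair_cohort(vals, vals), seed=0)
        assert sorted(pairs.table["pair_predicted"]) == sorted(vals)
        assert np.array_equal(
            pairs.table["treated_benefit"], pairs.table["control_benefit"]
        )

    def test_larger_arm_down_sampled(self):
        cohort = pair_cohort([0.1, 0.2, 0.3], [0.1, 0.15, 0.2, 0.25, 0.3])
        pairs = eb.match_by_predicted_benefit(cohort, seed=0)
        assert len(pairs) == 3
        assert pairs.n_dropped == 2

    def test_empty_arm_rejected(self):
        cohort = pair_cohort([0.1, 0.2], [])
        with pytest.raises(ValueError):
            eb.match_by_predicted_benefit(cohort, seed=0)

    def test_rank_matching_beats_random_pairing(self):
        rng = np.random.default_rng(50)
        for seed in range(20):
            bt = rng.uniform(0, 0.3, 40)
            bc = rng.uniform(0, 0.3, 40)
            pairs = eb.match_by_predicted_benefit(pair_cohort(bt, bc), seed=seed)
            matched_gap = np.abs(
                pairs.table["treated_benefit"] - pairs.table["control_benefit"]
            ).mean()
            shuffled_gap = np.abs(bt - rng.permutation(bc)).mean()
            assert matched_gap <= shuffled_gap + 1e-12

    def test_same_seed_reproducible(self):
        cohort = pair_cohort(
            np.linspace(0, 0.3, 10), np.linspace(0, 0.3, 7)
        )
        a = eb.match_by_predicted_benefit(cohort, seed=4).table
        b = eb.match_by_predicted_benefit(cohort, seed=4).table
        pd.testing.assert_frame_equal(a, b)

    def test_nearest_neighbor_method_pairs_everyone_once(self):
        rng = np.random.default_rng(51)
        cohort = pair_cohort(rng.uniform(0, 0.3, 12), rng.uniform(0, 0.3, 12))
        pairs = eb.match_by_predicted_benefit(cohort, seed=0, method="nearest")
        assert len(pairs) == 12
        assert pairs.table["treated_id"].nunique() == 12
        assert pairs.table["control_id"].nunique() == 12


class TestCForBenefit:
    def test_single_concordant_comparison(self):
        table = pd.DataFrame(
            {"pair_predicted": [0.20, 0.05], "pair_observed": [1, -1]}
        )
        assert eb.c_for_benefit(table) == 1.0

    def test_all_predicted_ties_give_half(self):
        table = pd.DataFrame(
            {"pair_predicted": [0.1] * 6, "pair_observed": [1, 0, -1, 1, 0, -1]}
        )
        assert eb.c_for_benefit(table) == 0.5

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(60)
        table = pd.DataFrame(
            {
                "pair_predicted": np.round(rng.uniform(0, 0.3, 100), 2),
                "pair_observed": rng.integers(-1, 2, 100),
            }
        )
        assert eb.c_for_benefit(table) == concordance_oracle(
            table["pair_predicted"], table["pair_observed"], larger_outcome_is_better=True
        )

    def test_invariant_under_increasing_transform(self):
        rng = np.random.default_rng(61)
        pred = rng.uniform(0, 0.3, 80)
        obs = rng.integers(-1, 2, 80)
        base = eb.c_for_benefit(pd.DataFrame({"pair_predicted": pred, "pair_observed": obs}))
        trans = eb.c_for_benefit(
            pd.DataFrame({"pair_predicted": np.exp(5 * pred), "pair_observed": obs})
        )
        assert trans == pytest.approx(base, abs=1e-12)

    def test_constant_observed_benefit_is_undefined_not_half(self):
        table = pd.DataFrame({"pair_predicted": [0.1, 0.2], "pair_observed": [1, 1]})
        with pytest.raises(UndefinedMetricError):
            eb.c_for_benefit(table)

    def test_perfect_ordering_gives_one(self):
        table = pd.DataFrame(
            {"pair_predicted": [0.01, 0.1, 0.2], "pair_observed": [-1, 0, 1]}
        )
        assert eb.c_for_benefit(table) == 1.0

    def test_no_heterogeneity_constant_prediction_is_half_via_pipeline(self):
        """Constant predicted benefit + varying outcomes -> exactly 0.5."""
        rng = np.random.default_rng(62)
        cohort = pair_cohort(
            [0.1] * 30,
            [0.1] * 30,
            y_t=rng.integers(0, 7, 30),
            y_c=rng.integers(0, 7, 30),
        )
        pairs = eb.match_by_predicted_benefit(cohort, seed=0)
        assert eb.c_for_benefit(pairs) == 0.5


class TestGroupCalibration:
    def test_class_cut_points_are_one_and_ten_percent(self):
        rng = np.random.default_rng(70)
        cohort = pair_cohort(rng.uniform(0, 0.3, 50), rng.uniform(0, 0.3, 50))
        out = eb.benefit_group_calibration(cohort, grouping="classes")
        assert BENEFIT_CLASS_CUTS == (0.01, 0.10)
        assert out.table["upper"].iloc[0] == 0.01
        assert out.table["lower"].iloc[1] == 0.01
        assert out.table["upper"].iloc[1] == 0.10
        assert list(out.table["group"]) == ["low", "moderate", "high"]
        recomputed = [
            ((cohort["benefit"] < 0.01).sum()),
            (((cohort["benefit"] >= 0.01) & (cohort["benefit"] < 0.10)).sum()),
            ((cohort["benefit"] >= 0.10).sum()),
        ]
        assert list(out.table["n_treated"] + out.table["n_control"]) == recomputed

    def test_counts_partition_the_cohort(self):
        rng = np.random.default_rng(71)
        cohort = pair_cohort(rng.uniform(0, 0.3, 200), rng.uniform(0, 0.3, 200))
        out = eb.benefit_group_calibration(cohort, grouping="quintiles")
        assert (out.table["n_treated"] + out.table["n_control"]).sum() == 400

    def test_constant_benefit_collapses_to_single_group(self):
        cohort = pair_cohort([0.1] * 5, [0.1] * 5)
        out = eb.benefit_group_calibration(cohort, grouping="quintiles")
        assert len(out.table) == 1
        assert out.table["n_treated"].iloc[0] == 5

    def test_empty_arm_in_group_is_flagged_not_fatal(self):
        cohort = pair_cohort([0.25, 0.28, 0.3], [0.01, 0.02, 0.03])
        out = eb.benefit_group_calibration(cohort, grouping="classes")
        assert "high" in out.flagged_groups or "low" in out.flagged_groups
        assert out.table["observed_benefit"].isna().any()

    def test_weighted_group_benefits_aggregate_to_cohort_benefit(self):
        """With arms balanced inside each group, count-weighted group observed
        benefits equal the whole-cohort arm difference in P(mRS 0-2)."""
        rng = np.random.default_rng(72)
        b = np.repeat(rng.uniform(0, 0.3, 50), 2)  # same benefit both arms
        y_t = rng.integers(0, 7, 50)
        y_c = rng.integers(0, 7, 50)
        cohort = pair_cohort(b[::2], b[1::2], y_t=y_t, y_c=y_c)
        out = eb.benefit_group_calibration(cohort, grouping="quintiles")
        w = out.table["n_treated"] + out.table["n_control"]
        agg = float((out.table["observed_benefit"] * w).sum() / w.sum())
        overall = float((y_t <= 2).mean() - (y_c <= 2).mean())
        assert agg == pytest.approx(overall, abs=1e-12)


class TestRegistrySurrogate:
    def test_requires_reperfusion_indicator_and_all_treated(self):
        rng = np.random.default_rng(80)
        cohort = pair_cohort(rng.uniform(0, 0.3, 10), rng.uniform(0, 0.3, 10))
        with pytest.raises(ValueError, match="etici"):
            eb.registry_surrogate_benefit(cohort)
        cohort["etici_success"] = 1
        with pytest.raises(ValueError, match="all-treated"):
            eb.registry_surrogate_benefit(cohort)

    def test_reperfusion_tied_to_outcome_shows_positive_surrogate_benefit(self):
        spec = eb.CohortSpec(n=20000, seed=81, design="registry", p_reperf=0.6)
        df = eb.generate_cohort(spec).df
        df["benefit"] = spec.true_model.as_model().predicted_benefit(df)["benefit"].to_numpy()
        out = eb.registry_surrogate_benefit(df, grouping="classes")
        assert out.surrogate
        high = out.table[out.table["group"] == "high"].iloc[0]
        assert high["observed_benefit"] > 0

    def test_null_registry_shows_no_surrogate_benefit(self, true_model):
        # no treatment effect and reperfusion independent of covariates
        null = eb.TrueOutcomeModel(
            spec=true_model.spec,
            cutpoints=true_model.cutpoints,
            coefficients={
                k: v
                for k, v in true_model.coefficients.items()
                if not k.startswith("evt")
            },
        )
        spec = eb.CohortSpec(
            n=50000, seed=82, design="registry", p_reperf=0.5, true_model=null
        )
        df = eb.generate_cohort(spec).df
        df["benefit"] = null.as_model().predicted_benefit(df)["benefit"].to_numpy()
        out = eb.benefit_group_calibration(
            df, grouping="quintiles", arm_col="etici_success"
        )
        for _, row in out.table.iterrows():
            n_t, n_c = row["n_treated"], row["n_control"]
            if n_t == 0 or n_c == 0:
                continue
            se = np.sqrt(0.25 / n_t + 0.25 / n_c)
            assert abs(row["observed_benefit"]) < 2.5 * se
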