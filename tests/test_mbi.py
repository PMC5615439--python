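import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from ebvar.errors import DomainError
from ebvar.mbi import (
    build_effect,
    classify_effect,
    covariate_effect,
    day_of_week_effects,
    order_effect,
    smallest_worthwhile_effect,
    substantiality_probabilities,
)
from ebvar.reliability import ModelSpec, fit_variance_model


class TestSmallestWorthwhileEffect:
    def test_fifth_of_between_subject_sd(self):
        assert smallest_worthwhile_effect(0.10) == pytest.approx(0.02)

    @given(st.floats(min_value=1e-6, max_value=10.0))
    def test_linear_in_sd(self, sd):
        assert smallest_worthwhile_effect(2 * sd) == pytest.approx(
            2 * smallest_worthwhile_effect(sd)
        )

    def test_degenerate_sd_rejected(self):
        with pytest.raises(DomainError):
            smallest_worthwhile_effect(0.0)


class TestSubstantialityProbabilities:
    def test_tiny_se_concentrates_on_trivial(self):
        p = substantiality_probabilities(0.0, 1e-12, 30, swe_log=0.05)
        assert p == pytest.approx((0.0, 1.0, 0.0), abs=1e-12)

    def test_effect_at_threshold_splits_evenly(self):
        p_pos, _, _ = substantiality_probabilities(0.05, 0.17, 12, swe_log=0.05)
        assert p_pos == 0.5  # exact: t is symmetric and (swe-b)/se = 0

    def test_t_distribution_oracle(self):
        swe = 0.04
        p_pos, _, _ = substantiality_probabilities(2 * swe, swe / 2, 30, swe)
        assert p_pos == pytest.approx(float(stats.t.sf(-2.0, 30)), abs=1e-12)
        assert p_pos == pytest.approx(0.9727, abs=2e-4)

    @given(
        b=st.floats(min_value=-1.0, max_value=1.0),
        se=st.floats(min_value=1e-4, max_value=1.0),
        df=st.integers(min_value=1, max_value=200),
    )
    def test_probabilities_sum_to_one(self, b, se, df):
        p = substantiality_probabilities(b, se, df, 0.05)
        assert sum(p) == pytest.approx(1.0, abs=1e-9)

    def test_monotone_in_effect(self):
        grid = np.linspace(-0.5, 0.5, 41)
        pos = [substantiality_probabilities(b, 0.1, 30, 0.05)[0] for b in grid]
        assert all(a <= b + 1e-15 for a, b in zip(pos, pos[1:]))

    def test_invalid_se_rejected(self):
        with pytest.raises(DomainError):
            substantiality_probabilities(0.1, 0.0, 30, 0.05)


class TestClassifyEffect:
    def test_dual_crossing_rule_makes_unclear(self):
        clarity, _, _ = classify_effect(0.20, 0.70, 0.10)
        assert clarity == "unclear"

    def test_most_likely_increase(self):
        assert classify_effect(0.998, 0.002, 0.0) == ("clear", "increase", "most likely")

    def test_possible_increase(self):
        assert classify_effect(0.60, 0.39, 0.01) == ("clear", "increase", "possible")

    def test_boundary_probability_takes_higher_bin(self):
        assert classify_effect(0.75, 0.25, 0.0)[2] == "likely"
        assert classify_effect(0.95, 0.05, 0.0)[2] == "very likely"

    def test_tie_breaks_toward_trivial(self):
        assert classify_effect(0.48, 0.48, 0.04)[1] == "trivial"

    @given(
        b=st.floats(min_value=-0.5, max_value=0.5),
        se=st.floats(min_value=1e-3, max_value=0.5),
        df=st.integers(min_value=2, max_value=100),
    )
    def test_negation_symmetry(self, b, se, df):
        e_pos = build_effect("x", b, se, df, 0.05)
        e_neg = build_effect("x", -b, se, df, 0.05)
        assert e_pos.p_positive == pytest.approx(e_neg.p_negative, abs=1e-12)
        assert e_pos.p_trivial == pytest.approx(e_neg.p_trivial, abs=1e-12)
        assert e_pos.clarity == e_neg.clarity
        mirror = {"increase": "decrease", "decrease": "increase", "trivial": "trivial"}
        assert e_neg.direction == mirror[e_pos.direction]

    @pytest.mark.parametrize(
        "b,expected", [(0.2, "increase"), (-0.2, "decrease"), (0.01, "trivial")]
    )
    def test_vanishing_se_recovers_deterministic_sign(self, b, expected):
        e = build_effect("x", b, 1e-10, 50, swe_log=0.05)
        assert (e.clarity, e.direction) == ("clear", expected)
        assert e.qualifier == "most likely"


class TestModelContrasts:
    def test_two_sd_effect_invariant_to_covariate_units(self, paperlike_frame):
        spec = ModelSpec(outcome="tee_kcal", fixed_covariates=("age", "sex"))
        vc = fit_variance_model(paperlike_frame, None, spec)
        months = paperlike_frame.copy()
        months["age"] = months["age"] * 12.0
        vc_m = fit_variance_model(months, None, spec)
        e, e_m = covariate_effect(vc, "age"), covariate_effect(vc_m, "age")
        assert e.effect_pct == pytest.approx(e_m.effect_pct, rel=1e-6)
        assert e.se_log == pytest.approx(e_m.se_log, rel=1e-6)

    def test_sex_contrast_uses_level_difference(self, paperlike_frame):
        vc = fit_variance_model(paperlike_frame, None, ModelSpec(outcome="tee_kcal"))
        e = covariate_effect(vc, "sex")
        assert e.effect_log == pytest.approx(vc.fixed_effects["sex[male]"].beta)

    def test_order_effect_back_transform_inverse(self, paperlike_frame):
        # force a known slope into the fitted coefficients: beta per day such
        # that the day1 -> day7 change back-transforms to exactly -15%
        vc = fit_variance_model(paperlike_frame, None, ModelSpec(outcome="intake_kcal"))
        vc.fe_params["order_index"] = math.log(0.85) / 6.0
        vc.fixed_effects["order_index"] = type(vc.fixed_effects["order_index"])(
            beta=math.log(0.85) / 6.0, se=vc.fixed_effects["order_index"].se
        )
        e = order_effect(vc, n_days=7)
        assert e.effect_pct == pytest.approx(-15.0, abs=1e-9)

    def test_order_requires_linear_term(self, paperlike_frame):
        vc = fit_variance_model(
            paperlike_frame, None, ModelSpec(outcome="tee_kcal", fixed_covariates=("sex",))
        )
        with pytest.raises(DomainError):
            order_effect(vc)

    def test_unknown_covariate_rejected(self, paperlike_frame):
        vc = fit_variance_model(paperlike_frame, None, ModelSpec(outcome="tee_kcal"))
        with pytest.raises(DomainError):
            covariate_effect(vc, "shoe_size")


class TestDayOfWeekEffects:
    def test_highest_lowest_consistent_with_day_coefficients(self, paperlike_frame):
        vc = fit_variance_model(paperlike_frame, None, ModelSpec(outcome="alcohol_pct"))
        dow = day_of_week_effects(vc)
        coefs = {
            d: float(vc.fe_params.get(f"day_of_week[{d}]", 0.0))
            for d in ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")
        }
        spread = max(coefs.values()) - min(coefs.values())
        assert dow.highest_lowest.effect_pct == pytest.approx(
            100.0 * (math.exp(spread) - 1.0), rel=1e-9
        )
        assert coefs[dow.highest_day] == max(coefs.values())

    def test_all_pairwise_contrasts_reported(self, paperlike_frame):
        vc = fit_variance_model(paperlike_frame, None, ModelSpec(outcome="tee_kcal"))
        dow = day_of_week_effects(vc)
        assert len(dow.pairwise) == 21  # 7 choose 2
        assert set(dow.adjusted_means["day"]) == {
            "Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun",
        }

    def test_flat_days_give_near_zero_effects(self):
        import pandas as pd

        rng = np.random.default_rng(9)
        days = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")
        rows = []
        for i in range(60):
            u = rng.normal(0, 0.3)
            for j in range(7):
                rows.append(
                    {"subject_id": f"S{i}", "order_index": j + 1, "day_of_week": days[j],
                     "wear_minutes": 1440.0, "wear_fraction": 1.0,
                     "y": math.exp(3.0 + u + rng.normal(0, 0.05))}
                )
        vc = fit_variance_model(
            pd.DataFrame(rows), None, ModelSpec(outcome="y", fixed_covariates=("day_of_week",))
        )
        dow = day_of_week_effects(vc)
        assert abs(dow.highest_lowest.effect_pct) < 3.0
        assert dow.pairwise["effect_pct"].abs().max() < 3.0

    def test_friday_alcohol_bump_recovered(self, paperlike_frame):
        # the study-like preset elevates Friday/Saturday alcohol share
        vc = fit_variance_model(paperlike_frame, None, ModelSpec(outcome="alcohol_pct"))
        dow = day_of_week_effects(vc)
        assert dow.highest_day in ("Fri", "Sat")
        means = dow.adjusted_means.set_index("day")["mean"]
        assert means[["Fri", "Sat"]].min() > means[["Mon", "Wed", "Thu"]].max()

    def test_holm_adjustment_optional(self, paperlike_frame):
        vc = fit_variance_model(paperlike_frame, None, ModelSpec(outcome="tee_kcal"))
        adj = day_of_week_effects(vc, holm_adjust=True).pairwise
        assert "p_holm" in adj.columns
        assert (adj["p_holm"] >= adj["p_value"] - 1e-12).all()
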