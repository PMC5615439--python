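import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import anova_components, balanced_grid
from ebvar.errors import DomainError, EstimationError
from ebvar.reliability import (
    ModelSpec,
    auto_offset,
    days_needed,
    fit_variance_model,
    icc_from_components,
    intra_individual_cv,
    inverse_log_transform,
    log_transform,
    reliability_table,
    spearman_brown_step_up,
)


class TestLogTransform:
    def test_log_of_one_is_zero(self):
        assert log_transform([1.0])[0] == 0.0

    def test_offset_handles_zero_outcome_days(self):
        # a zero-MVPA day with the +1 offset maps to log(1) = 0
        assert log_transform([0.0], offset=1.0)[0] == 0.0

    def test_nonpositive_shifted_value_names_the_record(self):
        with pytest.raises(DomainError, match="index 2"):
            log_transform([1.0, 2.0, -0.5], offset=0.0)

    @given(
        st.lists(st.floats(min_value=0.01, max_value=1e4), min_size=1, max_size=20),
        st.floats(min_value=0.0, max_value=10.0),
    )
    def test_round_trip_inverts(self, values, offset):
        back = inverse_log_transform(log_transform(values, offset), offset)
        assert np.allclose(back, values, rtol=1e-12)

    def test_auto_offset_policy(self):
        assert auto_offset([5.0, 2.0]) == 0.0  # strictly positive: no shift
        assert auto_offset([0.0, 3.0]) == 1.0  # zeros: conventional +1
        assert auto_offset([-50.0, 3.0]) == 51.0  # negative PAEE day: min -> 1


class TestVarianceModel:
    def test_reml_matches_anova_oracle_on_balanced_grid(self):
        df = balanced_grid(n_subjects=5, n_days=4)
        vc = fit_variance_model(df, None, ModelSpec(outcome="y", fixed_covariates=()))
        s2b_oracle, s2w_oracle = anova_components(df)
        assert vc.sigma2_between == pytest.approx(s2b_oracle, abs=1e-6)
        assert vc.sigma2_within == pytest.approx(s2w_oracle, abs=1e-6)
        icc = icc_from_components(vc)
        assert icc == pytest.approx(s2b_oracle / (s2b_oracle + s2w_oracle), abs=1e-6)

    def test_no_between_subject_signal_gives_near_zero_variance(self):
        rng = np.random.default_rng(5)
        rows = []
        for i in range(8):
            noise = rng.normal(0, 0.1, 6)
            noise -= noise.mean()  # identical subject means by construction
            for j, v in enumerate(noise):
                rows.append(
                    {
                        "subject_id": f"S{i}",
                        "order_index": j + 1,
                        "day_of_week": "Mon",
                        "wear_minutes": 1440.0,
                        "wear_fraction": 1.0,
                        "y": math.exp(2.0 + v),
                    }
                )
        vc = fit_variance_model(pd.DataFrame(rows), None, ModelSpec(outcome="y", fixed_covariates=()))
        assert vc.sigma2_between < 1e-4 * vc.sigma2_within

    def test_constant_covariate_is_a_singular_design(self, paperlike_frame):
        df = paperlike_frame.copy()
        df["age"] = 44.0
        with pytest.raises(EstimationError, match="age"):
            fit_variance_model(df, None, ModelSpec(outcome="tee_kcal"))

    def test_requires_repeated_measurements(self):
        df = balanced_grid(n_subjects=5, n_days=1)
        with pytest.raises(EstimationError, match="2 valid days"):
            fit_variance_model(df, None, ModelSpec(outcome="y", fixed_covariates=()))

    def test_full_covariate_fit_on_study_shaped_cohort(self, paperlike_frame):
        vc = fit_variance_model(paperlike_frame, None, ModelSpec(outcome="tee_kcal"))
        assert vc.converged
        assert vc.sigma2_between > 0 and vc.sigma2_within > 0
        # intercept + age + injury + wear + sex + 6 dow + order = 12 terms
        assert len(vc.fe_params) == 12
        assert vc.df_resid == vc.n_obs - 12 - vc.n_subjects


class TestICC:
    @pytest.mark.parametrize(
        "s2b,s2w,expected", [(1.0, 0.0, 1.0), (0.5, 0.5, 0.5), (0.2, 0.6, 0.25)]
    )
    def test_variance_ratio(self, s2b, s2w, expected):
        assert icc_from_components((s2b, s2w)) == pytest.approx(expected)

    def test_negative_between_estimate_truncated(self):
        assert icc_from_components((-0.1, 0.5)) == 0.0

    def test_undefined_when_both_zero(self):
        with pytest.raises(DomainError):
            icc_from_components((0.0, 0.0))


class TestDaysNeeded:
    @pytest.mark.parametrize("icc_s,n_exp", [(0.80, 1.0), (0.50, 4.0), (0.20, 16.0)])
    def test_prophecy_formula(self, icc_s, n_exp):
        n_real, n_int = days_needed(icc_s, 0.80)
        assert n_real == pytest.approx(n_exp, abs=1e-12)
        assert n_int == int(n_exp)

    @given(st.floats(min_value=0.01, max_value=0.99), st.floats(min_value=0.01, max_value=0.99))
    def test_step_up_identity(self, icc_s, icc_t):
        n_real, _ = days_needed(icc_s, icc_t)
        assert spearman_brown_step_up(icc_s, n_real) == pytest.approx(icc_t, abs=1e-12)

    def test_monotone_decreasing_in_single_day_icc(self):
        grid = np.linspace(0.05, 0.95, 50)
        n = [days_needed(i)[0] for i in grid]
        assert all(a > b for a, b in zip(n, n[1:]))

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.3])
    def test_degenerate_icc_rejected(self, bad):
        with pytest.raises(DomainError):
            days_needed(bad)


class TestIntraIndividualCV:
    def frame(self, per_subject_values):
        rows = []
        for sid, vals in per_subject_values.items():
            for j, v in enumerate(vals):
                rows.append(
                    {"subject_id": sid, "order_index": j + 1, "day_of_week": "Mon",
                     "wear_minutes": 1440.0, "wear_fraction": 1.0, "y": v}
                )
        return pd.DataFrame(rows)

    def test_identical_days_give_zero(self):
        cv = intra_individual_cv(self.frame({"A": [5, 5, 5], "B": [1, 2, 3]}), "y")
        assert cv.per_subject["A"] == 0.0

    def test_hand_arithmetic(self):
        cv = intra_individual_cv(self.frame({"A": [1, 2, 3]}), "y")
        assert cv.per_subject["A"] == pytest.approx(50.0)  # mean 2, sample SD 1

    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_scale_invariance(self, c):
        base = intra_individual_cv(self.frame({"A": [1, 2, 3]}), "y")
        scaled = intra_individual_cv(self.frame({"A": [c, 2 * c, 3 * c]}), "y")
        assert scaled.per_subject["A"] == pytest.approx(base.per_subject["A"], rel=1e-9)

    def test_zero_mean_subject_excluded_with_warning(self, caplog):
        df = self.frame({"A": [0.0, 0.0], "B": [1, 2]})
        with caplog.at_level("WARNING"):
            cv = intra_individual_cv(df, "y")
        assert "A" not in cv.per_subject and "B" in cv.per_subject
        assert any("zero" in m for m in caplog.messages)

    def test_single_day_subjects_excluded(self):
        cv = intra_individual_cv(self.frame({"A": [4.0], "B": [1, 2]}), "y")
        assert set(cv.per_subject) == {"B"}


class TestReliabilityTable:
    def test_deterministic_and_equal_outcomes_match(self, paperlike_frame):
        df = paperlike_frame.copy()
        df["tee_copy"] = df["tee_kcal"]
        a, b = reliability_table(df, None, ["tee_kcal", "tee_copy"])
        assert a.icc_single_day == b.icc_single_day
        assert a.days_needed == b.days_needed
        assert a.cv_mean_pct == b.cv_mean_pct

    def test_projection_beyond_observed_span_is_flagged(self, paperlike_frame):
        rows = reliability_table(paperlike_frame, None, ["tee_kcal", "fat_pct"])
        by_outcome = {r.outcome: r for r in rows}
        assert not by_outcome["tee_kcal"].extrapolated  # 1 day from 7 observed
        # dietary fat needs far more days than the week observed
        assert by_outcome["fat_pct"].days_needed > 7
        assert by_outcome["fat_pct"].extrapolated

    def test_zero_between_variance_reported_unreliable(self, monkeypatch):
        import ebvar.reliability as rel

        df = balanced_grid(n_subjects=4, n_days=3)

        def degenerate_fit(records, subjects, spec):
            vc = fit_variance_model(records, subjects, spec)
            vc.sigma2_between = 0.0
            return vc

        monkeypatch.setattr(rel, "fit_variance_model", degenerate_fit)
        (row,) = rel.reliability_table(df, None, ["y"], covariates=())
        assert row.unreliable
        assert row.days_needed is None and row.days_needed_real is None
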