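"""Variance partitioning, ICC and Spearman-Brown day projections."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arcgait import (
    VarianceComponents,
    build_day_table,
    day_of_week_effects,
    days_needed,
    fit_random_intercept,
    icc_single_day,
    icc_with_ci,
    reliability_table,
    simulate_latent_cohort,
    spearman_brown,
)


def anova_components(df, outcome="y", group="participant_id"):
    """Closed-form one-way expected-mean-squares solution (balanced)."""
    g = df.groupby(group)[outcome]
    k = df.groupby(group).size().iloc[0]
    n_subj = g.ngroups
    grand = df[outcome].mean()
    msb = k * ((g.mean() - grand) ** 2).sum() / (n_subj - 1)
    msw = g.apply(lambda s: ((s - s.mean()) ** 2).sum()).sum() / (len(df) - n_subj)
    s2b = max((msb - msw) / k, 0.0)
    return s2b, msw


@pytest.mark.parametrize("n_subj,n_days,seed", [(20, 4, 0), (50, 7, 1), (12, 3, 2)])
def test_reml_matches_anova_on_balanced_designs(n_subj, n_days, seed):
    df = simulate_latent_cohort(n_subj, n_days, 1.0, 0.8, seed=seed)
    vc = fit_random_intercept(df, "y")
    s2b, s2e = anova_components(df)
    assert vc.sigma2_between == pytest.approx(s2b, abs=1e-6)
    assert vc.sigma2_residual == pytest.approx(s2e, abs=1e-6)
    icc_anova = s2b / (s2b + s2e)
    assert icc_single_day(vc) == pytest.approx(icc_anova, abs=1e-6)


def test_reml_agrees_with_statsmodels_mixedlm():
    """Independent library cross-check of the in-package REML fit."""
    import statsmodels.formula.api as smf

    df = simulate_latent_cohort(40, 5, 0.9, 1.1, weekend_effect=-0.2, seed=4)
    vc = fit_random_intercept(df, "y", fixed_covariates=["is_weekend"])
    m = smf.mixedlm(
        "y ~ is_weekend", df.assign(is_weekend=df["is_weekend"].astype(float)),
        groups=df["participant_id"],
    ).fit(reml=True)
    assert vc.sigma2_between == pytest.approx(float(m.cov_re.iloc[0, 0]), rel=1e-3)
    assert vc.sigma2_residual == pytest.approx(float(m.scale), rel=1e-3)
    assert vc.fixed_effects["is_weekend"]["estimate"] == pytest.approx(
        float(m.params["is_weekend"]), abs=1e-4
    )


def test_zero_between_variance_hits_boundary():
    df = simulate_latent_cohort(60, 5, 0.0, 1.0, seed=6)
    vc = fit_random_intercept(df, "y")
    assert vc.sigma2_between == pytest.approx(0.0, abs=0.02)
    assert icc_single_day(vc) == pytest.approx(0.0, abs=0.02)


def test_insufficient_replication_errors():
    df = pd.DataFrame({"participant_id": ["a", "a", "b"], "y": [1.0, 2.0, 3.0]})
    with pytest.raises(ValueError, match="at least 2 subjects"):
        fit_random_intercept(df, "y")


def test_sqrt_transform_rejects_negative_outcomes():
    df = simulate_latent_cohort(10, 3, 1.0, 1.0, seed=0)
    with pytest.raises(ValueError, match="non-negative"):
        fit_random_intercept(df, "y", transform="sqrt")


def test_icc_arithmetic():
    def vc(b, e):
        return VarianceComponents(b, e, {}, 10, 50, False, 0.0)

    assert icc_single_day(vc(3.0, 1.0)) == pytest.approx(0.75)
    assert icc_single_day(vc(0.0, 1.0)) == 0.0
    assert math.isnan(icc_single_day(vc(0.0, 0.0)))


class TestDaysNeeded:
    @pytest.mark.parametrize(
        "icc_s, expected",
        [(0.71, 2), (0.8, 1), (0.37, 7), (0.46, 5), (0.63, 3), (0.53, 4)],
    )
    def test_published_examples(self, icc_s, expected):
        assert days_needed(icc_s, 0.8) == expected

    def test_formula_undefined_at_zero(self):
        with pytest.raises(ValueError, match="positive"):
            days_needed(0.0)
        with pytest.raises(ValueError):
            days_needed(-0.2)

    def test_perfect_reliability_needs_one_day(self):
        assert days_needed(1.0) == 1
        assert days_needed(0.999) == 1

    def test_bad_target_rejected(self):
        with pytest.raises(ValueError, match="target"):
            days_needed(0.5, icc_t=1.0)

    @given(st.floats(0.01, 0.99), st.floats(0.01, 0.99))
    @settings(max_examples=200, deadline=None)
    def test_composite_reliability_reaches_target(self, icc_s, icc_t):
        n = days_needed(icc_s, icc_t)
        assert spearman_brown(icc_s, n) >= icc_t - 1e-9
        if n > 1:
            assert spearman_brown(icc_s, n - 1) < icc_t

    @given(st.floats(0.02, 0.98), st.floats(0.0, 0.5))
    @settings(max_examples=200, deadline=None)
    def test_monotone_nonincreasing_in_icc(self, icc_s, bump):
        hi = min(icc_s + bump, 0.999)
        assert days_needed(hi) <= days_needed(icc_s)


def test_parameter_recovery_on_synthetic_cohort():
    """ICC from REML components recovers the generating variance split."""
    df = simulate_latent_cohort(200, 7, 1.0, 1.0, seed=12)
    icc = icc_single_day(fit_random_intercept(df, "y"))
    assert icc == pytest.approx(0.5, abs=0.05)


def test_bootstrap_ci_brackets_point_estimate():
    df = simulate_latent_cohort(60, 5, 1.0, 1.0, seed=13)
    icc, lo, hi = icc_with_ci(df, "y", n_boot=60, seed=13)
    assert lo < icc < hi
    assert 0 <= lo and hi <= 1


class TestReliabilityTable:
    def test_six_outcomes_by_four_strata(self, no_dropout_cohort):
        _, (days, _, _) = no_dropout_cohort
        table = build_day_table(days).table
        rel = reliability_table(table, n_boot=15, seed=0)
        assert len(rel) == 24
        assert rel["outcome"].nunique() == 6
        assert list(rel["stratum"].unique()) == [
            "whole_group",
            "dementia",
            "high",
            "intermediate",
        ]
        # volume outcomes precede pattern, pattern precede variability
        assert list(rel["outcome"][:4]) == ["total_walk_time_s"] * 4
        assert list(rel["outcome"][-4:]) == ["variability_s"] * 4

    def test_small_stratum_flagged_unavailable(self):
        df = simulate_latent_cohort(12, 5, 1.0, 1.0, seed=3)
        df["care_level"] = "high"
        df.loc[df["participant_id"] == "S0001", "care_level"] = "dementia"
        df["total_walk_time_s"] = np.exp(df.pop("y"))
        rel = reliability_table(
            df, strata=("dementia", "high"), n_boot=10, outcomes=["total_walk_time_s"]
        )
        dem = rel[rel["stratum"] == "dementia"].iloc[0]
        assert not dem["available"] and math.isnan(dem["icc"])
        assert rel[rel["stratum"] == "high"].iloc[0]["available"]


class TestDayOfWeekEffects:
    def test_reports_all_21_contrasts(self):
        df = simulate_latent_cohort(30, 7, 1.0, 1.0, seed=7)
        res = day_of_week_effects(df, "y")
        assert len(res.pairwise) == 21
        assert res.pairwise["available"].all()

    def test_constant_outcome_gives_zero_contrasts(self):
        df = simulate_latent_cohort(20, 7, 1.0, 0.0, seed=8)
        # remove all day-to-day variation within subject entirely
        res = day_of_week_effects(df, "y")
        np.testing.assert_allclose(res.pairwise["estimate"], 0.0, atol=1e-8)

    def test_weekend_shift_is_recovered(self):
        df = simulate_latent_cohort(300, 7, 0.8, 0.4, weekend_effect=-0.1, seed=9)
        res = day_of_week_effects(df, "y")
        w = res.weekend_beta
        assert w["ci_low"] <= -0.1 <= w["ci_high"]
        assert w["estimate"] == pytest.approx(-0.1, abs=0.05)

    def test_missing_day_level_flagged_unavailable(self):
        df = simulate_latent_cohort(30, 7, 1.0, 1.0, seed=10)
        df = df[df["day_of_week"] != "Wed"]
        res = day_of_week_effects(df, "y")
        wed = res.pairwise[
            (res.pairwise["day_a"] == "Wed") | (res.pairwise["day_b"] == "Wed")
        ]
        assert len(wed) == 6
        assert (~wed["available"]).all()
        assert wed["p_value"].isna().all()
        rest = res.pairwise[
            (res.pairwise["day_a"] != "Wed") & (res.pairwise["day_b"] != "Wed")
        ]
        assert rest["available"].all()
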