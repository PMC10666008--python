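"""Mixed-model workflow: fitting, selection, contrasts, CV, design calcs."""
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats
import statsmodels.api as sm

from heatwear.models import (
    CANDIDATE_ORDER,
    FitError,
    ModelSpec,
    add_quadratic_if_curved,
    attrition,
    cochran_sample_size,
    compare_heat_metrics,
    extreme_contrast,
    fit_lmm,
    loso_cv,
    lrt,
    marginal_effect,
    proportion_summary,
    stepwise_build,
    subgroup_sensitivity,
)


def make_panel(
    rng,
    n_pid=20,
    n_days=40,
    b0=7.0,
    b_heat=-0.05,
    b_heat2=0.0,
    b_rain=0.01,
    intercept_sd=0.5,
    resid_sd=0.6,
    extra=None,
):
    """Hand-built random-intercept panel with known coefficients."""
    rows = []
    intercepts = rng.normal(0, intercept_sd, n_pid)
    for i in range(n_pid):
        heat = rng.uniform(18, 30, n_days)
        rain = np.where(rng.random(n_days) < 0.2, rng.gamma(1.2, 8, n_days), 0)
        y = (
            b0
            + b_heat * heat
            + b_heat2 * heat**2
            + b_rain * rain
            + intercepts[i]
            + rng.normal(0, resid_sd, n_days)
        )
        for d in range(n_days):
            row = {
                "participant_id": f"P{i:03d}",
                "y": y[d],
                "heat": heat[d],
                "rain": rain[d],
            }
            if extra:
                row.update({k: v(rng) for k, v in extra.items()})
            rows.append(row)
    return pd.DataFrame(rows)


SPEC = ModelSpec(outcome="y", heat="heat", precip="rain")


class TestFitLMM:
    def test_null_effect_ci_covers_zero(self, rng):
        panel = make_panel(rng, b_heat=0.0, n_pid=30, n_days=40)
        fit = fit_lmm(SPEC, panel)
        lo, hi = fit.conf_int.loc["heat"]
        assert lo < 0.0 < hi

    def test_known_effects_recovered(self, rng):
        panel = make_panel(rng, n_pid=40, n_days=60)
        fit = fit_lmm(SPEC, panel)
        assert fit.params["heat"] == pytest.approx(-0.05, abs=0.02)
        assert fit.params["rain"] == pytest.approx(0.01, abs=0.01)
        assert fit.re_var == pytest.approx(0.25, rel=0.6)

    def test_degenerate_limit_matches_pooled_ols(self, rng):
        panel = make_panel(rng, intercept_sd=0.0, n_pid=15, n_days=30)
        fit = fit_lmm(SPEC, panel)
        X = sm.add_constant(panel[["heat", "rain"]])
        ols = sm.OLS(panel["y"], X).fit()
        assert fit.re_var == pytest.approx(0.0, abs=1e-3)
        assert fit.params["heat"] == pytest.approx(ols.params["heat"], abs=1e-3)
        assert fit.params["rain"] == pytest.approx(ols.params["rain"], abs=1e-3)

    def test_aic_identity(self, rng):
        panel = make_panel(rng, n_pid=10, n_days=10)
        fit = fit_lmm(SPEC, panel)
        assert fit.aic == pytest.approx(2 * fit.k_params - 2 * fit.loglik)

    def test_single_participant_rejected(self, rng):
        panel = make_panel(rng, n_pid=1, n_days=10)
        with pytest.raises(FitError):
            fit_lmm(SPEC, panel)

    def test_listwise_deletion(self, rng):
        panel = make_panel(rng, n_pid=8, n_days=12)
        panel.loc[panel.index[:10], "heat"] = np.nan
        fit = fit_lmm(SPEC, panel)
        assert fit.nobs == len(panel) - 10


class TestLRT:
    def test_identical_models_give_zero_and_p_one(self, rng):
        panel = make_panel(rng, n_pid=8, n_days=10)
        fit = fit_lmm(SPEC, panel)
        stat, df, p = lrt(fit, fit)
        assert stat == 0.0
        assert df == 0
        assert p == 1.0

    def test_chi_square_reference_value(self):
        # df=1, statistic 3.84 -> p ~ 0.05
        assert scipy.stats.chi2.sf(3.84, 1) == pytest.approx(0.05, abs=0.001)

    def test_definitional_statistic(self, rng):
        panel = make_panel(rng, n_pid=12, n_days=15)
        small = fit_lmm(ModelSpec(outcome="y", heat="heat"), panel[
            ["participant_id", "y", "heat", "rain"]].dropna())
        big = fit_lmm(SPEC, panel)
        stat, df, p = lrt(small, big)
        assert stat == pytest.approx(2 * (big.loglik - small.loglik), abs=1e-9)
        assert df == 1

    def test_differing_rows_rejected(self, rng):
        panel = make_panel(rng, n_pid=8, n_days=10)
        a = fit_lmm(SPEC, panel)
        b = fit_lmm(SPEC, panel.iloc[:-5])
        with pytest.raises(ValueError):
            lrt(a, b)


class TestStepwise:
    def test_null_candidate_removed_strong_candidate_kept(self, rng):
        panel = make_panel(rng, n_pid=25, n_days=40)
        # 'group_a' shifts y strongly; 'group_b' is pure noise
        panel["group_a"] = rng.choice(["x", "y"], size=len(panel))
        panel["y"] += np.where(panel["group_a"] == "x", 1.5, 0.0)
        panel["group_b"] = rng.choice(["u", "v"], size=len(panel))
        base = ModelSpec(outcome="y", heat="heat", precip="rain")
        final, trail = stepwise_build(base, ("group_a", "group_b"), panel)
        trail = trail.set_index("candidate")
        assert trail.loc["group_a", "kept"]
        assert not trail.loc["group_b", "kept"]
        assert final.covariates == ("group_a",)

    def test_audit_trail_reproducible(self, rng):
        panel = make_panel(rng, n_pid=10, n_days=20)
        panel["sex"] = rng.choice(["male", "female"], size=len(panel))
        base = ModelSpec(outcome="y", heat="heat", precip="rain")
        a_spec, a_trail = stepwise_build(base, ("sex",), panel)
        b_spec, b_trail = stepwise_build(base, ("sex",), panel)
        assert a_spec == b_spec
        pd.testing.assert_frame_equal(a_trail, b_trail)

    def test_default_candidate_order(self):
        assert CANDIDATE_ORDER == ("month", "weekend", "age_group", "sex",
                                   "bmi_group")


class TestQuadratic:
    def test_alpha_zero_never_adds(self, rng):
        panel = make_panel(rng, b_heat2=-0.05, n_pid=15, n_days=30)
        spec, audit, resid = add_quadratic_if_curved(SPEC, panel, alpha=0.0)
        assert not spec.quadratic

    def test_strong_curvature_detected(self, rng):
        panel = make_panel(rng, b_heat=2.4, b_heat2=-0.05, n_pid=20, n_days=40)
        spec, audit, _ = add_quadratic_if_curved(SPEC, panel)
        assert spec.quadratic
        assert audit["p"].iloc[0] < 0.05

    def test_linear_world_usually_rejected(self, rng):
        panel = make_panel(rng, n_pid=20, n_days=30)
        spec, audit, resid = add_quadratic_if_curved(SPEC, panel)
        assert "residual" in resid.columns and "heat" in resid.columns

    def test_quadratic_requires_heat(self):
        with pytest.raises(ValueError):
            ModelSpec(outcome="y", quadratic=True)


class TestMarginalEffect:
    def test_table_arithmetic(self):
        # rounded coefficients 606 and -12 at 20 C give +114 per degree
        assert marginal_effect(606, -12, 20) == pytest.approx(114.0)

    def test_no_quadratic_returns_slope(self):
        for x in (0.0, 20.0, 30.0):
            assert marginal_effect(-0.04, 0.0, x) == pytest.approx(-0.04)

    def test_sign_change_location(self):
        b1, b2 = 606.0, -12.0
        x_star = -(b1 / b2 + 1.0) / 2.0
        assert marginal_effect(b1, b2, x_star - 0.5) > 0
        assert marginal_effect(b1, b2, x_star + 0.5) < 0
        assert marginal_effect(b1, b2, x_star) == pytest.approx(0.0, abs=1e-9)

    def test_matches_prediction_difference(self, rng):
        panel = make_panel(rng, b_heat=2.0, b_heat2=-0.04, n_pid=15, n_days=30)
        fit = fit_lmm(SPEC.with_quadratic(True), panel)
        b1 = fit.params["heat"]
        b2 = fit.params["I(heat ** 2)"]
        for x in (20.0, 25.0, 30.0):
            direct = (b1 * (x + 1) + b2 * (x + 1) ** 2) - (b1 * x + b2 * x**2)
            assert marginal_effect(b1, b2, x) == pytest.approx(direct)


class TestSubgroups:
    def test_null_interaction_not_retained(self, rng):
        panel = make_panel(rng, n_pid=24, n_days=30)
        panel["sex"] = np.repeat(
            rng.choice(["male", "female"], size=24), 30
        )
        out = subgroup_sensitivity(SPEC, panel, "sex")
        assert not out["significant"]
        assert out["per_level"] is None

    def test_heterogeneous_slopes_detected_and_ordered(self, rng):
        # women's heat slope much steeper than men's
        n_pid, n_days = 30, 40
        sex = np.repeat(np.where(np.arange(n_pid) % 2 == 0, "male", "female"),
                        n_days)
        panel = make_panel(rng, n_pid=n_pid, n_days=n_days, b_heat=0.0)
        panel["sex"] = sex
        panel["y"] += np.where(sex == "female", -0.3, -0.05) * panel["heat"]
        out = subgroup_sensitivity(SPEC, panel, "sex")
        assert out["significant"]
        per = out["per_level"].set_index("level")
        assert per.loc["female", "heat_estimate"] < per.loc["male", "heat_estimate"]
        assert per.loc["female", "heat_estimate"] == pytest.approx(-0.3, abs=0.05)

    def test_single_level_factor_errors(self, rng):
        panel = make_panel(rng, n_pid=6, n_days=10)
        panel["sex"] = "male"
        with pytest.raises(ValueError, match="single level"):
            subgroup_sensitivity(SPEC, panel, "sex")

    def test_unknown_factor_rejected(self, rng):
        panel = make_panel(rng, n_pid=6, n_days=10)
        with pytest.raises(ValueError):
            subgroup_sensitivity(SPEC, panel, "village")


class TestExtremeContrast:
    def test_recovers_binary_shift(self, rng):
        panel = make_panel(rng, b_heat=0.0, n_pid=30, n_days=40)
        flag = rng.random(len(panel)) < 0.3
        panel["stress"] = flag
        panel["heavy_rain"] = rng.random(len(panel)) < 0.1
        panel["y"] += np.where(flag, -0.24, 0.0)
        spec = ModelSpec(outcome="y", heat="stress", precip="heavy_rain")
        fit = extreme_contrast(spec, panel)
        lo, hi = fit.conf_int.loc["stress"]
        assert lo <= -0.24 <= hi

    def test_uncorrelated_flag_ci_covers_zero(self, rng):
        panel = make_panel(rng, b_heat=0.0, b_rain=0.0, n_pid=25, n_days=30)
        panel["stress"] = rng.random(len(panel)) < 0.3
        panel["heavy_rain"] = rng.random(len(panel)) < 0.1
        spec = ModelSpec(outcome="y", heat="stress", precip="heavy_rain")
        fit = extreme_contrast(spec, panel)
        lo, hi = fit.conf_int.loc["stress"]
        assert lo < 0.0 < hi

    def test_constant_flag_rejected(self, rng):
        panel = make_panel(rng, n_pid=6, n_days=10)
        panel["stress"] = False
        panel["heavy_rain"] = rng.random(len(panel)) < 0.5
        spec = ModelSpec(outcome="y", heat="stress", precip="heavy_rain")
        with pytest.raises(ValueError, match="no contrast"):
            extreme_contrast(spec, panel)


class TestCompareMetrics:
    def test_duplicate_metric_ties(self, rng):
        panel = make_panel(rng, n_pid=10, n_days=20)
        panel["heat_copy"] = panel["heat"]
        out = compare_heat_metrics(
            SPEC, panel, {"a": "heat", "b": "heat_copy"}
        )
        assert abs(out["aic"].iloc[0] - out["aic"].iloc[1]) < 1e-6

    def test_true_metric_wins(self, rng):
        panel = make_panel(rng, b_heat=-0.2, n_pid=25, n_days=40)
        panel["noise_metric"] = panel["heat"] + rng.normal(0, 4, len(panel))
        out = compare_heat_metrics(
            SPEC, panel, {"true": "heat", "noisy": "noise_metric"}
        )
        assert out["metric"].iloc[0] == "true"


class TestLOSO:
    def test_matches_naive_refit_loop(self, rng):
        panel = make_panel(rng, n_pid=10, n_days=12)
        res = loso_cv(SPEC, panel)
        # oracle: naive loop refitting and scoring by hand
        for row in res.per_participant.itertuples():
            train = panel[panel["participant_id"] != row.participant_id]
            test = panel[panel["participant_id"] == row.participant_id]
            fit = fit_lmm(SPEC, train)
            pred = fit.predict(test)
            y = test["y"].to_numpy()
            sse = np.sum((y - pred) ** 2)
            sst = np.sum((y - y.mean()) ** 2)
            assert row.r2 == pytest.approx(1 - sse / sst, rel=1e-9)
            assert row.rmse == pytest.approx(np.sqrt(sse / len(test)), rel=1e-9)
        assert res.mean_r2 == pytest.approx(res.per_participant["r2"].mean())

    def test_near_noiseless_data_scores_perfectly(self, rng):
        panel = make_panel(rng, intercept_sd=0.0, resid_sd=1e-6, n_pid=6,
                           n_days=10)
        res = loso_cv(SPEC, panel)
        assert (res.per_participant["r2"] > 1 - 1e-6).all()
        assert (res.per_participant["rmse"] < 1e-4).all()

    def test_constant_outcome_reported_missing(self, rng):
        panel = make_panel(rng, n_pid=6, n_days=10)
        pid = "P000"
        panel.loc[panel["participant_id"] == pid, "y"] = 5.0
        res = loso_cv(SPEC, panel)
        row = res.per_participant.set_index("participant_id").loc[pid]
        assert math.isnan(row["r2"])
        assert not math.isnan(res.mean_r2)

    def test_too_few_participants(self, rng):
        panel = make_panel(rng, n_pid=2, n_days=10)
        with pytest.raises(ValueError):
            loso_cv(SPEC, panel)


# ---------------------------------------------------------------------------
# design and descriptive calculations
# ---------------------------------------------------------------------------

class TestSampleSize:
    def test_study_design_value(self):
        assert cochran_sample_size(100_000, 0.95, 0.08) == 150

    def test_monotone_decreasing_in_margin(self):
        sizes = [cochran_sample_size(100_000, 0.95, e)
                 for e in (0.02, 0.05, 0.08, 0.2)]
        assert sizes == sorted(sizes, reverse=True)

    def test_infinite_population_limit(self):
        z = scipy.stats.norm.ppf(0.975)
        n0 = round(z * z * 0.25 / 0.08**2)
        assert cochran_sample_size(None, 0.95, 0.08) == n0
        assert cochran_sample_size(10**9, 0.95, 0.08) in (n0, n0 - 1)

    @pytest.mark.parametrize("conf,margin", [(0.0, 0.08), (1.0, 0.08),
                                             (0.95, 0.0), (0.95, 1.0)])
    def test_invalid_fractions(self, conf, margin):
        with pytest.raises(ValueError):
            cochran_sample_size(1000, conf, margin)


def test_attrition_arithmetic():
    assert attrition(152, [7, 1, 1]) == 143
    with pytest.raises(ValueError):
        attrition(5, [7])


class TestProportion:
    @pytest.mark.parametrize(
        "k,n,expected",
        [(55, 137, "55/137, 40.1%"), (7, 152, "7/152, 4.6%"),
         (0, 10, "0/10, 0.0%"), (10, 10, "10/10, 100.0%")],
    )
    def test_formatting(self, k, n, expected):
        assert proportion_summary(k, n) == expected

    def test_invalid(self):
        with pytest.raises(ValueError):
            proportion_summary(1, 0)
        with pytest.raises(ValueError):
            proportion_summary(5, 4)
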