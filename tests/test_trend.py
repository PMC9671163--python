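"""Trend inference: paired test, profiled-ML mixed model, LRT, contrasts."""

import numpy as np
import pandas as pd
import pytest

from duetflow.trend import (
    fit_random_intercept_ml,
    linear_trend_contrast,
    lrt_fixed_effect,
    paired_direction_test,
    semipartial_r2,
    trial_trend,
)

from conftest import make_mixed_table


class TestPairedDirectionTest:
    def test_closed_form_small_sample(self):
        # differences [1,2,3]: t = mean/(sd/sqrt(n)) = 2/(1/sqrt(3))
        res = paired_direction_test([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert res.t_stat == pytest.approx(2 * np.sqrt(3), abs=1e-4)
        assert res.df == 2

    def test_df_convention_8x8(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.1, 0.02, 64)
        b = rng.normal(0.05, 0.02, 64)
        assert paired_direction_test(a, b).df == 63

    def test_identical_pairs_raise(self):
        with pytest.raises(ValueError, match="zero variance"):
            paired_direction_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_location_invariance(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=30)
        b = rng.normal(size=30)
        r1 = paired_direction_test(a, b)
        r2 = paired_direction_test(a + 5.0, b + 5.0)
        assert r1.t_stat == pytest.approx(r2.t_stat)


class TestMixedModel:
    def test_collapses_to_ols_without_participant_variance(self):
        table = make_mixed_table(beta=-0.004, sigma_participant=0.0, sigma_resid=0.01, seed=3)
        full, _ = fit_random_intercept_ml(table)
        slope_ols = np.polyfit(table["trial"], table["value"], 1)[0]
        assert full.slope == pytest.approx(slope_ols, abs=1e-6)

    def test_matches_statsmodels_ml(self):
        statsmodels = pytest.importorskip("statsmodels.regression.mixed_linear_model")
        table = make_mixed_table(beta=-0.005, sigma_participant=0.02, sigma_resid=0.01, seed=4)
        full, _ = fit_random_intercept_ml(table)
        y = table["value"].to_numpy()
        x = np.column_stack([np.ones(len(table)), table["trial"].to_numpy()])
        sm_fit = statsmodels.MixedLM(y, x, groups=table["participant"].to_numpy()).fit(reml=False)
        assert full.beta == pytest.approx(sm_fit.fe_params, abs=1e-5)
        assert full.loglik == pytest.approx(sm_fit.llf, abs=1e-4)
        assert full.sigma_resid2 == pytest.approx(sm_fit.scale, rel=1e-2)

    def test_full_likelihood_dominates_reduced(self):
        for seed in range(5):
            table = make_mixed_table(beta=0.002, sigma_participant=0.02, sigma_resid=0.01, seed=seed)
            full, reduced = fit_random_intercept_ml(table)
            assert full.loglik >= reduced.loglik - 1e-8

    def test_parameter_recovery_mean_slope(self):
        slopes = [
            fit_random_intercept_ml(
                make_mixed_table(beta=-0.005, sigma_participant=0.02, sigma_resid=0.01, seed=s)
            )[0].slope
            for s in range(100)
        ]
        assert np.mean(slopes) == pytest.approx(-0.005, rel=0.10)

    def test_degenerate_designs_raise(self):
        one_part = make_mixed_table(0.0, 0.01, 0.01).query("participant == 0")
        with pytest.raises(ValueError):
            fit_random_intercept_ml(one_part)


class TestLrtAndR2:
    def test_null_data_gives_valid_small_statistic(self):
        table = make_mixed_table(beta=0.0, sigma_participant=0.02, sigma_resid=0.01, seed=6)
        full, reduced = fit_random_intercept_ml(table)
        stat, p = lrt_fixed_effect(full, reduced)
        assert stat >= 0.0 and 0.0 <= p <= 1.0

    def test_non_nested_inputs_raise(self):
        table = make_mixed_table(beta=0.0, sigma_participant=0.02, sigma_resid=0.01, seed=6)
        full, reduced = fit_random_intercept_ml(table)
        with pytest.raises(ValueError):
            lrt_fixed_effect(reduced, full)

    def test_statistic_monotone_in_effect_size(self):
        means = []
        for beta in (0.0, 0.002, 0.005):
            stats_ = []
            for seed in range(30):
                table = make_mixed_table(beta=beta, sigma_participant=0.02, sigma_resid=0.01, seed=seed)
                full, reduced = fit_random_intercept_ml(table)
                stats_.append(lrt_fixed_effect(full, reduced)[0])
            means.append(np.mean(stats_))
        assert means[0] < means[1] < means[2]

    def test_wald_equivalence_order_of_magnitude(self):
        # LRT ~ (beta / se)^2 asymptotically; at n = 64 the two agree to
        # ~15% for moderate effects (they diverge by construction for huge
        # effects, where LRT ~ n ln(1 + W/n) < W)
        table = make_mixed_table(beta=-0.0015, sigma_participant=0.02, sigma_resid=0.01, seed=7)
        full, reduced = fit_random_intercept_ml(table)
        stat, _ = lrt_fixed_effect(full, reduced)
        trials = np.tile(np.arange(1, 9), 8).astype(float)
        se2 = full.sigma_resid2 / np.sum((trials - trials.mean()) ** 2)
        wald = full.slope**2 / se2
        assert stat == pytest.approx(wald, rel=0.15)

    def test_semipartial_zero_when_slope_is_zero(self):
        # participant offsets only: the fitted slope is exactly zero
        part = np.repeat(np.arange(8), 8)
        trial = np.tile(np.arange(1, 9), 8).astype(float)
        offsets = np.linspace(0.1, 0.8, 8)
        table = pd.DataFrame({"participant": part, "trial": trial, "value": offsets[part]})
        full, reduced = fit_random_intercept_ml(table)
        assert abs(full.slope) < 1e-10
        assert semipartial_r2(full, reduced) == pytest.approx(0.0, abs=1e-6)

    def test_semipartial_near_one_for_noise_free_trend(self):
        table = make_mixed_table(beta=-0.01, sigma_participant=0.05, sigma_resid=1e-8, seed=9)
        full, reduced = fit_random_intercept_ml(table)
        assert semipartial_r2(full, reduced) > 0.99

    def test_semipartial_monotone_in_effect(self):
        r2 = []
        for beta in (0.0, 0.003, 0.01):
            vals = [
                semipartial_r2(
                    *fit_random_intercept_ml(
                        make_mixed_table(beta=beta, sigma_participant=0.02, sigma_resid=0.01, seed=s)
                    )
                )
                for s in range(20)
            ]
            r2.append(np.mean(vals))
        assert r2[0] < r2[1] < r2[2]


class TestLinearTrendContrast:
    def test_df_convention_8x8(self):
        table = make_mixed_table(beta=-0.005, sigma_participant=0.02, sigma_resid=0.01, seed=10)
        res = linear_trend_contrast(table)
        assert (res.df_num, res.df_den) == (1, 56)

    def test_noise_free_linear_trend_significant(self):
        part = np.repeat(np.arange(8), 8)
        trial = np.tile(np.arange(1, 9), 8).astype(float)
        offsets = np.linspace(0.0, 0.7, 8)
        table = pd.DataFrame(
            {"participant": part, "trial": trial, "value": offsets[part] + 0.01 * trial}
        )
        res = linear_trend_contrast(table)
        assert res.p_value < 1e-6

    def test_flat_means_give_zero_f(self):
        part = np.repeat(np.arange(8), 8)
        trial = np.tile(np.arange(1, 9), 8).astype(float)
        offsets = np.linspace(0.0, 0.7, 8)
        table = pd.DataFrame({"participant": part, "trial": trial, "value": offsets[part]})
        res = linear_trend_contrast(table)
        assert res.F_stat == pytest.approx(0.0, abs=1e-9)

    def test_incomplete_design_raises(self):
        table = make_mixed_table(beta=0.0, sigma_participant=0.02, sigma_resid=0.01)
        with pytest.raises(ValueError, match="incomplete"):
            linear_trend_contrast(table.iloc[:-1])

    def test_scale_and_location_invariance(self):
        table = make_mixed_table(beta=0.004, sigma_participant=0.02, sigma_resid=0.01, seed=11)
        res1 = linear_trend_contrast(table)
        shifted = table.assign(value=3.0 * table["value"] + 10.0)
        res2 = linear_trend_contrast(shifted)
        assert res1.F_stat == pytest.approx(res2.F_stat, rel=1e-9)


def test_trial_trend_summary_consistency():
    table = make_mixed_table(beta=-0.005, sigma_participant=0.02, sigma_resid=0.01, seed=12)
    fit = trial_trend(table)
    assert fit.slope < 0
    assert 0.0 <= fit.r2_semipartial <= 1.0
    assert fit.lrt_stat >= 0.0 and 0.0 <= fit.p_value <= 1.0
    assert fit.sigma_participant2 >= 0.0 and fit.sigma_resid2 > 0.0
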