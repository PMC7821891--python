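"""Unit, oracle and Monte-Carlo tests for the harmonic seasonality module."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from dietseason.seasonality import (
    HarmonicFit,
    HarmonicSeasonality,
    amplitude_peak,
    fit_harmonic,
    fit_monthly_indicator,
    intensity,
    seasonality_table,
    summarize,
)
from dietseason.synthetic import ItemTruth, ScenarioConfig, generate_price_panel

from oracles import circular_month_distance, peak_grid_argmax


def make_fit(beta_s, beta_c, cov=None, scale="log"):
    cov = np.zeros((2, 2)) if cov is None else np.asarray(cov, dtype=float)
    return HarmonicFit(
        beta0=0.0, beta_s=beta_s, beta_c=beta_c, cov=cov, scale=scale,
        n_obs=60, estimator="ols",
    )


class TestHarmonicFit:
    def test_noiseless_exact_recovery(self, make_harmonic_series):
        df = make_harmonic_series(beta0=1.0, beta_s=0.03, beta_c=0.04)
        fit = fit_harmonic(df, scale="log")
        assert fit.beta_s == pytest.approx(0.03, abs=1e-12)
        assert fit.beta_c == pytest.approx(0.04, abs=1e-12)
        assert fit.estimator == "ols"

    def test_linear_trend_absorbed(self, make_harmonic_series):
        base = make_harmonic_series(beta_s=0.03, beta_c=0.04, trend=0.0)
        trended = make_harmonic_series(beta_s=0.03, beta_c=0.04, trend=0.01)
        f0, f1 = fit_harmonic(base), fit_harmonic(trended)
        assert f1.beta_s == pytest.approx(f0.beta_s, abs=1e-10)
        assert f1.beta_c == pytest.approx(f0.beta_c, abs=1e-10)

    def test_price_scale_invariance(self, make_harmonic_series):
        df = make_harmonic_series(beta_s=0.05, beta_c=-0.02, noise_sd=0.03, seed=4)
        df_scaled = df.assign(value=df["value"] * 1000.0)
        m1 = HarmonicSeasonality().fit(df)
        m2 = HarmonicSeasonality().fit(df_scaled)
        assert m2.amplitude_ == pytest.approx(m1.amplitude_, rel=1e-9)
        assert m2.peak_month_ == pytest.approx(m1.peak_month_, rel=1e-9)
        assert m2.intensity_ == pytest.approx(m1.intensity_, rel=1e-9)

    def test_too_few_observations(self, make_harmonic_series):
        with pytest.raises(ValueError, match="24"):
            fit_harmonic(make_harmonic_series(n_months=18))

    def test_mixed_equals_pooled_ols_without_heterogeneity(self):
        cfg = ScenarioConfig(
            items=[ItemTruth("x", "starchy staples", 5.0, amplitude=0.05,
                             peak_month=3.0)],
            n_markets=20, sigma_eps=0.05, seed=11,
        )
        d = generate_price_panel(cfg).panel.data.rename(
            columns={"price_lcu_per_kg": "value"}
        )
        mixed = fit_harmonic(d, estimator="mixed")
        pooled = fit_harmonic(d, estimator="ols")
        assert mixed.estimator == "mixed"
        assert mixed.beta_s == pytest.approx(pooled.beta_s, abs=1e-4)
        assert mixed.beta_c == pytest.approx(pooled.beta_c, abs=1e-4)


class TestAmplitudePeak:
    def test_three_four_five_amplitude(self):
        amp, _, _, _ = amplitude_peak(make_fit(0.03, 0.04))
        assert amp == pytest.approx(0.05, abs=1e-15)

    def test_variance_collapses_for_equal_sd_zero_covariance(self):
        cov = np.diag([1e-4, 1e-4])
        _, var_a, _, _ = amplitude_peak(make_fit(0.07, -0.19, cov))
        assert var_a == pytest.approx(1e-4, rel=1e-12)

    def test_peak_at_cosine_origin_is_december(self):
        _, _, peak, _ = amplitude_peak(make_fit(0.0, 1.0))
        assert peak == 12.0
        assert circular_month_distance(peak, peak_grid_argmax(0.0, 1.0)) < 1e-3

    def test_zero_coefficients_flag_undefined_peak(self):
        amp, _, peak, var_p = amplitude_peak(make_fit(0.0, 0.0))
        assert amp == 0.0 and peak is None and var_p is None

    @given(
        st.floats(min_value=-1.0, max_value=1.0),
        st.floats(min_value=-1.0, max_value=1.0),
    )
    def test_closed_form_peak_equals_grid_argmax(self, beta_s, beta_c):
        if beta_s**2 + beta_c**2 < 1e-4:
            return
        _, _, peak, _ = amplitude_peak(make_fit(beta_s, beta_c))
        assert circular_month_distance(peak, peak_grid_argmax(beta_s, beta_c)) < 1e-3

    def test_generator_phase_convention_round_trip(self):
        # bs = A sin(2 pi P/12), bc = A cos(2 pi P/12) must invert to (A, P)
        for p_star in (0.5, 3.0, 6.0, 9.25, 12.0):
            it = ItemTruth("x", "sweets", 1.0, amplitude=0.08, peak_month=p_star)
            amp, _, peak, _ = amplitude_peak(make_fit(it.beta_s, it.beta_c))
            assert amp == pytest.approx(0.08, rel=1e-12)
            assert circular_month_distance(peak, p_star) < 1e-9


class TestIntensity:
    def test_zero_amplitude_zero_intensity(self):
        val, _ = intensity(0.0, 0.0, "log")
        assert val == 0.0

    def test_half_log_two_doubles_prices(self):
        val, _ = intensity(np.log(2.0) / 2.0, 0.0, "log")
        assert val == pytest.approx(100.0, rel=1e-12)

    def test_five_percent_amplitude(self):
        val, _ = intensity(0.05, 0.0, "log")
        assert val == pytest.approx(10.517, abs=5e-4)

    def test_level_scale_is_twice_amplitude(self):
        val, ci = intensity(7.5, 1.0, "level")
        assert val == 15.0
        assert ci == (2 * (7.5 - 1.96), 2 * (7.5 + 1.96))

    def test_ci_transform_monotone(self):
        _, (lo, hi) = intensity(0.05, 1e-4, "log")
        assert lo < 10.517 < hi

    def test_intensity_equals_peak_over_nadir_excess(self, make_harmonic_series):
        # multiplicative seasonal component: peak/nadir - 1 = exp(2A) - 1
        m = HarmonicSeasonality().fit(
            make_harmonic_series(beta_s=0.06, beta_c=0.02)
        )
        months = np.linspace(0, 12, 14401)
        comp = np.exp(m.predict_seasonal(months))
        assert m.intensity_ / 100.0 == pytest.approx(
            comp.max() / comp.min() - 1.0, rel=1e-6
        )

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            intensity(0.05, -1.0, "log")


class TestDeltaMethodVariances:
    def test_match_monte_carlo_at_small_sigma(self):
        rng = np.random.default_rng(12)
        beta = np.array([0.03, 0.04])
        cov = np.array([[1e-6, 3e-7], [3e-7, 1.5e-6]])
        draws = rng.multivariate_normal(beta, cov, size=200_000)
        amp = np.hypot(draws[:, 0], draws[:, 1])
        phi = -np.arctan(draws[:, 0] / draws[:, 1])
        fit = make_fit(*beta, cov)
        _, var_a, _, var_p = amplitude_peak(fit)
        var_phi = var_p / (12.0 / (2 * np.pi)) ** 2
        assert amp.var() == pytest.approx(var_a, rel=0.10)
        assert phi.var() == pytest.approx(var_phi, rel=0.10)

    def test_analytic_sign_beats_published_sign(self):
        # the Monte-Carlo variance of phi adjudicates the cross-term sign
        rng = np.random.default_rng(13)
        beta = np.array([0.03, 0.04])
        cov = np.array([[1e-6, 4e-7], [4e-7, 1e-6]])
        draws = rng.multivariate_normal(beta, cov, size=200_000)
        phi_var = (-np.arctan(draws[:, 0] / draws[:, 1])).var()
        fit = make_fit(*beta, cov)
        scale = (12.0 / (2 * np.pi)) ** 2
        minus = amplitude_peak(fit)[3] / scale
        plus = amplitude_peak(fit, published_phase_var=True)[3] / scale
        assert abs(minus - phi_var) < abs(plus - phi_var)


class TestMonthlyIndicator:
    def test_base_month_coefficient_zero(self, make_harmonic_series):
        m = fit_monthly_indicator(make_harmonic_series(noise_sd=0.05, seed=3))
        assert m.month_effects_.loc[11] == 0.0

    def test_flat_series_all_zero(self):
        df = pd.DataFrame(
            {
                "year": 2011 + (np.arange(60)) // 12,
                "month": (np.arange(60)) % 12 + 1,
                "value": 100.0,
            }
        )
        m = fit_monthly_indicator(df)
        assert np.allclose(m.month_effects_, 0.0, atol=1e-12)

    def test_noiseless_harmonic_reproduced_at_month_midpoints(
        self, make_harmonic_series
    ):
        bs, bc = 0.03, 0.04
        df = make_harmonic_series(beta0=1.0, beta_s=bs, beta_c=bc)
        m = fit_monthly_indicator(df, scale="log")
        months = np.arange(1, 13)
        harmonic = bs * np.sin(2 * np.pi * months / 12) + bc * np.cos(
            2 * np.pi * months / 12
        )
        fitted = m.fitted_monthly_means().to_numpy()
        assert np.allclose(fitted, 1.0 + harmonic, atol=1e-10)
        h = HarmonicSeasonality().fit(df)
        assert circular_month_distance(h.peak_month_, m.peak_month_) <= 0.5

    def test_missing_calendar_month_errors(self, make_harmonic_series):
        df = make_harmonic_series(n_months=60)
        with pytest.raises(ValueError, match="missing"):
            fit_monthly_indicator(df[df["month"] != 7])


class TestSeasonalityTable:
    def test_row_accounting_and_statuses(self):
        frames = []
        rng = np.random.default_rng(21)
        for key in [f"item_{i}" for i in range(5)]:
            t = np.arange(1, 61)
            frames.append(
                pd.DataFrame(
                    {
                        "key": key,
                        "year": 2011 + (t - 1) // 12,
                        "month": (t - 1) % 12 + 1,
                        "value": np.exp(rng.normal(5.0, 0.1, 60)),
                    }
                )
            )
        # one series too short to fit: must carry a status, not vanish
        frames.append(
            pd.DataFrame(
                {"key": "short", "year": 2011, "month": range(1, 13), "value": 10.0}
            )
        )
        table = seasonality_table(pd.concat(frames), by="key")
        assert len(table) == 6
        assert (table.loc[table["key"] == "short", "status"] != "ok").all()
        assert (table.loc[table["key"] != "short", "status"] == "ok").all()

    def test_null_false_positive_rate_matches_rayleigh_theory(self):
        # With A* = 0 the amplitude CI test is a 2-dof chi-square check:
        # P(A > 1.96 SE) = exp(-1.96^2/2) ~ 14.6%, not the nominal 5%.
        rng = np.random.default_rng(22)
        t = np.arange(1, 61)
        hits = 0
        reps = 400
        for _ in range(reps):
            df = pd.DataFrame(
                {
                    "year": 2011 + (t - 1) // 12,
                    "month": (t - 1) % 12 + 1,
                    "value": np.exp(rng.normal(3.0, 0.05, t.size)),
                }
            )
            hits += HarmonicSeasonality().fit(df).significant_
        rate = hits / reps
        expected = np.exp(-(1.96**2) / 2.0)
        # 3 binomial SEs around the theoretical rate
        se = np.sqrt(expected * (1 - expected) / reps)
        assert abs(rate - expected) < 3 * se + 0.01

    def test_inverse_variance_pooling_consistent_with_national_fit(self):
        cfg = ScenarioConfig(
            items=[ItemTruth("x", "starchy staples", 5.0, amplitude=0.06,
                             peak_month=4.0)],
            n_markets=6, sigma_eps=0.05, seed=23,
        )
        d = generate_price_panel(cfg).panel.data.rename(
            columns={"price_lcu_per_kg": "value"}
        )
        national = fit_harmonic(d, estimator="ols")
        num = den = 0.0
        for _, grp in d.groupby("market"):
            f = fit_harmonic(grp, estimator="ols")
            w = 1.0 / f.cov[0, 0]
            num += w * f.beta_s
            den += w
        pooled_bs = num / den
        assert pooled_bs == pytest.approx(
            national.beta_s, abs=3 * np.sqrt(national.cov[0, 0])
        )


class TestEndToEndRecovery:
    def test_noiseless_panel_recovers_truth_exactly(self):
        cfg = ScenarioConfig(
            items=[ItemTruth("x", "sweets", 2.0, amplitude=0.05, peak_month=3.0)],
            n_markets=1, sigma_eps=0.0, seed=0,
        )
        d = generate_price_panel(cfg).panel.data.rename(
            columns={"price_lcu_per_kg": "value"}
        )
        m = HarmonicSeasonality().fit(d)
        assert m.amplitude_ == pytest.approx(0.05, abs=1e-10)
        assert m.peak_month_ == pytest.approx(3.0, abs=1e-9)

    def test_estimated_amplitude_unbiased_over_replicates(self):
        # mean of estimated A over noisy multi-market replicates within
        # 3 MC SEs of A* (amplitude has a small Rice-type finite-sample
        # bias of order Var(beta)/A, negligible at the 20-market size)
        a_star, estimates = 0.05, []
        for rep in range(60):
            cfg = ScenarioConfig(
                items=[ItemTruth("x", "sweets", 2.0, amplitude=a_star,
                                 peak_month=3.0)],
                n_markets=20, sigma_eps=0.05, seed=1000 + rep,
            )
            d = generate_price_panel(cfg).panel.data.rename(
                columns={"price_lcu_per_kg": "value"}
            )
            estimates.append(
                HarmonicSeasonality(estimator="ols").fit(d).amplitude_
            )
        estimates = np.asarray(estimates)
        mc_se = estimates.std(ddof=1) / np.sqrt(len(estimates))
        assert abs(estimates.mean() - a_star) < 3 * mc_se + 1e-4
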