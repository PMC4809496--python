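"""Robust trend fitting, season-trend models and break detection."""

import numpy as np
import pytest

import forestchange as fc
from forestchange.core import IrregularTimeSeries
from forestchange.synthetic_data import TrajectoryParams
from forestchange.temporal_metrics import detect_single_break


def _line(times, intercept=2.0, slope=0.5):
    return intercept + slope * (times - fc.BASELINE_YEAR)


class TestRlmTrend:
    def test_noiseless_line_recovered_exactly(self):
        t = np.linspace(2000, 2010, 50)
        ts = IrregularTimeSeries(t, _line(t))
        intercept, slope = fc.fit_rlm_trend(ts)
        assert intercept == pytest.approx(2.0, abs=1e-9)
        assert slope == pytest.approx(0.5, abs=1e-9)

    def test_constant_series_has_zero_slope(self):
        t = np.linspace(2000, 2010, 30)
        ts = IrregularTimeSeries(t, np.full(30, 0.7))
        _, slope = fc.fit_rlm_trend(ts)
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_resists_one_sided_outliers_better_than_ols(self):
        """10% of points shifted by -0.5 barely move the robust slope."""
        slope_true = 0.01
        rlm_dev, ols_dev = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            t = np.sort(rng.uniform(2000, 2014, 200))
            y = _line(t, 0.3, slope_true) + rng.normal(0, 0.02, t.size)
            y[rng.random(t.size) < 0.10] -= 0.5
            ts = IrregularTimeSeries(t, y)
            _, slope = fc.fit_rlm_trend(ts)
            ols_slope = np.polyfit(t - fc.BASELINE_YEAR, y, 1)[0]
            rlm_dev.append(abs(slope - slope_true))
            ols_dev.append(abs(ols_slope - slope_true))
        assert np.mean(rlm_dev) < 0.002
        assert np.mean(rlm_dev) < 0.5 * np.mean(ols_dev)

    def test_too_few_observations_rejected(self):
        ts = IrregularTimeSeries([2000.0, 2001.0, 2002.0], [1, 2, 3])
        with pytest.raises(fc.InsufficientDataError):
            fc.fit_rlm_trend(ts)


class TestSeasonTrend:
    def test_noiseless_parameters_recovered(self, clean_sampling):
        params = fc.stable_params(1.0, 0.2, 0.3, 0.5)
        ts = fc.generate_timeseries(params, clean_sampling)
        fit = fc.fit_season_trend(ts)
        assert fit.alpha == pytest.approx(1.0, abs=1e-6)
        assert fit.beta == pytest.approx(0.2, abs=1e-6)
        assert fit.gamma == pytest.approx(0.3, abs=1e-6)
        assert fit.delta == pytest.approx(0.5, abs=1e-6)

    def test_pure_line_has_negligible_amplitude(self):
        t = np.sort(np.random.default_rng(1).uniform(2000, 2012, 150))
        ts = IrregularTimeSeries(t, _line(t))
        fit = fc.fit_season_trend(ts)
        assert fit.gamma <= 1e-9

    def test_gamma_always_non_negative(self, noisy_sampling):
        for delta in (-2.0, 0.0, 2.5):
            params = fc.stable_params(0.3, 0.0, 0.05, delta)
            ts = fc.generate_timeseries(params, noisy_sampling)
            assert fc.fit_season_trend(ts).gamma >= 0

    def test_short_window_rejected(self):
        t = np.linspace(2000.0, 2000.8, 20)
        ts = IrregularTimeSeries(t, np.sin(2 * np.pi * t))
        with pytest.raises(fc.SeasonalUnidentifiableError):
            fc.fit_season_trend(ts)

    def test_robust_equals_ols_on_noiseless_data(self, clean_sampling):
        params = fc.stable_params(0.4, -0.01, 0.08, 1.2)
        ts = fc.generate_timeseries(params, clean_sampling)
        fit = fc.fit_season_trend(ts)
        w = 2 * np.pi * ts.times
        X = np.column_stack(
            [np.ones(len(ts)), ts.times - fc.BASELINE_YEAR, np.sin(w), np.cos(w)]
        )
        ols = np.linalg.lstsq(X, ts.values, rcond=None)[0]
        assert fit.alpha == pytest.approx(ols[0], abs=1e-8)
        assert fit.beta == pytest.approx(ols[1], abs=1e-8)

    def test_noisy_amplitude_recovery_rate(self):
        """|gamma_hat - gamma| <= 0.03 in >= 95% of 50 noisy replicates."""
        gamma = 0.1
        ok = 0
        for seed in range(50):
            params = fc.stable_params(0.3, 0.005, gamma, 0.7)
            sampling = fc.SamplingModel(
                noise_sd=0.02, outlier_prob=0.05, outlier_shift=-0.1,
                dropout_prob=0.0, mean_revisit=23.4, seed=seed,
            )
            ts = fc.generate_timeseries(params, sampling)
            fit = fc.fit_season_trend(ts)
            ok += abs(fit.gamma - gamma) <= 0.03
        assert ok >= 48

    def test_corruption_robustness_bound(self):
        """<=10% corruption moves the slope < 3x the uncorrupted change."""
        params = fc.stable_params(0.3, 0.01, 0.05, 0.4)
        base_dev, corr_dev = [], []
        for seed in range(10):
            sampling = fc.SamplingModel(
                noise_sd=0.01, outlier_prob=0.0, dropout_prob=0.0, seed=seed
            )
            ts = fc.generate_timeseries(params, sampling)
            fit = fc.fit_season_trend(ts)
            base_dev.append(abs(fit.beta - 0.01))
            rng = np.random.default_rng(seed + 100)
            y = ts.values.copy()
            y[rng.random(len(ts)) < 0.10] -= 0.3
            corr = fc.fit_season_trend(IrregularTimeSeries(ts.times, y))
            corr_dev.append(abs(corr.beta - 0.01))
        assert np.mean(corr_dev) < 3 * max(np.mean(base_dev), 1e-4)


class TestBreakDetection:
    @staticmethod
    def _break_params(drop, break_time=2007.0):
        return TrajectoryParams(
            alpha1=0.3, beta1=0.0, gamma1=0.02, delta1=0.7,
            alpha2=0.3 - drop, beta2=0.0, gamma2=0.02, delta2=0.7,
            break_time=break_time, change_class="DEF",
        )

    def test_abrupt_drop_located_within_five_observations(self, noisy_sampling):
        hits = 0
        for seed in range(25):
            sampling = fc.SamplingModel(
                noise_sd=0.02, outlier_prob=0.05, outlier_shift=-0.1,
                dropout_prob=0.0, mean_revisit=19.5, seed=seed,
            )
            ts = fc.generate_timeseries(self._break_params(0.1), sampling)
            result = fc.detect_single_break(ts)
            if result.has_break:
                true_idx = int(np.searchsorted(ts.times, 2007.0))
                hits += abs(result.break_index - true_idx) <= 5
        assert hits >= 23

    def test_stationary_series_rarely_flags_break(self):
        false_pos = 0
        for seed in range(25):
            params = fc.stable_params(0.3, 0.0, 0.02, 0.7)
            sampling = fc.SamplingModel(
                noise_sd=0.02, outlier_prob=0.05, outlier_shift=-0.1,
                dropout_prob=0.0, mean_revisit=19.5, seed=seed,
            )
            ts = fc.generate_timeseries(params, sampling)
            false_pos += fc.detect_single_break(ts).has_break
        assert false_pos <= 3

    def test_break_flag_consistent_with_bic(self, noisy_sampling):
        ts = fc.generate_timeseries(self._break_params(0.1), noisy_sampling)
        result = fc.detect_single_break(ts)
        assert result.has_break == (result.bic1 < result.bic0)
        assert result.break_time is not None

    def test_short_series_degenerate_no_break(self):
        t = np.linspace(2000, 2005, 10)
        ts = IrregularTimeSeries(t, np.sin(2 * np.pi * t))
        result = fc.detect_single_break(ts)
        assert not result.has_break
        assert result.degenerate
        assert result.bic1 is None

    def test_break_time_lies_between_flanking_observations(self, noisy_sampling):
        ts = fc.generate_timeseries(self._break_params(0.15), noisy_sampling)
        result = fc.detect_single_break(ts)
        assert result.has_break
        i = result.break_index
        assert ts.times[i - 1] < result.break_time < ts.times[i]


class TestExtractMetrics:
    def test_no_break_duplicates_segment_parameters(self, noisy_sampling):
        params = fc.stable_params(0.3, 0.0, 0.05, 0.4)
        ts = fc.generate_timeseries(params, noisy_sampling)
        mv = fc.extract_metrics({"NIR": ts})
        m = mv.metrics["NIR"]
        assert m["gamma2"] == m["gamma1"]
        assert m["beta2"] == m["beta1"]

    def test_fourteen_bands_give_84_metrics(self, clean_sampling):
        params = fc.stable_params(0.3, 0.0, 0.05, 0.4)
        series = {
            band: fc.generate_timeseries(params, clean_sampling, band=band)
            for band in fc.ALL_BANDS
        }
        mv = fc.extract_metrics(series)
        assert len(mv) == 84
        assert len(mv.to_series()) == 84

    def test_deforestation_trajectory_separates_segments(self, noisy_sampling):
        params = TrajectoryParams(
            alpha1=0.35, beta1=0.0, gamma1=0.03, delta1=0.2,
            alpha2=0.25, beta2=0.0, gamma2=0.015, delta2=0.2,
            break_time=2007.0, change_class="DEF",
        )
        ts = fc.generate_timeseries(params, noisy_sampling)
        mv = fc.extract_metrics({"NIR": ts})
        m = mv.metrics["NIR"]
        assert m["gamma2"] != m["gamma1"]
        # overall robust trend reflects the level drop
        assert m["rlm_slope"] < 0

    def test_empty_series_reported_as_missing(self, noisy_sampling):
        params = fc.stable_params(0.3, 0.0, 0.05, 0.4)
        good = fc.generate_timeseries(params, noisy_sampling)
        empty = IrregularTimeSeries([], [], band="G")
        mv = fc.extract_metrics({"NIR": good, "G": empty})
        assert mv.missing_bands == ["G"]
        assert np.isnan(mv.metrics["G"]["gamma1"])
        assert np.isfinite(mv.metrics["NIR"]["gamma1"])
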