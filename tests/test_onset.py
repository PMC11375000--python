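"""Rate-of-change, accumulation rates, Mann-Kendall, back-extrapolation."""

import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from icebloom.config import ScenarioConfig
from icebloom.onset import (ChlSeries, accumulation_rate, chl_par_regression,
                            detect_onset_roc, exp_backextrapolate_doubling,
                            mann_kendall, rate_of_change, summarize_rates)
from icebloom import synthetic as syn

D0 = dt.date(2020, 3, 1)


def series_from(values, start=D0, step=1, source="underway"):
    dates = tuple(start + dt.timedelta(days=step * i) for i in range(len(values)))
    return ChlSeries(dates=dates, concentrations=tuple(float(v) for v in values))


class TestRateOfChange:
    def test_linear_series_recovers_slope_everywhere(self):
        slopes = rate_of_change(series_from(0.02 + 0.001 * np.arange(20)))
        assert np.allclose(slopes.values, 0.001, atol=1e-12)

    def test_constant_series_has_zero_slopes(self):
        slopes = rate_of_change(series_from([0.015] * 15))
        assert np.allclose(slopes.values, 0.0, atol=1e-15)

    def test_noiseless_onset_splits_signs(self):
        sc = ScenarioConfig(sigma_log=0.0, chl_replicates=1, seed=0)
        chl = syn.gen_chl_series(dt.date(2020, 3, 7), dt.date(2020, 4, 16), sc)
        slopes = rate_of_change(chl)
        pre = slopes[[d <= sc.onset_day for d in slopes.index]]
        post = slopes[[d > sc.onset_day + dt.timedelta(days=5)
                       for d in slopes.index]]
        assert np.allclose(pre.values, 0.0, atol=1e-12)
        assert (post.values > 0).all()

    def test_windows_with_long_gaps_skipped(self):
        values = [0.02] * 20
        dates = [D0 + dt.timedelta(days=i) for i in range(20) if i not in (9, 10, 11)]
        s = ChlSeries(dates=tuple(dates), concentrations=tuple(values[:len(dates)]))
        slopes = rate_of_change(s)
        assert dt.date(2020, 3, 13) not in slopes.index  # 3-day hole inside window
        assert dt.date(2020, 3, 8) in slopes.index


class TestDetectOnsetRoc:
    def test_all_negative_slopes_yield_none(self):
        slopes = pd.Series([-0.01] * 10,
                           index=pd.Index([D0 + dt.timedelta(days=i)
                                           for i in range(10)]))
        assert detect_onset_roc(slopes) is None

    def test_run_of_four_days_is_not_an_onset(self):
        signs = [-1, 1, 1, 1, 1, -1, -1, -1, -1, -1]
        slopes = pd.Series([0.001 * s for s in signs],
                           index=pd.Index([D0 + dt.timedelta(days=i)
                                           for i in range(10)]))
        assert detect_onset_roc(slopes, run_days=5) is None
        assert detect_onset_roc(slopes, run_days=4) == D0 + dt.timedelta(days=1)

    def test_low_noise_scenario_detected_near_true_onset(self):
        sc = ScenarioConfig(seed=2, sigma_log=0.02,
                            start=dt.date(2020, 2, 26), end=dt.date(2020, 4, 25))
        chl = syn.gen_chl_series(sc.start, sc.end, sc)
        onset = detect_onset_roc(rate_of_change(chl))
        assert onset is not None
        assert 0 <= (onset - sc.onset_day).days <= 3


class TestAccumulationRate:
    def test_pure_exponential_gives_exact_constant(self):
        vals = 0.015 * np.exp(0.06 * np.arange(30))
        rates = accumulation_rate(series_from(vals), interval_days=7)
        assert np.allclose(rates.values, 0.06, atol=1e-12)

    def test_constant_series_gives_zero(self):
        rates = accumulation_rate(series_from([0.02] * 20))
        assert np.allclose(rates.values, 0.0, atol=1e-15)

    def test_missing_partner_days_skipped(self):
        dates = [D0 + dt.timedelta(days=i) for i in range(20) if i != 12]
        s = ChlSeries(dates=tuple(dates), concentrations=tuple([0.02] * 19))
        rates = accumulation_rate(s)
        assert D0 + dt.timedelta(days=5) not in rates.index
        assert D0 + dt.timedelta(days=4) in rates.index

    def test_pre_post_summary_brackets_the_split(self):
        sc = ScenarioConfig(sigma_log=0.0, chl_replicates=1)
        chl = syn.gen_chl_series(dt.date(2020, 2, 26), dt.date(2020, 4, 25), sc)
        rates = accumulation_rate(chl)
        summary = summarize_rates(rates, sc.onset_day)
        assert summary["pre"]["mean"] == pytest.approx(0.0, abs=1e-12)
        assert summary["post"]["mean"] == pytest.approx(0.06, abs=1e-12)
        assert summary["post"]["sd"] == pytest.approx(0.0, abs=1e-12)


class TestMannKendall:
    def test_monotone_series_saturate_s(self):
        assert mann_kendall([1, 2, 3, 4, 5]).s == 10
        assert mann_kendall([5, 4, 3, 2, 1]).s == -10

    def test_s_matches_brute_force_for_small_n(self):
        rng = np.random.default_rng(11)
        for trial in range(30):
            n = int(rng.integers(4, 13))
            x = rng.integers(0, 6, size=n).astype(float)  # ties likely
            s_brute = sum(np.sign(x[j] - x[i])
                          for i in range(n) for j in range(i + 1, n))
            assert mann_kendall(x).s == int(s_brute)

    def test_tau_matches_scipy_kendalltau(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=25)
        tau_scipy, _ = stats.kendalltau(np.arange(25), x)
        assert mann_kendall(x).tau == pytest.approx(float(tau_scipy), rel=1e-12)

    def test_all_tied_series_flagged(self):
        res = mann_kendall([2.0] * 6)
        assert res.all_tied and res.trend == "no trend"

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            mann_kendall([1.0, 2.0, 3.0])


class TestBackExtrapolation:
    def test_exact_exponential_doubles_on_schedule(self):
        rate = math.log(2) / 10
        vals = 0.5 * np.exp(rate * np.arange(40))
        res = exp_backextrapolate_doubling(series_from(vals))
        assert res.rate == pytest.approx(rate, rel=1e-10)
        assert res.t_doubling_days == pytest.approx(10.0, abs=1e-9)
        assert res.doubling_date == D0 + dt.timedelta(days=10)

    def test_flat_series_has_no_doubling(self):
        res = exp_backextrapolate_doubling(series_from([1.0] * 10))
        assert res.no_doubling and res.doubling_date is None

    def test_noisy_ice_core_series_recovers_doubling_window(self):
        # ~8x increase over six weeks, seeded measurement noise
        rng = np.random.default_rng(21)
        rate = math.log(8) / 42
        vals = 0.6 * np.exp(rate * np.arange(43)) * rng.lognormal(0, 0.1, 43)
        res = exp_backextrapolate_doubling(series_from(vals))
        assert res.r_squared > 0.8
        truth = math.log(2) / rate
        assert abs(res.t_doubling_days - truth) <= 3.0


class TestChlParRegression:
    def test_exact_exponential_in_par_gives_unit_r2(self):
        par = {D0 + dt.timedelta(days=i): 0.002 * (i + 1) for i in range(30)}
        chl = series_from([0.01 * math.exp(30 * par[D0 + dt.timedelta(days=i)])
                           for i in range(30)])
        out = chl_par_regression(chl, par, split=D0 + dt.timedelta(days=15))
        assert out["pre"]["r_squared"] == pytest.approx(1.0, abs=1e-10)
        assert out["post"]["r_squared"] == pytest.approx(1.0, abs=1e-10)

    def test_par_independent_baseline_has_near_zero_r2(self):
        rng = np.random.default_rng(8)
        par = {D0 + dt.timedelta(days=i): 0.001 * (i + 1) for i in range(40)}
        chl = series_from(0.015 * rng.lognormal(0, 0.1, 40))
        out = chl_par_regression(chl, par, split=D0 + dt.timedelta(days=40))
        assert out["pre"]["r_squared"] < 0.15

    def test_post_onset_coupling_detected(self, sixty_day_scenario):
        sc = sixty_day_scenario
        chl = syn.gen_chl_series(sc.start, sc.end, sc).daily_average()
        # PAR creeping up through late winter, ramping after the onset
        par = {d: (max(0.0, 0.002 * (d - sc.onset_day).days)
                   + 0.00002 * (d - sc.start).days + 0.001)
               for d in chl.dates}
        out = chl_par_regression(chl, par, split=sc.onset_day)
        assert out["post"]["r_squared"] > 0.5
        assert out["pre"]["r_squared"] < 0.3

    def test_excluded_dates_and_sparse_periods(self):
        par = {D0 + dt.timedelta(days=i): 0.001 * (i + 1) for i in range(10)}
        chl = series_from([0.02] * 10)
        out = chl_par_regression(chl, par, split=D0 + dt.timedelta(days=8),
                                 exclude_dates=[D0 + dt.timedelta(days=8),
                                                D0 + dt.timedelta(days=9)])
        assert "post" not in out  # < 3 matched points after exclusion
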