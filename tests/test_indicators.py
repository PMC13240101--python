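"""Climatology, pulse/press indicators, and autocorrelation diagnostics."""

import numpy as np
import pandas as pd
import pytest

import oxysqueeze as oz
from oxysqueeze.errors import InsufficientDataError
from oxysqueeze.indicators import day_of_year


def _vol_table(dates, values, range_name="r1", scenario="both"):
    return pd.DataFrame(
        {
            "date": pd.DatetimeIndex(dates),
            "range_name": range_name,
            "scenario": scenario,
            "volume_m3": values,
        }
    )


class TestDayOfYear:
    def test_leap_calendar_alignment(self):
        # same calendar date -> same day number in leap and non-leap years
        assert day_of_year(["2000-03-01"])[0] == day_of_year(["2001-03-01"])[0] == 61
        assert day_of_year(["2000-02-29"])[0] == 60
        assert day_of_year(["2000-12-31"])[0] == day_of_year(["2001-12-31"])[0] == 366


class TestClimatology:
    def test_duplicate_years_zero_sd(self):
        d1 = pd.date_range("2000-06-01", "2000-08-01")
        d2 = pd.date_range("2001-06-01", "2001-08-01")
        vals = np.arange(len(d1), dtype=float)
        clim = oz.seasonal_climatology(
            pd.concat([_vol_table(d1, vals), _vol_table(d2, vals)])
        )
        assert (clim["sd_m3"] == 0.0).all()
        assert (clim["n"] == 2).all()

    def test_two_point_mean_sd(self):
        d1 = pd.date_range("2000-06-01", "2000-06-10")
        d2 = pd.date_range("2001-06-01", "2001-06-10")
        clim = oz.seasonal_climatology(
            pd.concat([_vol_table(d1, 10.0), _vol_table(d2, 20.0)])
        )
        assert (clim["mean_m3"] == 15.0).all()
        assert clim["sd_m3"].unique() == pytest.approx(np.std([10, 20], ddof=1))

    def test_single_year_identity(self):
        d = pd.date_range("2000-01-01", "2000-12-31")
        vals = np.linspace(0, 1, len(d))
        clim = oz.seasonal_climatology(_vol_table(d, vals)).sort_values("doy")
        np.testing.assert_allclose(clim["mean_m3"], vals)
        assert (clim["sd_m3"] == 0.0).all()

    def test_permutation_invariant_over_years(self):
        rng = np.random.default_rng(0)
        tables = [
            _vol_table(pd.date_range(f"{y}-01-01", f"{y}-12-31"), rng.uniform(0, 1, 365 + (y == 2004)))
            for y in (2001, 2002, 2003)
        ]
        a = oz.seasonal_climatology(pd.concat(tables))
        b = oz.seasonal_climatology(pd.concat(tables[::-1]))
        pd.testing.assert_frame_equal(
            a.sort_values(["doy"]).reset_index(drop=True),
            b.sort_values(["doy"]).reset_index(drop=True),
        )

    def test_empty_input_empty_output(self):
        out = oz.seasonal_climatology(_vol_table([], []))
        assert len(out) == 0


class TestAnnualIndicators:
    def test_annual_min_direct(self):
        d = pd.date_range("2000-05-01", periods=3)
        v = _vol_table(d, [5.0, 3.0, 7.0])
        assert oz.annual_min(v, 2000, "r1") == 3.0

    def test_zero_floor(self):
        d = pd.date_range("2000-05-01", periods=10)
        vals = np.linspace(1, 10, 10)
        vals[4] = 0.0
        assert oz.annual_min(_vol_table(d, vals), 2000, "r1") == 0.0

    def test_rolling_constant_invariance(self):
        d = pd.date_range("2000-01-01", "2000-12-31")
        v = _vol_table(d, 4.2)
        for w in (1, 14, 30):
            assert oz.rolling_min_average(v, 2000, "r1", w) == pytest.approx(4.2)

    def test_rolling_hand_enumeration(self):
        d = pd.date_range("2000-03-01", periods=6)
        v = _vol_table(d, [1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        assert oz.rolling_min_average(v, 2000, "r1", 2) == 1.5

    def test_window_one_equals_annual_min(self):
        rng = np.random.default_rng(5)
        d = pd.date_range("2000-01-01", "2000-12-31")
        v = _vol_table(d, rng.uniform(0, 100, len(d)))
        assert oz.rolling_min_average(v, 2000, "r1", 1) == oz.annual_min(v, 2000, "r1")

    def test_rolling_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(6)
        d = pd.date_range("2001-01-01", "2001-12-31")
        vals = rng.uniform(0, 100, len(d))
        v = _vol_table(d, vals)
        for w in (14, 30):
            oracle = min(
                np.mean(vals[i : i + w]) for i in range(len(vals) - w + 1)
            )
            assert oz.rolling_min_average(v, 2001, "r1", w) == pytest.approx(oracle)

    def test_windows_spanning_gaps_excluded(self):
        d = pd.date_range("2000-01-01", "2000-12-31")
        vals = np.full(len(d), 10.0)
        vals[100:160] = 1.0
        v = _vol_table(d, vals)
        # remove days inside the low period: complete 30-day windows wholly
        # within it disappear, raising the achievable minimum
        keep = np.ones(len(d), bool)
        keep[110:150] = False
        v_gap = _vol_table(d[keep], vals[keep])
        assert oz.rolling_min_average(v, 2000, "r1", 30) == 1.0
        assert oz.rolling_min_average(v_gap, 2000, "r1", 30) > 1.0

    def test_pulse_below_press(self, short_sim):
        ind = oz.annual_indicators(short_sim["volumes"])
        ok = ind.dropna(subset=["min_daily_m3", "min_avg_14d_m3", "min_avg_30d_m3"])
        assert (ok["min_daily_m3"] <= ok["min_avg_14d_m3"] + 1e-9).all()
        assert (ok["min_daily_m3"] <= ok["min_avg_30d_m3"] + 1e-9).all()

    def test_low_season_coverage_flagged(self):
        # only January observed: squeeze season entirely missing
        d = pd.date_range("2000-01-01", "2000-01-31")
        ind = oz.annual_indicators(_vol_table(d, 5.0), windows=(14, 30))
        assert not ind["valid"].any()


class TestLag1Autocorrelation:
    def test_alternating_series(self):
        d = pd.date_range("2000-01-01", periods=100)
        v = _vol_table(d, [1.0, -1.0] * 50)
        assert oz.lag1_autocorrelation(v, "r1") == pytest.approx(-1.0, abs=1e-9)

    def test_constant_series_undefined(self):
        d = pd.date_range("2000-01-01", periods=50)
        assert np.isnan(oz.lag1_autocorrelation(_vol_table(d, 3.3), "r1"))

    def test_ar1_consistency(self):
        rng = np.random.default_rng(1)
        n = 5000
        x = np.zeros(n)
        e = rng.normal(0, 1, n)
        for t in range(1, n):
            x[t] = 0.9 * x[t - 1] + e[t]
        d = pd.date_range("2000-01-01", periods=n)
        assert oz.lag1_autocorrelation(_vol_table(d, x), "r1") == pytest.approx(
            0.9, abs=0.03
        )

    def test_pairs_across_gaps_excluded(self):
        # oracle: correlation over explicitly enumerated within-block pairs;
        # the naive positional lag (which would bridge the gap) differs
        rng = np.random.default_rng(4)
        d1 = pd.date_range("2000-01-01", periods=10)
        d2 = pd.date_range("2000-03-01", periods=10)
        v1, v2 = rng.uniform(0, 1, 10), rng.uniform(100, 101, 10)
        v = pd.concat([_vol_table(d1, v1), _vol_table(d2, v2)])
        x = np.concatenate([v1[:-1], v2[:-1]])
        y = np.concatenate([v1[1:], v2[1:]])
        oracle = np.corrcoef(x, y)[0, 1]
        naive_vals = np.concatenate([v1, v2])
        naive = np.corrcoef(naive_vals[:-1], naive_vals[1:])[0, 1]
        got = oz.lag1_autocorrelation(v, "r1")
        assert got == pytest.approx(oracle, abs=1e-12)
        assert got != pytest.approx(naive, abs=1e-6)

    def test_too_few_pairs_rejected(self):
        d = pd.date_range("2000-01-01", periods=3)
        with pytest.raises(InsufficientDataError):
            oz.lag1_autocorrelation(_vol_table(d, [1.0, 2.0, 3.0]), "r1")
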