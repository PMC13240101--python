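"""Additive trend model: design table, REML fit, term tests."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

import oxysqueeze as oz
from oxysqueeze.errors import InsufficientDataError
from oxysqueeze.gam import fit_squeeze_gam, long_term_trend_test, prepare_gam_table


def _vol_table(dates, values, range_name="r1", scenario="both"):
    return pd.DataFrame(
        {
            "date": pd.DatetimeIndex(dates),
            "range_name": range_name,
            "scenario": scenario,
            "volume_m3": values,
        }
    )


def _levels(dates, level=189.0):
    return pd.DataFrame({"date": pd.DatetimeIndex(dates), "level_m": level})


def _sim_table(n=1095, seed=0, trend=0.0, noise=0.3, level_beta=0.5):
    rng = np.random.default_rng(seed)
    dates = pd.date_range("2000-01-01", periods=n)
    doy = dates.dayofyear.to_numpy(float)
    season = np.sin(2 * np.pi * doy / 365.25)
    ar = np.zeros(n)
    innov = rng.normal(0, 0.1, n)
    for t in range(1, n):
        ar[t] = 0.95 * ar[t - 1] + innov[t]
    level = 189 + 0.5 * season + ar
    yr_frac = (dates.year + doy / 365.25).to_numpy()
    y = 10 + 3 * season + level_beta * (level - 189) + trend * (yr_frac - 2000)
    y = y + rng.normal(0, noise, n)
    return pd.DataFrame(
        {
            "volume_m3": y[1:],
            "volume_lag1_m3": y[:-1],
            "day_of_year": doy[1:],
            "date_frac": yr_frac[1:],
            "level_m": level[1:],
        }
    )


class TestPrepareTable:
    def test_lag_drops_first_day(self):
        d = pd.date_range("2000-01-01", periods=10)
        tab_src = _vol_table(d, np.arange(10.0) + 50)
        # relax the row minimum by padding with a long prior year
        d2 = pd.date_range("1999-01-01", periods=360)
        src = pd.concat([_vol_table(d2, 1.0), tab_src])
        out = prepare_gam_table(src, _levels(src["date"]), "r1")
        recent = out[out["date"] >= "2000-01-01"]
        assert len(recent) == 9

    def test_interior_gap_drops_two_rows(self):
        d = pd.date_range("2000-01-01", periods=60).delete(30)
        src = _vol_table(d, 1.0 * np.arange(len(d)))
        out = prepare_gam_table(src, _levels(d), "r1")
        # missing day itself and its successor both lack a usable lag
        assert len(out) == len(d) - 2

    def test_fractional_year_convention(self):
        d = pd.date_range("1994-12-01", "1995-01-05")
        src = _vol_table(d, 1.0 * np.arange(len(d)))
        out = prepare_gam_table(src, _levels(d), "r1")
        jan1 = out[out["date"] == "1995-01-01"]["date_frac"].iloc[0]
        assert jan1 == pytest.approx(1995.003, abs=5e-4)

    def test_insufficient_rows_rejected(self):
        d = pd.date_range("2000-01-01", periods=20)
        with pytest.raises(InsufficientDataError):
            prepare_gam_table(_vol_table(d, 1.0), _levels(d), "r1")


class TestFit:
    def test_seasonal_signal_recovery(self):
        """A pure day-of-year sinusoid is recovered by the cyclic smooth."""
        rng = np.random.default_rng(7)
        n = 1095
        dates = pd.date_range("2000-01-01", periods=n)
        doy = dates.dayofyear.to_numpy(float)
        truth = np.sin(2 * np.pi * doy / 365.25)
        y = 5 + 2 * truth + rng.normal(0, 0.3, n)
        tab = pd.DataFrame(
            {
                "volume_m3": y,
                "volume_lag1_m3": rng.permutation(y),
                "day_of_year": doy,
                "date_frac": dates.year + doy / 365.25,
                "level_m": rng.normal(189, 1, n),
            }
        )
        fit = fit_squeeze_gam(tab, k_lag=8, k_doy=16, k_date=8, k_level=8)
        seas = fit.term("day_of_year")
        assert seas.p_value < 0.01
        pe = fit.partial_effects
        grid_eff = pe[pe["term"] == "day_of_year"]
        corr = np.corrcoef(
            grid_eff["effect"], np.sin(2 * np.pi * grid_eff["grid_value"] / 365.25)
        )[0, 1]
        assert corr > 0.95
        # unrelated predictors carry no significant effect; date and level
        # smooths shrink to (at most) the effectively linear null
        assert fit.term("date_frac").edf <= 1.5
        assert fit.term("level_m").edf <= 1.5
        assert fit.term("volume_lag1_m3").p_value > 0.01

    def test_constant_response_degenerate(self):
        n = 400
        dates = pd.date_range("2000-01-01", periods=n)
        doy = dates.dayofyear.to_numpy(float)
        tab = pd.DataFrame(
            {
                "volume_m3": np.full(n, 7.0),
                "volume_lag1_m3": np.full(n, 7.0),
                "day_of_year": doy,
                "date_frac": dates.year + doy / 365.25,
                "level_m": np.linspace(188, 190, n),
            }
        )
        with pytest.warns(UserWarning):
            fit = fit_squeeze_gam(tab, k_lag=6, k_doy=8, k_date=6, k_level=6)
        assert fit.r_squared == 0.0
        for t in fit.terms:
            assert t.degenerate
            assert t.edf == 0.0
            assert t.p_value == 1.0

    def test_cyclic_continuity_across_year_boundary(self):
        tab = _sim_table(seed=3)
        fit = fit_squeeze_gam(tab, k_lag=6, k_doy=12, k_date=6, k_level=6)
        pe = fit.partial_effects
        seas = pe[pe["term"] == "day_of_year"].sort_values("grid_value")
        scale = seas["effect"].abs().max()
        assert abs(seas["effect"].iloc[0] - seas["effect"].iloc[-1]) < 1e-6 * max(
            scale, 1.0
        )

    def test_reproducible(self):
        tab = _sim_table(seed=9)
        f1 = fit_squeeze_gam(tab, k_lag=6, k_doy=12, k_date=6, k_level=6)
        f2 = fit_squeeze_gam(tab, k_lag=6, k_doy=12, k_date=6, k_level=6)
        np.testing.assert_array_equal(f1.fitted, f2.fitted)
        assert f1.summary_frame().equals(f2.summary_frame())

    def test_lagged_effect_near_proportional_on_synthetic_lake(self, short_sim):
        """Day-to-day persistence: the lag effect rises close to
        proportionally, with only sub-percent wiggles."""
        tab = prepare_gam_table(short_sim["volumes"], short_sim["levels"], "acute_30")
        fit = fit_squeeze_gam(tab)
        pe = fit.partial_effects
        lag = pe[pe["term"] == "volume_lag1_m3"].sort_values("grid_value")
        lo, hi = np.quantile(lag["grid_value"], [0.05, 0.95])
        central = lag[(lag["grid_value"] >= lo) & (lag["grid_value"] <= hi)]
        rise = central["effect"].iloc[-1] - central["effect"].iloc[0]
        assert rise > 0
        # non-decreasing up to wiggles below 0.5% of the total rise
        assert (np.diff(central["effect"]) >= -5e-3 * rise).all()
        assert fit.term("volume_lag1_m3").p_value < 0.001


class TestTrendTest:
    def test_strong_linear_decline_detected(self):
        hits = linear = 0
        for seed in range(10):
            tab = _sim_table(seed=100 + seed, trend=-1.0, noise=0.5)
            res = long_term_trend_test(
                fit_squeeze_gam(tab, k_lag=6, k_doy=12, k_date=8, k_level=6)
            )
            hits += res["significant"]
            linear += res["shape"] == "linear"
        assert hits >= 9
        assert linear >= 9

    def test_no_trend_usually_insignificant(self):
        rej = 0
        for seed in range(20):
            tab = _sim_table(seed=200 + seed, trend=0.0)
            res = long_term_trend_test(
                fit_squeeze_gam(tab, k_lag=6, k_doy=12, k_date=8, k_level=6)
            )
            rej += res["significant"]
        assert rej <= 4


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
def test_matches_mgcv_reference(tmp_path):
    """Independent oracle: mgcv's REML GAM on the same data agrees closely."""
    tab = _sim_table(n=600, seed=21)
    csv = tmp_path / "tab.csv"
    tab.to_csv(csv, index=False)
    rscript = f"""
    suppressMessages(library(mgcv))
    d <- read.csv("{csv}")
    m <- gam(volume_m3 ~ s(volume_lag1_m3, k=6, bs="bs") + s(day_of_year, k=12, bs="cc") +
             s(date_frac, k=6, bs="bs") + s(level_m, k=6, bs="bs"),
             data=d, method="REML", knots=list(day_of_year=c(1,366)))
    write.csv(data.frame(fitted=fitted(m), r2=summary(m)$r.sq), "{tmp_path}/out.csv", row.names=FALSE)
    """
    subprocess.run(["Rscript", "-e", rscript], check=True, capture_output=True)
    ref = pd.read_csv(tmp_path / "out.csv")
    fit = fit_squeeze_gam(tab, k_lag=6, k_doy=12, k_date=6, k_level=6)
    assert np.corrcoef(fit.fitted, ref["fitted"])[0, 1] > 0.995
    assert fit.r_squared_adj == pytest.approx(ref["r2"].iloc[0], abs=0.02)
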