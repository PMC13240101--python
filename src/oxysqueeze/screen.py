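"""Annual regression screen of survey metrics on lagged habitat indicators.

Each winter survey descriptor (catch per net night and relative weight by
size class) is regressed, one model at a time, on each annual habitat
indicator from the previous summer: 3 squeeze ranges x 3 indicators x 6
descriptors = 54 ordinary least-squares models under the default design.
Family-wise error across the screen is controlled with a Bonferroni-corrected
significance level alpha/m.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidConfigError, NoOverlapError

INDICATOR_COLS = ("min_daily_m3", "min_avg_14d_m3", "min_avg_30d_m3")


@dataclass(frozen=True)
class OlsResult:
    slope: float
    intercept: float
    p_value: float
    stderr: float
    n: int
    degenerate: bool = False


def simple_ols(x: np.ndarray, y: np.ndarray) -> OlsResult:
    """Single-predictor OLS with a two-sided t test on the slope.

    Closed form (normal equations); a zero-variance predictor yields a
    degenerate result with undefined p rather than an exception.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points")
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx == 0.0:
        return OlsResult(np.nan, ym, np.nan, np.nan, n, degenerate=True)
    sxy = float(((x - xm) * (y - ym)).sum())
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = y - intercept - slope * x
    rss = float(resid @ resid)
    if rss <= 0.0:
        # perfect fit: p underflows to 0
        return OlsResult(slope, intercept, 0.0, 0.0, n)
    se = np.sqrt(rss / (n - 2) / sxx)
    t = slope / se
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return OlsResult(slope, intercept, float(p), float(se), n)


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Family-wise corrected per-test level alpha/m."""
    if not 0 < alpha < 1:
        raise InvalidConfigError("alpha must lie in (0, 1)")
    if m < 1:
        raise InvalidConfigError("number of tests m must be >= 1")
    return alpha / m


def align_survey_to_indicators(
    survey: pd.DataFrame,
    indicators: pd.DataFrame,
    lag_years: int = 1,
    require_valid: bool = True,
) -> pd.DataFrame:
    """Pair survey year Y with habitat indicators of year Y - lag_years.

    Indicator years flagged invalid (low squeeze-season coverage or
    undefined indicators) are dropped before pairing when
    ``require_valid``.  Returns one row per (survey year, descriptor,
    range) carrying the descriptor value, the three indicator columns and
    the provenance years.
    """
    ind = indicators.copy()
    if require_valid and "valid" in ind.columns:
        ind = ind[ind["valid"]]
    ind = ind.rename(columns={"year": "indicator_year"})
    pairs = survey.copy()
    pairs["indicator_year"] = pairs["year"] - lag_years
    out = pairs.merge(ind, on="indicator_year", how="inner")
    out = out.dropna(subset=[c for c in INDICATOR_COLS if c in out.columns])
    if len(out) == 0:
        raise NoOverlapError("no survey year has indicators for its lagged year")
    return out


def run_screen(
    paired: pd.DataFrame,
    ranges: Sequence[str] | None = None,
    indicator_cols: Sequence[str] = INDICATOR_COLS,
    descriptors: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fit every (range x indicator x descriptor) regression and flag
    significance at the Bonferroni-corrected level.

    Returns a frame with one row per model: range, indicator, descriptor,
    n, slope, intercept, p, degenerate, significant (p < alpha/m) and
    significant_nominal (p < alpha).  The corrected level is stored in
    ``frame.attrs``.
    """
    if ranges is None:
        ranges = sorted(paired["range_name"].unique())
    if descriptors is None:
        descriptors = sorted(paired["descriptor"].unique())
    rows = []
    for rng_name in ranges:
        sub_r = paired[paired["range_name"] == rng_name]
        for ind_col in indicator_cols:
            for desc in descriptors:
                sub = sub_r[sub_r["descriptor"] == desc].dropna(
                    subset=[ind_col, "value"]
                )
                if len(sub) < 3:
                    continue
                fit = simple_ols(sub[ind_col].to_numpy(), sub["value"].to_numpy())
                rows.append(
                    {
                        "range_name": rng_name,
                        "indicator": ind_col,
                        "descriptor": desc,
                        "n": fit.n,
                        "slope": fit.slope,
                        "intercept": fit.intercept,
                        "p": fit.p_value,
                        "degenerate": fit.degenerate,
                    }
                )
    results = pd.DataFrame(rows)
    if len(results) == 0:
        raise NoOverlapError("no estimable regression models")
    m = len(results)
    alpha_corr = bonferroni_alpha(alpha, m)
    results["significant"] = results["p"] < alpha_corr
    results["significant_nominal"] = results["p"] < alpha
    results.attrs["alpha"] = alpha
    results.attrs["alpha_corrected"] = alpha_corr
    results.attrs["m"] = m
    return results


def screen_summary(results: pd.DataFrame) -> dict:
    """Headline numbers of a completed screen."""
    if len(results) == 0:
        raise ValueError("empty results")
    alpha = results.attrs.get("alpha", 0.05)
    m = results.attrs.get("m", len(results))
    alpha_corr = results.attrs.get("alpha_corrected", bonferroni_alpha(alpha, m))
    valid_p = results["p"].dropna()
    return {
        "n_models": int(m),
        "alpha": float(alpha),
        "alpha_corrected": float(alpha_corr),
        "alpha_corrected_2sf": float(f"{alpha_corr:.2g}"),
        "min_p": float(valid_p.min()),
        "max_p": float(valid_p.max()),
        "n_significant": int(results["significant"].sum()),
        "n_significant_nominal": int(results["significant_nominal"].sum()),
    }


def screen_report(results: pd.DataFrame) -> str:
    """One-page text summary of the screen."""
    s = screen_summary(results)
    lines = [
        "Habitat-indicator regression screen",
        "===================================",
        f"models fitted: {s['n_models']}",
        f"family-wise alpha: {s['alpha']:.3g} -> Bonferroni-corrected "
        f"alpha: {s['alpha_corrected_2sf']:.2g}",
        f"slope p-values range: {s['min_p']:.3f} .. {s['max_p']:.3f}",
        f"significant at corrected alpha: {s['n_significant']}",
        f"significant at nominal alpha: {s['n_significant_nominal']}",
        "",
    ]
    sig = results[results["significant"]]
    if len(sig):
        lines.append("significant models:")
        for _, r in sig.iterrows():
            lines.append(
                f"  {r['range_name']} / {r['indicator']} -> {r['descriptor']}: "
                f"slope={r['slope']:.3g}, p={r['p']:.2e}, n={r['n']}"
            )
    else:
        lines.append("no models significant at the corrected level")
    return "\n".join(lines)
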