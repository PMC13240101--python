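# Methods

## The habitat model

The analysis treats a reservoir as horizontally homogeneous below a given
depth plane: one temperature/DO profile per day applies lake-wide, and
habitat at depth d is either the whole plane or nothing. This mirrors the
single-profile structure of reservoir water-quality models and keeps the
volume arithmetic exact: with the basin's hypsometric step function
A(z) = N(z)·a (N(z) = cells at or below elevation z, a = cell area), the
daily suitable volume is a sum of at most eleven plane areas. There is no
sub-cell interpolation and no averaging of slab top/bottom areas — a plane
at elevation L−d contributes A(L−d)×1 m when suitable, zero otherwise —
so every volume is an integer multiple of the cell area and can be checked
against a per-cell count with zero tolerance.

Two conventions worth stating explicitly:

* **Inclusive thresholds.** A plane at exactly the thermal limit or the DO
  floor counts as suitable (T ≤ T_max, DO ≥ DO_min). The DO wording
  "minimum 3 mg/L" forces inclusivity there; temperature follows for
  symmetry.
* **Eleven planes.** Profiles cover depths 0–10 m at 1 m intervals, and
  all eleven planes contribute one metre each. The deepest plane can be
  switched off (`n_planes=10`) where a ten-layer reading is preferred.

Depth planes below the basin minimum have zero area and contribute
nothing, so the model degrades gracefully at low water. NaN profile
values make a plane unsuitable (except under the no-stressor control) and
are logged rather than raised, so gap-adjacent partial profiles survive.

## Indicators

The seasonal climatology groups daily volumes by a leap-stable day-of-year
index (Feb 29 is day 60 in every year, Mar 1 is 61), so the same calendar
date always lands in the same bin; SD is the across-year sample SD,
reported as 0 where only one year contributes.

Annual indicators per squeeze range are computed under the
combined-stressor scenario: the yearly minimum daily volume (pulse), and
the minimum 14- and 30-day forward rolling-window means (press). Windows
start on each calendar day, must lie wholly inside the year, and are
discarded if any member day is unobserved — no partial-window averaging
and no imputation. Years observing fewer than half of the June–October
squeeze-season days are flagged invalid and excluded from the survey
screen, since an unobserved squeeze season makes the annual minimum
meaningless. The lag-1 autocorrelation diagnostic uses only pairs of
dates exactly one day apart, so data gaps cannot manufacture spurious
lags; a zero-variance series returns NaN rather than raising.

## Trend model

Per squeeze range, a Gaussian additive model with identity link:

    V_t = b0 + f1(V_{t-1}) + f2(doy_t) + f3(date_t) + f4(level_t) + e_t

f2 uses a cyclic cubic regression spline (effect continuous across the
Dec 31 → Jan 1 boundary; basis dimension k=20 by default), f1/f3/f4 use
cubic penalized B-splines with k=10 and *equally spaced* knots — quantile
knots collapse when the volume series has a point mass at zero, as it does
whenever a range closes completely in summer. Each smooth carries a
sum-to-zero constraint absorbed by a null-space reparameterisation.
Fractional years follow the year + doy/365.25 convention (Jan 1 1995 →
1995.003). Rows whose previous calendar day is unobserved are dropped
(the lag must be a real one-day lag), as are rows without a level.

Smoothing parameters minimise the profiled REML criterion

    (n - M_p) log(||y - Xb||^2 + b'S(l)b) + log|X'X + S(l)| - sum_j r_j log(l_j)

by L-BFGS-B in log(λ) with the exact analytic gradient, started from the
balanced guess λ_j = tr(X_j'X_j)/tr(S_j). The start matters: when a
flexible date smooth can alias the annual cycle (short series, large k),
the REML surface is multimodal, and the balanced start keeps the optimum
in the intended basin — the same behaviour as mgcv's initialisation, with
which this fitter agrees closely (fitted-value correlation > 0.999 and
matching per-term edf on shared test data; the suite cross-checks against
mgcv through Rscript when R is available).

Per-term significance uses a Wald-type F statistic on the fitted smooth,
pseudo-inverted at an integer rank taken from the *alternative* edf
tr(2F − F²) (floor, bumped when the fractional part exceeds 0.05), with
residual df n − edf_total. Under zero-trend simulations this test rejects
at close to the nominal rate (~0.05–0.075 at α = 0.05). The long-term
trend classification calls a date smooth with edf ≤ 1.1 "effectively
linear". A residual lag-1 ACF is reported as a diagnostic for whether the
lagged-response term removed the temporal dependence; the model keeps
Gaussian errors even though volumes are bounded below at zero, a known
approximation shared with the standard practice for such series.

## Survey screen

Each (range × indicator × descriptor) model is a single-predictor OLS of
survey year Y on the indicator of calendar year Y−1 ("previous summer";
the lag is configurable), fitted in closed form with a two-sided t test on
the slope. With the default three ranges, three indicators and six
descriptors this is 54 models; family-wise error is controlled by
Bonferroni, α/54 ≈ 0.00093 (the unrounded 0.05/54 is used internally,
with strict inequality p < α/m). A zero-variance indicator — e.g. a range
whose yearly minimum is zero every single year — yields a flagged
degenerate result with undefined p rather than an exception, and
degenerate models are excluded from calibration-rate denominators.
Missing survey years are allowed per descriptor (no balanced panel is
required), and no outlier handling or robust alternative is applied.

## The synthetic lake

The generator produces inputs with the statistical structure the analysis
assumes, not a hydrodynamic simulation:

* **Bathymetry** — an elliptic-paraboloid bowl on a square-cell grid,
  rescaled so the raster minimum/maximum equal the configured basin floor
  and rim exactly; optional seeded roughness. Defaults: 40×40 cells of
  486.06 m (full-pool plan area ≈ 3.8×10⁸ m², a ~36,000 ha impoundment),
  floor 178 m, rim 195 m AMSL.
* **Water levels** — mean 189 m + 2 m seasonal sinusoid + AR(1) residual
  (φ = 0.97, innovation SD 0.15 m), spanning roughly 185–193 m over a
  26-year run. Gap windows are absent rows, not sentinels.
* **Profiles** — surface temperature is an 18 ± 11 °C sinusoid peaking in
  late July, plus a persistent AR(1) anomaly (φ = 0.98, innovation SD
  0.15 °C) so summers differ from year to year; between day-of-year 150
  and 290 a sin² stratification index s(t) ramps a logistic thermocline
  (total contrast 12 °C, midpoint 11 m, width 2 m) and depletes
  hypolimnetic DO from 8 toward 1 mg/L along the same logistic. The
  midpoint sits just below the profiled 0–10 m window, so at peak
  stratification the whole window exceeds 25 °C (the preference range
  closes) while DO stays above 3 mg/L within it (the acute range keeps
  most of the layer) — the squeeze pattern the trait thresholds are meant
  to resolve. Mixed winter columns are depth-constant by construction.
* **Survey** — each descriptor is baseline + slope × indicator(year−1) +
  Gaussian noise, with realistic baselines (e.g. 10 fish/net-night total
  C/f, relative weights near 85–92) and zero slopes by default, making
  the null screen exact by construction.

All four generators draw from independent streams spawned from one master
seed; identical config + seed gives bit-identical outputs.

What the generator does **not** emulate: lateral heterogeneity (coves,
riverine arms, tailwater refugia), level-dependent stratification
feedback, DO interannual anomalies separate from temperature, observation
error in the survey design (gillnet selectivity, effort changes), and any
fish movement or bioenergetics. Passing tests therefore demonstrate that
the pipeline's geometry, reductions and inference behave correctly on
data satisfying the stated assumptions — not that those assumptions hold
for a particular real reservoir.

## Problem sizes and numerical choices

The test suite runs the full pipeline on the 26-year default lake
(~9,500 days; a GAM fit there takes well under a second) and uses
two-to-six-year lakes for module tests. Calibration checks use 500
replicate null screens and 200 replicate GAM fits on two-year series —
sizes chosen so Monte-Carlo error is small relative to the tolerance being
asserted. Geometry is validated on 500 random small grids against an
explicit per-cell oracle with zero tolerance. Degenerate inputs are
first-class: constant responses yield a flagged all-degenerate GAM fit,
constant predictors a warned zero-effect term, and empty inputs empty
outputs rather than exceptions wherever the contract allows.

## Known limitations

* The additive-model F tests use an integer-rank approximation of the
  fractional-rank reference distribution; p-values agree with mgcv to
  within Monte-Carlo error in our checks but are not bit-identical.
* The screen's year alignment (survey Y on indicators of Y−1) is one
  interpretation of "previous summer" for late-winter surveys; the lag is
  exposed as a parameter.
* Rasters must be single-band, square-cell and pre-aligned; there is no
  reprojection or mosaicking.
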