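# oxysqueeze

Habitat analysis for fish caught in a summer **temperature–oxygen squeeze**:
in a thermally stratified reservoir, surface water becomes too warm while
deep water loses dissolved oxygen (DO), pinching the volume of water a
species can actually occupy into a narrow mid-depth band. `oxysqueeze`
quantifies that squeeze day by day for a reservoir and relates it to annual
fish-survey metrics. It is written for reservoir fisheries scientists and
quantitative ecologists who want a reproducible, fully scripted version of
this analysis — either on their own rasters/profiles or on the built-in
synthetic lake.

## What it computes

Given a bathymetric elevation raster, a daily water-surface-level series,
and daily vertical profiles of temperature and DO at 1 m depth intervals
(0–10 m), the pipeline:

1. **Hypsometry** — builds the exact area-at-elevation step function
   A(z) = (number of raster cells with elevation ≤ z) × cell area.
2. **Daily habitat volume** — for each day t with surface level L_t, each
   1 m depth plane d ∈ {0,…,10} contributes its full plan area when its
   water is suitable:

   V_t = Σ_d A(L_t − d) · (1 m) · 1[T_{t,d} ≤ T_max ∧ DO_{t,d} ≥ DO_min]

   under three trait threshold ranges for adult striped bass —
   preference (25 °C), tolerance (28 °C) and acute tolerance (30 °C), all
   with a 3 mg/L DO floor — and four stressor scenarios (none / DO only /
   temperature only / both) that decompose which stressor drives the loss.
3. **Indicators** — a day-of-year climatology (mean ± SD across years) and
   three annual disturbance indicators per range: the yearly minimum daily
   volume (an abrupt "pulse" squeeze) and the minimum 14-day and 30-day
   forward rolling-window averages (sustained "press" squeezes).
4. **Trend model** — a Gaussian additive model per range,

   V_t = β₀ + f(V_{t−1}) + f(doy_t) + f(date_t) + f(level_t) + ε_t,

   with a cyclic cubic spline for day of year and penalized B-splines for
   the other smooths; smoothing parameters are selected by REML and terms
   are summarised by effective degrees of freedom (edf) and Wood-style
   F tests.
5. **Survey screen** — 54 ordinary least-squares regressions (3 ranges ×
   3 indicators × 6 winter gillnet descriptors: catch-per-net-night for
   total/<12 in/12–20 in/>20 in and relative weight for <12 in/>20 in) of
   each survey year on the previous summer's indicator, with a Bonferroni
   family-wise correction (α = 0.05/54 ≈ 0.00093).

A seeded synthetic-lake generator (bowl bathymetry, seasonal + AR(1) water
levels, logistic thermocline/oxycline with interannual temperature
anomalies, and survey metrics with configurable — by default zero — habitat
effects) provides all inputs for testing and simulation studies.

## Worked example

Run the whole pipeline on the default synthetic lake:

```bash
oxysqueeze run-all --seed 1 --outdir out/
```

which prints the screen summary:

```json
{
  "n_models": 54,
  "alpha": 0.05,
  "alpha_corrected": 0.000925925925925926,
  "alpha_corrected_2sf": 0.00093,
  "min_p": 0.0367335487095711,
  "max_p": 0.9136700611088515,
  "n_significant": 0,
  "n_significant_nominal": 3
}
```

Reading this: all 54 indicator→descriptor regressions were fitted; the
smallest slope p-value (0.037) beats the nominal 0.05 in 3 models — about
what chance alone produces in 54 tests — but none survives the corrected
level of 0.00093, so the screen finds no evidence that the previous
summer's squeeze drives the survey metrics (the default generator injects
no effect, so this is the correct answer). `out/` also contains every
stage product: the bathymetry GeoTIFF, the hypsometric curve, daily
volumes per range × scenario, the climatology, annual indicators, GAM
summaries and partial-effect curves (`gam_summary.csv` shows, e.g., the
lagged-volume smooth with edf ≈ 9 and p ≈ 0 — strong day-to-day
persistence — and an insignificant long-term date trend), the synthetic
survey and a `manifest.json` that records the config hash, seed and row
counts so the run can be reproduced byte-for-byte.

Stage subcommands (`simulate`, `hypsometry`, `volumes`, `indicators`,
`gam`, `screen`) run the same steps against files on disk; all parameters
can be set in a flat YAML config (`--config`), e.g. `grid_rows: 40`,
`mean_level: 189.0`, `years: [2001, 2002]`.

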