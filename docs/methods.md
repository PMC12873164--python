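# Methods

This note documents the models, parameter choices, numerical conventions and
limitations behind `wheatclim`. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Calendar conventions

Day counts are **inclusive**: the sowing day is day 1, so sowing on 15
October with 100 days to anthesis gives anthesis on 22 January. This is the
single convention used everywhere (season extraction, GDD inversion, scenario
arithmetic); mixing inclusive and exclusive counting is a classic source of
off-by-one disagreements between published scenario tables, and we fix one
rule rather than emulate inconsistencies. Scenario arithmetic defaults to a
non-leap reference year (2001), matching the convention under which the
standard five-sowing table is internally consistent; all other calendar work
uses the real proleptic Gregorian calendar, leap years included.

The 15 Oct–30 Apr growing-season window spans 198 days by inclusive calendar
counting (199 across a leap February). A nominal figure of 196 days is
sometimes quoted for this window; it is recorded as a documentation constant
(`NOMINAL_SEASON_LENGTH_DAYS`) and never used in computation — season lengths
are always derived from the calendar.

## Growing degree days

Daily thermal time uses the mean-temperature form with cardinal temperatures:

* `T̄ = (Tmax + Tmin)/2` is clamped to `[T_base, T_opt]`; the contribution is
  `T̄ − T_base` (so it saturates at `T_opt − T_base`);
* the whole day contributes **zero** when `Tmax` exceeds the phase ceiling
  `T_ceil`. The trigger is the daily *maximum* because heat-stress thresholds
  for wheat are phrased against daily highs.

The clamp-plateau rule is the simplest response consistent with both the
plain `(Tmax+Tmin)/2 − T_base` formula and a ceiling-zero rule. A
**trapezoidal** alternative (linear decline of the contribution between
optimum and ceiling) is available via `PhaseSchedule(response="trapezoid")`
and is clearly labelled as the optional mode.

Default cardinal triplets (°C, from the Porter & Gawith wheat synthesis):
vegetative 4.0/22.0/32.7, anthesis→grain-fill 9.5/21.0/31.0,
grain-fill→maturity 9.2/20.7/35.4. The grain-fill ceiling is 35.4 °C while a
*separate* counter tallies days with Tmax > 35 °C (`heat_zero_threshold`),
because the two thresholds serve different purposes (development cutoff vs
terminal-heat-stress exposure index); both are configurable.

When only days-to-anthesis is known, the default three-phase schedule is
vegetative = days 1..DTA, anthesis→grain-fill = the next 10 days (the
standard flowering duration), grain-fill→maturity = the remainder.

`days_to_reach` inverts cumulative GDD against a target and returns a
distinguished `NonAttainment` object (not an exception) when the series ends
first, since non-attainment is an expected outcome in cool seasons.

## Synthetic weather generator

The generator emulates the statistical structure of a multi-decadal
semi-arid winter-wheat station record:

```
T̄_d = μ + λ·(d / 3652.5) − A·cos(2π(doy_d − doy_cold)/365.25) + u_y(d) + e_d
e_d = ρ·e_{d−1} + ε_d,           ε_d ~ N(0, σ²(1−ρ²))
Tmax/Tmin = T̄ ± R_d/2,           R_d ~ N(μ_R, σ_R) truncated at 0.5 °C
```

with λ the warming trend (°C/decade), `u_y` a season-level N(0, σ_y) offset
shared by all days of one July–June year, and `e` stationary AR(1) noise
(σ = `residual_sd` is the *stationary* SD, so the lag-1 autocorrelation of
the deseasonalized daily residual recovers ρ directly — a tested property).

Rainfall is independent of temperature (no cross-dependence structure is
assumed): occurrence follows a two-state Markov chain
(`p_wet_given_dry` = 0.15, `p_wet_given_wet` = 0.50 by default, a
climatological wet fraction of ≈0.23), amounts on wet days are
gamma-distributed (shape 0.45), and each July–June year's gamma scale is
multiplied by a mean-one lognormal factor (log-sd 0.6). The year factor is a
deliberate addition: without it, seasonal totals of ~45 wet days are nearly
symmetric by the central limit theorem, whereas semi-arid seasonal rainfall
records are strongly right-skewed (skewness ≈ 3 in the motivating region);
the mixture restores that heavy right tail. Likewise the season-level
temperature effect σ_y = 1.5 °C is needed to reproduce the ≈2 °C interannual
SD of seasonal mean temperature that daily AR(1) noise alone cannot produce
(a 198-day mean of AR(1) noise has SD ≈ 0.3 °C).

**Seeding.** One master seed spawns independent substreams (numpy
`SeedSequence`) for temperature and rainfall, so toggling rainfall parameters
leaves the temperature field bit-identical (tested).

**Site presets.** `preset("islamabad")` and `preset("chakwal")` back out the
annual-mean and gamma-scale parameters analytically so the *expected*
41-season climatology hits the target seasonal mean temperature (19.3 /
18.3 °C, tolerance ±0.5 °C across seeds) and mean seasonal rainfall total
(427.93 / 296.62 mm). Warming trends are 0.40 and 0.24 °C/decade; the
Chakwal figure reads the site's reported ≈1 °C total warming over 41 years as
a per-decade rate, and the field remains a free parameter for users who
prefer another reading. Trend recovery is unbiased: across seeds the mean
OLS slope of seasonal means equals the configured trend within Monte-Carlo
error (the acceptance suite checks 200 seeds × 41 seasons).

**What the generator does not emulate:** spatial correlation between sites,
humidity/wind/solar fields (the .WTH writer fills SRAD with a documented
15 MJ m⁻² d⁻¹ placeholder), temperature–rainfall dependence, monsoon timing
within the off-season, and any trend in rainfall. Tests passing on synthetic
data therefore validate the *machinery* (accumulation rules, statistics,
reproducibility), not site-specific climatologies beyond the calibrated
moments above.

## Trend statistics

Descriptive statistics are survey-style: sample (n−1) variance/SD, adjusted
Fisher–Pearson skewness, **excess** kurtosis (normal → 0; the convention
under which near-uniform annual series can legitimately show negative
kurtosis). Constant vectors raise by default (`strict=False` flags them with
zero spread instead).

Polynomial trends default to degree 2 — the standard choice for
decadal-scale agro-climatic series, allowing curvature such as accelerating
warming — with degree as a knob. Fits go through statsmodels OLS on a
Vandermonde design; rank deficiency (fewer distinct x values than
coefficients) is detected and named before fitting. The reported p-value is
the overall model F-test, two-sided; it is informational and never drives an
automated decision. Pearson correlation matrices refuse zero-variance
columns by name.

## Sowing-date scenarios

The five standard sowings are 15/25 October, 4/14/24 November, with site
days-to-anthesis fixed at the long-term means (105 days Islamabad-like, 100
days Chakwal-like) and a 10-day flowering window starting at anthesis. The
flowering-window temperature is the mean daily T̄ over the window, averaged
across every year of the series that covers it.

The relative rise between the earliest and a later sowing is
`(T_k − T_first)/T_k × 100` — note the **later** sowing's temperature in the
denominator. This is the only convention under which both canonical
percentages (33.41 % and ≈35.68 %) follow from the published window
temperatures; a 0.01-point discrepancy on the second value is a rounding
artefact of the source and is asserted as such in the tests.

The yield-loss column of a scenario table is *data*, not computation: the
canonical values come from process-model runs this package deliberately does
not re-implement. Supplied losses pass through verbatim; the sensitivity
surrogate can fill the column in clearly-labelled demo mode.

Stage rainfall partitions each season's rain at the fixed site DTA
(vegetative = days 1..DTA after sowing, reproductive = remainder); the split
conserves season totals exactly. Decadal aggregation supports both means and
sums via a flag — published stage-rainfall tables are ambiguous about which
they report, so neither is asserted as canonical.

The economics helper is pure arithmetic: kg = t × 1000, maunds = kg/40,
PKR = maunds × support price (default 3100 PKR/40 kg), USD = PKR/fx. The
PKR/USD rate is an explicit input (default 278.5, a 2023-era market rate)
because quoted dollar figures are meaningless without it.

## Sensitivity analysis

The statistics are exact ratios: loss %/°C = `(Y_amb − Y_+1)/Y_amb × 100`,
change %/100 ppm = `(Y_elev − Y_base)/Y_base × 100` per 100-ppm step; when a
whole ΔT (or CO₂) axis is supplied, per-increment rates are averaged.

The **surrogate yield model** `Y = Y₀(1 − r·ΔT)(1 + g·ln(C/C_ref)) + ε`
(floored at 0) is the simplest shape consistent with a near-linear %/°C loss
and a saturating CO₂ benefit. Site calibrations: baseline 4.0 t/ha with
r = 4.5 %/°C (Islamabad-like) and 6 %/°C (Chakwal-like), g = 0.08/0.07 per
log-unit CO₂, reference 350 ppm (410 ppm is an equally defensible modern
baseline; the reference is a config field). It is a surrogate for exercising
the sensitivity statistics and is nowhere claimed to emulate process-model
dynamics. By construction the CO₂ benefit cannot offset warming once
`r·ΔT > g·ln(C_max/C_ref)` — with the default calibration that crossover sits
near ΔT ≈ 1.5 °C, so temperature dominates across most of the 0–8 °C grid
(asserted on the surrogate only).

Grid estimates of the loss rate converge on the configured r with noise: the
tests check an 8-realisation mean of 500-replicate grids against 3
Monte-Carlo standard errors.

## Model evaluation metrics

R² is the **squared Pearson correlation** of observed and simulated — the
printed-formula convention in crop-model validation — and is therefore blind
to additive/multiplicative bias; the 1 − SSE/SST form is exposed separately
as `nse` (Nash–Sutcliffe efficiency), which can go negative under bias. Bias
is mean(S − O): positive means over-simulation. RMSE ≥ MAE ≥ 0 and
RMSE ≥ |bias| are enforced identities (note some published metric tables
violate MAE ≤ RMSE, which is arithmetically impossible under these formulas
and flags a transcription error). A constant observed vector raises, naming
the undefined statistics.

## Pipeline and reproducibility

`run_pipeline` chains weather → GDD → trends → scenarios → sensitivity →
evaluation and writes a manifest (canonical config, master seed, package
version, SHA-256 per output). All floats are written with fixed formats, so
identical config + seed gives a byte-identical bundle (tested). The demo
phenology stage inverts cumulative GDD against targets of 1365 (anthesis)
and 1585 °C·day (maturity) — calibrated to the generator's climatology so
derived DTA/DTM land near the site-typical 105/135 days — and simulates
yield with the surrogate driven by each season's temperature anomaly; these
are self-contained synthetic demonstrations, not reconstructions of observed
records. The evaluation stage scores the quadratic trend model's fitted
values against the synthetic observations.

## Problem sizes

Default runs use 41 seasons (1980–2021), the scale of a four-decade station
record; the trend-recovery checks use 200 seeds × 41 seasons, and sensitivity
recovery uses 500 replicates per grid cell — sizes at which Monte-Carlo
standard errors are several times smaller than the tolerances being asserted.

## Known limitations

* The GDD ceiling-zero rule and clamp plateau are one defensible reading of
  mean-temperature thermal time; trapezoidal and hourly-interpolation
  responses differ most near the cardinals. Only the trapezoid is provided.
* Vernalization and photoperiod are not modelled; thermal-time inversion
  alone overstates development speed in warm autumns.
* The surrogate yield model has no water balance, so rainfall never affects
  its yields; stage-rainfall tables are descriptive only.
* Generated series have no rainfall trend and no temperature–rainfall
  coupling; drought–heat compounding cannot be studied with the defaults.
* The .WTH writer uses two-digit DSSAT years (century pivot 50 on re-read);
  series spanning 1950–2049 round-trip unambiguously, others need care.
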