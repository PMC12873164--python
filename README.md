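# wheatclim

Agro-climatic analysis of warming impacts on rainfed winter wheat, built for
semi-arid environments like Pakistan's Pothwar Plateau, where wheat is sown in
mid-October and harvested by the end of April. The package is aimed at
agronomists and crop-climate analysts who need a reproducible pipeline from
daily weather to phenology/yield trend statistics, sowing-date adaptation
tables, and temperature/CO₂ sensitivity summaries — including when the
underlying multi-decadal station records cannot be redistributed, in which
case a calibrated stochastic weather generator stands in for them.

## What it computes

**Thermal time.** Wheat development is driven by growing degree days with
phase-specific cardinal temperatures (base / optimum / ceiling):

```
GDD_d = clamp(T̄_d, T_base, T_opt) − T_base,   T̄_d = (Tmax_d + Tmin_d) / 2
GDD_d = 0                                      when Tmax_d > T_ceil
```

with triplets 4/22/32.7 °C (sowing→anthesis), 9.5/21/31 °C
(anthesis→grain-fill) and 9.2/20.7/35.4 °C (grain-fill→maturity), plus a
separate count of terminal heat-stress days (Tmax > 35 °C). Inverting
cumulative GDD against a thermal-time target yields days-to-anthesis/maturity.

**Synthetic weather.** Daily mean temperature is modelled as
annual mean + linear warming trend + a cosine seasonal harmonic + a
season-level random effect + AR(1) daily noise; Tmax/Tmin split by a sampled
diurnal range; rainfall follows a two-state Markov occurrence chain with
gamma amounts scaled by a lognormal year factor (strongly right-skewed
seasonal totals). Site presets (`islamabad`, `chakwal`) are calibrated so the
41-season climatology matches 19.3 / 18.3 °C seasonal means with 0.40 / 0.24
°C-per-decade warming.

**Statistics.** Survey-style descriptive statistics (sample SD/variance,
adjusted Fisher–Pearson skewness, excess kurtosis), polynomial trend
regression `Y = β₀ + β₁X + β₂X² + … + ε` via OLS with overall-F p-values,
decadal min/max/mean summaries, Pearson correlation matrices, and the
standard crop-model evaluation battery (R² as squared correlation, RMSE, MAE,
bias, 1:1 regression `S = a + bO`).

**Scenarios and sensitivity.** Five sowing dates (15 Oct … 24 Nov in 10-day
steps) with fixed site DTA give anthesis dates by inclusive day arithmetic
(sowing day = day 1); the 10-day flowering-window mean temperature and its
relative rise `(T_k − T_first)/T_k × 100` quantify late-sowing heat exposure.
Yield sensitivity statistics — loss %/°C and change %/100 ppm CO₂ — run over
a documented surrogate response surface
`Y = Y₀(1 − r·ΔT)(1 + g·ln(C/C_ref)) + ε` standing in for a process-based
crop simulator.

## Worked example

```python
import wheatclim as wc
from wheatclim.weather import seasonal_table

series = wc.generate_series(wc.preset("islamabad", seed=1))
tab = seasonal_table(series)
fit = wc.fit_polynomial(tab.index.to_numpy(float), tab["tmean"].to_numpy(), 1)
print(f"fitted warming trend: {fit.slope*10:.3f} C/decade (R2={fit.r_squared:.2f})")

for r in wc.scenario_table(series, wc.standard_scenarios(dta_days=105)):
    print(f"{r.scenario.label}: anthesis {r.anthesis:%d %b}, "
          f"window Tmean {r.window_tmean:.2f} C, "
          f"rise vs SD1 {r.relative_rise_vs_first:.2f}%")
```

prints

```
fitted warming trend: 0.328 C/decade (R2=0.05)
SD1: anthesis 27 Jan, window Tmean 16.04 C, rise vs SD1 0.00%
SD2: anthesis 06 Feb, window Tmean 16.36 C, rise vs SD1 1.99%
SD3: anthesis 16 Feb, window Tmean 17.39 C, rise vs SD1 7.78%
SD4: anthesis 26 Feb, window Tmean 18.56 C, rise vs SD1 13.59%
SD5: anthesis 08 Mar, window Tmean 19.52 C, rise vs SD1 17.87%
```

One 41-season realisation recovers the configured 0.40 °C/decade trend only
noisily (here 0.33; interannual variability dominates a single record — the
across-seed mean is unbiased), and delaying sowing from 15 October to 24
November pushes anthesis from late January into March, warming the flowering
window by ~3.5 °C in this draw. The five-row table mirrors the structure used
to argue for early sowing as a heat-avoidance strategy.

The same stages are scriptable from the shell:

```bash
wheatclim run --site islamabad --seed 7 --outdir out/       # full bundle
wheatclim generate --site chakwal --seed 3 --out chakwal.csv
wheatclim sensitivity --site islamabad --seed 5 --outdir sens/
```

`wheatclim run` writes weather (CSV and DSSAT-style .WTH), per-season GDD and
heat-day counts, descriptive/trend/correlation tables, the sowing-scenario
and stage-rainfall tables, the sensitivity grid with its %/°C and %/100 ppm
summaries, trend-model evaluation metrics, and a manifest with the config
hash and SHA-256 of every output — identical config + seed reproduces the
bundle byte for byte.

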