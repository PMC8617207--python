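# phenoflux

Tools for studying how **spring snowmelt timing and greenup timing
control carbon uptake in Arctic tundra**, built around a snowmelt-gated
phenology index and a set of constrained regression analyses, with a
fully synthetic site generator so that every method can be exercised —
and its error characterised — against known ground truth.

## The problem

In tundra ecosystems, two spring events set the length and productivity
of the growing season: the date meteorology becomes favourable for leaf
growth (*greenup*), and the date the snowpack clears. Greenup is mostly
temperature-driven and is advancing quickly; snowmelt depends on both
winter precipitation and spring temperature, and can lag behind — a
*delayed snowmelt* postpones leaf-out even when air temperatures are
ready, cutting early-season carbon uptake. Separating these two
controls in observations is hard because interannual weather variation
moves fluxes too. `phenoflux` implements the quantitative chain such a
study needs:

* **Climatic limit scalars** — monthly percentage reductions of
  vegetation growing days from temperature (linear ramp, 100% at
  −5 °C to 0% at +5 °C), water (P/PET ratio ramp, 100% at 0 to 0% at
  0.75, with Priestley–Taylor PET), and radiation (0.5% per 1% of
  cloudiness above 10%, cloudiness inverted from
  R = R₀(1 − 0.75 n³·⁴)).
* **Growing-season index (GSI)** — the daily product of three [0, 1]
  ramps of daylength, VPD and a growing-degree-day sum (above −5 °C
  from Jan 1 in spring; chilling below 20 °C from Aug 1 in fall), with
  thresholds calibrated from observed phenology dates, and its
  snowmelt-gated variant **SGSI = GSI × iS**, where the gate iS is 0
  while snow-cover fraction exceeds 0.1.
* **Timing extraction** — logistic fits to snow-cover series (0.1
  crossing, two-week gap rejection), interpolated 0.1/0.5 index
  crossings, and smoothing-spline flux timings (source–sink transition,
  half-max productivity).
* **Trend inference** — Mann–Kendall (exact small-sample null) and
  Spearman tests, OLS/Sen slopes in days per decade, and bootstrap 95%
  CIs that resample each year's timing from its stated uncertainty.
* **Effect analysis** — meteorological-similarity and greenup
  screening, then least-squares regression of seasonal flux deviations
  on timing deviations, reported as Δ per 10 days; plus paired
  gated/ungated emulator runs whose difference isolates the pure
  snow-gate effect.
* **Synthetic sites** — an Arctic weather generator, a degree-day
  snowpack, thermal-sum phenology dates, and a small flux emulator with
  *configurable, known* NEP sensitivities to snowmelt and greenup
  timing, standing in for reanalysis forcing, satellite products, flux
  towers and a full ecosystem model.

## Worked example

```python
import phenoflux as pf

cfg = pf.SiteConfig(site_id="SYN-1", latitude=68.0, years=18, seed=42)
met = pf.generate_met(cfg)
snow = pf.generate_snow(met)
phen = pf.derive_phenology(met)

limits = pf.seasonal_limit_summary(met)
print(limits[["t_limit", "w_limit", "r_limit"]].astype(float).round(1))
print("limit class:", pf.classify_site(limits["t_limit"], limits["w_limit"]))

spring = pf.calibrate_thresholds(met, phen, "spring")
fall = pf.calibrate_thresholds(met, phen, "fall")
index = pf.annual_index(met, spring, fall, snow=snow)

timings = pf.extract_timings(snow=snow, gsi=index)
print(timings[["year", "snowmelt_doy", "t_gsi_01", "t_sgsi_01"]].head(3).round(1))

res = pf.TimingTrend.from_dataframe(timings, "snowmelt_doy").fit(
    three_sigma=6.6, seed=1)
print(res.summary())
```

prints

```
t_limit    24.4
w_limit    59.1
r_limit    19.6
limit class: MCL
 year  snowmelt_doy  t_gsi_01  t_sgsi_01
 2001         138.3     141.3      141.3
 2002         151.2     141.9      151.1
 2003         150.3     140.6      150.1
variable                 snowmelt_doy
slope_days_per_decade       -0.691812
p_mk                         0.649446
ci_low                      -2.626112
ci_high                      1.253067
n_years                            18
```

Reading this: the site's growing days are reduced ~24% by temperature
and ~59% by water (a moderately colimited site); in 2001 snow cleared
(DOY 138.3) before meteorology was ready (GSI crossed 0.1 on DOY
141.3), so the gated and ungated onsets coincide, while in 2002–2003
snow persisted ~9–10 days past meteorological readiness and delayed the
gated onset to the snowmelt date. Over 18 years the snowmelt trend is
−0.7 days per decade with a bootstrap 95% CI of [−2.6, +1.3] — no
significant advance (Mann–Kendall p = 0.65).

The whole chain also runs from a YAML config:

```bash
phenoflux run --config demo.yml --out run_dir --seed 3
```

or stage by stage (`phenoflux simulate | limits | gsi | timings |
neereg | trends`).

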