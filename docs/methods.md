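# Methods

This note documents the models implemented in `phenoflux`, the defaults
chosen where the underlying procedure leaves details open, what the
synthetic generator does and does not emulate, and the numerical
conventions the tests rely on.

## Climatic limit scalars

Vegetation growing days lost to each climatic constraint are expressed
as monthly percentages, computed from calendar-month aggregates of the
daily record (no partial months):

* temperature: 100% at monthly mean T ≤ −5 °C, 0% at ≥ +5 °C, linear
  between;
* water: the ratio of monthly precipitation to Priestley–Taylor PET,
  mapped 100% → 0% over the ratio range 0 → 0.75;
* radiation: 0.5% per percentage point of monthly cloudiness above
  10%, with cloudiness n inverted from R = R₀(1 − 0.75 n³·⁴).

Priestley–Taylor details are configurable with common defaults:
α = 1.26, net radiation approximated as (1 − 0.2) × SW↓, ground heat
flux G = 0, λ = 2.45 MJ kg⁻¹, Δ and γ from standard psychrometric
formulas. PET is floored at 0 so freezing months cannot produce a
negative water ratio; when PET = 0 exactly, the water limit is defined
as 0% if any precipitation fell and 100% otherwise. In months of polar
night (zero clear-sky radiation) cloudiness is undefined and treated as
clear sky.

Season-scale values average the window months within each year and then
across years (`year-then-month`); pooled averaging is available because
the aggregation order is genuinely ambiguous. All ramps are continuous,
piecewise linear and clamped — the tests assert continuity at every
knot. Sites are classed for cross-site reporting as strongly colimited
(both T and water limits ≥ 35%), moderately colimited (both ≥ 15%) or
weakly water-limited, thresholds chosen to reproduce the qualitative
split between high-latitude and low-latitude tundra sites.

## GSI and the snow gate

The daily growing-season index is GSI = iX₁ · iX₂ · iX₃, the product of
[0, 1] ramps of daylength, VPD and a growing-degree-day accumulator.
Spring indices run Jan 1 – Jul 31 with GDD the exceedance sum
max(0, T + 5) from Jan 1; fall indices run Aug 1 – Dec 31 with a
chilling sum max(0, 20 − T). Exceedance is the standard degree-day
convention; a raw-temperature-sum alternative was considered and
rejected as non-standard. The gated index is SGSI = GSI × iS with
iS = 0 strictly above snow-cover fraction 0.1 (cover of exactly 0.1
leaves the gate open). No smoothing is applied by default — the index
is a daily product — but a centred running mean is available.

Ramp thresholds are calibrated from yearly phenology dates: for each
variable, the minimum over years of its value on the greenup day and on
the maturity day (dormancy and senescence in fall). The smaller
calibrated value becomes x_min, the larger x_max, and the configured
direction carries the semantics. Directions default to increasing for
daylength, increasing for spring GDD, decreasing for the fall chilling
sum, and **increasing for VPD**: the calibration anchors the index near
0 at onset and near 1 at full canopy, and in climates where VPD rises
between greenup and maturity only an increasing ramp is consistent with
those anchors (the classic high-VPD-limiting convention is available
via `vpd_direction="decreasing"`, which simply reverses which end of
the calibrated ramp maps to 1). A degenerate calibration
(x_min ≥ x_max) raises an error naming the offending variable rather
than being silently repaired.

The central gating property — holding meteorology fixed, clearing snow
k days after the GSI 0.1-crossing delays the SGSI 0.1-crossing by
exactly k — is asserted for k = 0…20.

## Timing extraction

Snowmelt (spring) and snowpack onset (fall) come from least-squares
fits of a four-parameter logistic f(t) = c + (d − c)/(1 + e^((t−m)/s)),
0 ≤ c, d ≤ 1, to good-quality cover fractions over Jan–Jul
(decreasing) or Aug–Dec (increasing); the reported date is the
closed-form fractional day where the *fitted* curve crosses 0.1, not a
raw-data crossing. A year is rejected when the good-data record has a
gap longer than 14 days intersecting the ±14-day window around the
crossing; the window width is a documented reading of "around the
event" and is configurable in the source. Fits are deterministic (no
random restarts).

Index timings are first upward crossings of 0.1 and 0.5 with linear
interpolation between days. Flux timings use a cubic smoothing spline
with generalized cross-validated smoothing (`lam` overridable): the
source–sink transition is the first spring upward zero-crossing of
smoothed daily NEP (NEP = −NEE, positive = sink) followed by at least
7 consecutive positive spline days — the sustained-positivity guard
skips transient spring spikes, since nothing in the underlying
procedure says how multiple crossings are resolved; half-max
productivity is the first upward crossing of half the spline's annual
GPP maximum. Crossing extraction is translation-equivariant and every
returned date brackets the threshold in the fit.

## Trend inference

Mann–Kendall S uses the exact tie-free null distribution (inversion
count recursion) for n ≤ 10 and the tie-corrected normal approximation
with continuity correction otherwise; Spearman's ρ is computed against
year. The point trend is the OLS slope of timing on year, ×10 for days
per decade; Sen's slope is offered because the plain "trend" of a
resampled timing set admits either reading. Confidence intervals are
percentile intervals (not BCa) over 3000 parametric bootstrap sets,
each redrawing every year's timing from Normal(observed, 3σ/3) with
the stated 3-sigma uncertainty (defaults 6.6 d for snowmelt, 10 d for
greenup timings). Years with rejected timings are dropped
(complete-case) before fitting. The coverage of this interval against
a zero-trend truth is itself measured in the acceptance suite (93–97%
band over 400 replications).

## Stepwise NEE regression

Daily growing-season NEE is regressed on T, VPD and PAR with all seven
main-effect and interaction candidates. Forward selection admits, at
each step, the candidate with the smallest partial p-value below 0.05;
there is no removal step, hierarchy is not enforced (the candidate set
lists all terms symmetrically), and p-ties break on fixed candidate
order, making selection invariant to row ordering. Rank-deficient
additions are skipped with a warning. The null false-entry rate of
this machinery is checked against an independently simulated
family-wise chance level, P(min of the seven marginal p-values < 0.05).

## Effect analysis

Years enter the deviation regressions only if (a) their weekly mean GSI
(Jan-1-anchored 7-day blocks, growing-season weeks) stays within ±1 SD
of the across-year weekly mean, and (b) their greenup date lies within
1 SD of the mean greenup date (strictly-greater deviations excluded;
the SD is computed over all study years before any met screening).
The week quantifier is configurable: the library default demands every
GS week, the pipeline default demands 90% of them — with ~26 GS weeks
the all-weeks rule retains almost no year of a realistic 18-year
record, while the 90% rule retains roughly half, matching the retention
a practitioner would expect from this screening.

Seasonal values are totals for fluxes (g C m⁻² per season) and means
for state variables; seasons are GS (May–Oct), early (May–Jun), peak
(Jul–Aug) and late (Sep–Oct). The regression is ordinary least squares
of seasonal deviations on timing deviations over retained years, with
two-sided p-values from the t-transform of Pearson r and effects
reported as slope × 10 ("per 10 days"). The gated/ungated differencing
regresses the per-year difference of each variable between SGSI- and
GSI-driven runs on the snow-imposed delay, defined as
(first day SGSI > 0.1) − (first day GSI > 0.1), floored at 0, over
rows with positive delay.

## Synthetic sites and the flux emulator

The generator produces what the analysis consumes, with the simplest
mechanisms that preserve the causal structure under study:

* temperature: sinusoid peaking mid-July plus AR(1) noise (ρ = 0.7,
  sd 2 °C by default; sd 0 gives a noiseless climate);
* precipitation: Bernoulli(0.35)-gamma events, seasonally weighted so
  Nov–Apr receives the configured winter fraction — snowmelt timing
  therefore responds to winter precipitation and spring temperature;
* radiation: clear-sky solar geometry attenuated by an autocorrelated
  cloudiness series through the same R = R₀(1 − 0.75 n³·⁴) relation the
  analysis inverts; VPD from the saturation deficit at the generated
  temperature under a fixed seasonal relative-humidity climatology;
* snowpack: single-layer degree-day model (melt factor
  2.5 mm °C⁻¹ d⁻¹), cover fraction min(1, SWE/20 mm), optional random
  quality degradation for gap-rule testing;
* phenology dates: thermal-sum rules (greenup/maturity from the spring
  GDD sum at 120/300 °C d; senescence/dormancy from the fall chilling
  sum at 350/900 °C d), chosen to place greenup in the observed DOY
  130–145 range for the default climate;
* fluxes: LAI = LAI_max × index; GPP = A_max × LAI × light ×
  temperature × VPD factors; Ra = 0.45 GPP; Rh = Q10 curve of a
  snow-insulated surface soil temperature × a bucket-moisture factor;
  NEP = GPP − Ra − Rh and NPP = GPP − Ra hold exactly by construction,
  and the water bucket conserves mass to 10⁻⁶ mm.

Evapotranspiration and the soil states depend only on meteorology and
snow, so paired runs sharing forcing have identical Rh when snow
insulation is off; the net-uptake cost of a gated canopy day is then
exactly (1 − ra_frac) × GPP. `calibrate_uptake` exploits this to give
the emulator a *known* sensitivity: it rescales A_max so the mean daily
net canopy uptake over the 15 days following each year's gated onset
equals a target β (g C m⁻² per day of delay). The calibration
deliberately uses the mean daily uptake, not an inversion of the
delay-regression itself, so the end-to-end recovery of β by the
differencing machinery remains a genuine test; it succeeds to within
~10% because the seasonal ramp of the response factors makes per-day
uptake only approximately constant across the delay window.

What the generator does **not** emulate: sub-daily variability,
energy-balance snow physics, permafrost/active-layer dynamics,
multi-species canopies, observation error structure of satellite
products beyond simple missing-data flags, and flux-tower gap-filling
artefacts. Passing tests therefore demonstrate that the analysis chain
is correct and well-calibrated on data whose generating process is
known — not that real tundra sites obey the emulator's simplifications.

## Problem sizes and numerics

The test and acceptance runs use 6–18 year sites, 500-seed Monte Carlo
batches for timing recovery, 400 × 3000 resamples for bootstrap
coverage, and 16 imposed delays for the paired-run recovery — sizes at
which every stochastic tolerance in the suite is stable across seeds.
Logistic fits bound the scale parameter away from zero and clip the
exponent to avoid overflow; spline roots are refined by bisection
between daily grid points; all fractional dates are reported to 0.1 d
while test comparisons use whole-day tolerances. Every random draw in
the package flows through an explicit `numpy` generator seed, and
identical configurations reproduce outputs bit-for-bit.
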