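# Methods

## Hydroperiod computation

The water-level substrate is a regular grid (default 6-minute spacing) of
levels in metres on a declared vertical datum; the analysis refuses to mix
datums. A plot is inundated at a sample iff `level > elevation` — strict
exceedance, with exact ties counted dry. Ties are measure-zero in real gauge
data; fixing the convention makes results bit-for-bit reproducible. Each
sample represents its own interval, so annual hours are
`(#wet samples) × interval/60` with no interpolation of crossing times; that
matches the behaviour of a sample-scanning macro, and sub-interval crossing
refinement is deliberately not the default. Events are maximal consecutive
runs of wet samples.

Missing samples (gaps in the record, or years only partly covered by the
series span) count as *not* inundated and break events. Coverage — the
fraction of the calendar year's expected samples that are non-missing — is
reported on every summary, and a warning is raised below 95%. Percent of
year always uses the full calendar-year length (8760 h, 8784 h in leap
years) as denominator, never the covered length; with partial coverage the
two readings are distinguishable because coverage is carried alongside. A
year with no data at all yields a summary with coverage 0 and missing
metrics rather than an error, so multi-year tables keep their shape.

Plot elevations are treated as static across all years, as in monitoring
designs surveyed once mid-record with RTK-GPS.

MHHW is the mean over 24.84-h tidal days of each day's highest water; the
partition starts at the epoch start and a trailing partial tidal day is
dropped. Monthly mean sea level is the mean of non-missing samples per
calendar month; seasonal adjustment subtracts each calendar month's
long-term mean and restores the grand mean (≥ 24 months required).

## Statistical stages

**Plot-level trends.** OLS with calendar year as the continuous predictor,
centered internally (the slope is invariant to centering). Porewater fits
use the monthly replicate means as within-year replicates (n = 44 per plot
over 11 years × 4 growing-season months) — acknowledged pseudo-replication,
kept because it reflects how such monitoring series are analysed in
practice; inundation fits use the 11 annual totals. The slope t test is
two-sided; slopes with p < α (default 0.05) are reported as rates of
change. No multiple-testing correction is applied across plots by default
(a Benjamini–Hochberg option exists at the call sites via the returned
p-values). Conventions: a constant response returns slope 0, r² 0, p 1;
fewer than 3 points or constant x is an estimation error.

**Zone × year mixed model.** Response is the natural log of concentration;
zero or negative concentrations are a hard error naming the offending rows —
no silent offsets (the generator's detection floor keeps synthetic values
positive). Fixed effects: zone, year (two-level categorical: first and last
sampling year) and their interaction; random intercepts for year and for
month nested within year, REML. Because year is also a fixed effect, its
random-intercept design is contained in the fixed-effect span and the REML
criterion is flat in the year variance; the identified solution pins that
component to 0, and the month-within-year intercept (one level per
year:month cell) plus the residual are estimated with statsmodels MixedLM.
With a single month per year the month component is likewise boundary-pinned
and the fit reduces to OLS with the unbiased residual variance — this is the
fixed-effects limit the tests exercise against a two-way ANOVA oracle.

Inference is by sequential (Type-I) F tests: the data are whitened with the
estimated marginal covariance and term sums of squares are accumulated in
the order zone, year, zone:year; the denominator mean square is the whitened
residual mean square. Denominator DF follow a containment rule: terms
varying at the observation level (zone, zone:year) use
`N − (#year:month groups) − rank(observation-level fixed terms)`; year,
which varies at the month-within-year level, uses
`(#year:month groups) − (#years)` (= 6 for two years of four months).
Marginal and conditional R² follow the Nakagawa–Schielzeth decomposition
with the fixed-effect variance computed from the linear predictor
(sample variance, ddof 1); all variance components are non-negative by
construction, so marginal ≤ conditional always holds here.

**Rates vs rates.** OLS of plot-level nutrient slopes on plot-level
inundation slopes across plots, using *all* plot slopes whether or not the
individual trends reached significance; requires identical plot sets and at
least 3 plots.

**Monthly anomalies.** Deviation from the calendar-month climatology, with
an OLS trend on decimal year. For seasonally adjusted monthly *sea level*,
however, the trend regression uses integer calendar year as the predictor:
the seasonal adjustment removes all within-year structure, so a
month-resolution predictor would only add variance to x and attenuate the
slope by var(year)/(var(year)+var(month fraction)) ≈ 0.8% over 11 years.

## Synthetic generators

The generators define the study conditions the package validates itself
under; defaults are fixed once and shared by tests and the acceptance
script.

**Tide.** `level(t) = mean + β·t + s·sin(2πt/1 yr) + Σ aᵢ·sin(2πt/Tᵢ + φᵢ) + ε`,
ε ~ N(0, σ²), t in 365.25-day years from the record start, sampled every 6
minutes on real calendar timestamps (leap years honoured). Defaults:
mean 0.10 m NAVD88; constituents M2-like (0.65 m, 12.42 h), S2 (0.10 m,
12.00 h), diurnal (0.08 m, 23.93 h); trend β = 13.2 mm/yr (the 2009–2019
rate the record emulates); seasonal amplitude 0.10 m; σ = 0.05 m; span
2009-01-01 … 2019-12-31. These amplitudes give annual flooding fractions of
roughly 1.5% (high marsh) to 50% (creekbank) and inundation rates of change
of ~3–95 h/yr per yr across the elevation span — the observed orders of
magnitude. A purely harmonic tide lacks spring–neap modulation, storm
surges and meteorological set-up, so mid-marsh flooding percentages run
somewhat high relative to field values; the analysis stages are insensitive
to this since they condition on whatever hydroperiod is realized.

**Marsh.** Segment A: 3 transects × 9 plots, elevations linear from 1.09 m
(forest) to −0.467 m (creek), ~255 m long, zones low/mid/high split at 0.45
and 0.75 m. Segment B: 3 × 8, 1.117 → −0.255 m, ~100 m, a single boundary
at 0.95 m and no mid zone (its high marsh is a thin fringe). Interior plot
elevations get N(0, 0.02 m) jitter; endpoints are pinned so each transect
spans its range exactly. Totals 51 plots — the per-transect split (27 + 24)
is one consistent reading of a design whose exact per-transect counts are
not recoverable; zone assignment is by elevation threshold alone, a
machine-reproducible stand-in for elevation-plus-vegetation classification.

**Porewater.** For each plot × year × month × replicate:
`conc = baseline(zone) + (γ·r_p)·(year − 2009) + month effect + N(0, σ_zone²)`,
truncated below at the detection floor (0.01 µM); salinity declines at
−1.0 psu/yr everywhere. Additive Gaussian noise with floor truncation is
the simplest model consistent with analysing untransformed rates; real
porewater concentrations are right-skewed and heteroscedastic beyond the
per-zone σ used here. r_p is the plot's inundation rate of change, so
nutrient trends are coupled to hydrology by construction. The couplings γ
default to calibration at generation time: γ = target / mean(low-marsh
r_p), making the mean low-marsh trend equal the configured targets —
8.96 µM/yr (NH₄) and 0.86 µM/yr (PO₄) — for whatever tide realization is
in play. Baselines (NH₄ 55/28/15, PO₄ 5.3/2.8/1.5 µM, salinity 30/33/35 psu
for low/mid/high) and noise (NH₄ 15/8/5, PO₄ 1.0/0.6/0.4 µM, salinity
2 psu) sit in the observed low-vs-high marsh ranges; month effects are
small fixed seasonal offsets summing near zero. No spatial autocorrelation
between plots, no wrack disturbance, no year-level random shocks are
simulated — so recovery tests demonstrate estimator correctness under the
assumed model, not robustness to every field complication.

Determinism: every generator draws from `numpy.random.default_rng(seed)`;
identical seeds give bit-identical output. The pipeline derives stage seeds
from its single seed, and its manifest records a SHA-256 per output file.

## Recovery experiments and problem sizes

`run_nutrient_recovery` fixes one tide realization (hence one inundation
design and one calibrated coupling pair), then generates 100 independent
porewater datasets and averages the low-marsh OLS slopes over plots and
replicates; reported with the standard error across replicates. The truth
is the calibration target itself, so this checks the whole chain
(generation → monthly means → plot OLS → aggregation) end to end.

`run_msl_recovery` generates 20 independent 11-year records — constituent
phases drawn uniformly per record as well as the noise, because tidal
constituents alias into monthly means as a slow wobble; with fixed phases
every record would share one small deterministic trend offset, while over
random phases the (linear) trend estimator is exactly unbiased and the
across-seed spread reflects the aliasing. Each record yields a seasonally
adjusted monthly MSL trend in mm/yr.

Null calibration runs 21 porewater datasets × 51 plots with zero coupling,
zero month effects and no salinity trend — i.e. pure noise about the
baselines, the regime in which the t test's nominal size applies — and
checks the plot-level rejection rate against α = 0.05 with a 3σ binomial
band over the 1071 tests. With the default seasonal month effects left in,
the test is conservative (≈2–4% rejection) because balanced month effects
inflate the residual variance but not the slope's sampling variance.

These sizes (100 replicates, 20 records, 1071 null tests) were chosen so
the standard errors are small enough for a meaningful 3·SE comparison while
a full validation run stays in the tens of seconds on one core.

## Known limitations

- The harmonic tide omits spring–neap and meteorological variability; use
  `files` mode with a real CO-OPS export for real records.
- The mixed model fits exactly two comparison years; multi-year designs
  need the plot-level trend machinery instead.
- Containment denominator DFs are a convention; different mixed-model
  software assigns observation-level DFs differently (and reported field
  values additionally reflect missing data), so F tests agree across
  packages but p-values can differ slightly in unbalanced designs.
- Porewater trend fits treat monthly means as independent within-plot
  replicates; temporal autocorrelation within a season is not modelled.
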