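# marshflood

Tidal hydroperiod metrics and porewater nutrient trend analysis for
salt-marsh monitoring programs.

Accelerating sea-level rise is increasing how long salt-marsh platforms sit
under water, and porewater chemistry appears to respond: long-term monitoring
in a southeastern US *Spartina* marsh shows dissolved NH₄ and PO₄ rising
fastest in the plots whose flooding time is increasing fastest. `marshflood`
implements the full computational chain behind that kind of analysis, for
anyone running permanent-plot marsh monitoring against a nearby tide gauge:

1. **Hydroperiod** — scan a 6-minute water-level record (m NAVD88) for
   samples strictly exceeding each plot's surveyed elevation *z*; annual
   hours inundated are `H_py = 0.1 h × #{t in year y : w(t) > z_p}`, with
   event counts/durations, percent of year, and explicit data-coverage
   accounting. MHHW and monthly mean sea level (with seasonal adjustment)
   are included.
2. **Plot-level rates of change** — OLS of each response on calendar year
   (`x` = year): annual inundation hours (n = 11), or monthly replicate-mean
   NH₄/PO₄/salinity during the May–August growing season (n = 44). Slopes
   with *p* < α are the "rates of change"; `rate_grid` lays them out on the
   transect grid with non-significant cells masked.
3. **Zone × year comparison** — `log(conc) ~ zone * year` (first vs last
   year) with a random intercept for month nested within year, REML,
   sequential F tests with containment denominator DF, and
   Nakagawa–Schielzeth marginal/conditional R²:
   `R²_m = σ²_f / (σ²_f + Σσ²_r + σ²_ε)`,
   `R²_c = (σ²_f + Σσ²_r) / (σ²_f + Σσ²_r + σ²_ε)`.
4. **Rates vs rates** — cross-plot OLS of nutrient rate on inundation rate,
   using every plot's slope (no significance filter).

Because raw monitoring data of this kind are rarely public, the package
ships first-class synthetic generators with known ground truth: a harmonic
semidiurnal tide with a linear sea-level-rise trend (default 13.2 mm/yr),
two marsh segments × three transects of 9/8 plots (51 plots spanning
−0.467 … 1.117 m NAVD88, Segment B without a mid-marsh zone), and triplicate
monthly porewater samples whose trends are coupled plot-by-plot to the
realized inundation rates — calibrated so the mean low-marsh NH₄ and PO₄
rates are 8.96 and 0.86 µM/yr. Every stage is validated against independent
oracles and by parameter recovery on these generators.

The statistical stages are scikit-learn style estimators (`LinearTrend`,
`ZoneMixedModel`, `RateOnRateRegression`) with `fit` and fitted
`_`-suffixed attributes; the module-level functions wrap them.

## Worked example

```python
from marshflood import PipelineConfig
from marshflood.pipeline import run_pipeline

run_pipeline(PipelineConfig(seed=42, output_dir="demo"))
```

writes a tidy CSV bundle (`inundation_summary.csv`, `trends_*.csv`,
`rate_grid_*.csv`, `zone_model.csv`, `rate_relation.csv`, plus a manifest
with a SHA-256 per file). From `rate_relation.csv` of that run:

```
variable    slope  intercept      p_value  r_squared  n_plots
     nh4 0.128618   0.107105 3.785074e-49   0.988463       51
     po4 0.012471  -0.002855 4.816158e-59   0.995448       51
```

Each slope is (µM/yr) of nutrient increase per (h/yr per yr) of inundation
increase across the 51 plots: plots whose flooding time grows one hour-per-
year faster accumulate NH₄ about 0.13 µM/yr faster. Both relations are
strongly positive, as built into the generator's coupling. The zone model
output mirrors the usual mixed-model ANOVA layout; for PO₄ at Segment A in
the same run:

```
factor     num_df  den_df        F            p  marginal_r2  conditional_r2
zone            2     204  342.936 5.634796e-66     0.874394        0.885562
year            1       6  251.762 3.976255e-06     0.874394        0.885562
zone:year       2     204   20.881 5.618535e-09     0.874394        0.885562
```

The same chain is scriptable from a shell:

```sh
marshflood run --config study.yaml --seed 42 --out demo
marshflood inundate --water-level wl.csv --plots plots.csv --out inund.csv
```

with `simulate`, `trends`, `zonemodel` and `slopes` subcommands for the
individual stages, and a single YAML file for all configuration.

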