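# ozcrop

County-level crop yield and economic losses from gridded hourly surface
ozone, via the AOT40 cumulative exposure index and a linear
dose–response function — with paired-scenario differencing for
counterfactual emissions analyses.

## Who this is for

Surface ozone damages sensitive crops (soybean above all among the
major U.S. field crops). Air-quality models produce hourly O₃
concentration fields on regular grids under alternative emissions
scenarios; agricultural statistics are tallied per county. `ozcrop` is
the bridge: it turns two gridded hourly ozone scenarios plus county
polygons and county production into per-county exposures, relative
yield losses, bushel losses, dollar losses, scenario differences,
regional summaries and domain totals. A seeded synthetic generator
emulates all inputs (diurnal photochemical cycle, spatial correlation,
regionally signed scenario offsets of ±1–3 ppbV), so the whole pipeline
is testable end to end without any model output or agency download.

## The model

**Exposure.** For each grid cell, over a growing-season window (default
May 1 – Aug 1, all 24 hours):

    AOT40 = Σᵢ max(C_O₃(i) − 0.04, 0)    [ppmV·hr]

the accumulated exceedance of the hourly-mean ozone concentration over
a 0.04 ppmV (40 ppb) cutoff.

**Aggregation.** County AOT40 is the area-weighted mean of cell values,
with weight(c, cell) = area(polygon_c ∩ cell) / area(polygon_c ∩ domain).
Because AOT40 is a thresholded (nonlinear) functional, averaging
exposures and averaging concentrations first differ; both orders are
implemented (`aggregation_mode`), exposure-first is the default.

**Dose–response.** Relative yield loss is linear in exposure,
RYL = a · AOT40 with a = 0.0113 per ppmV·hr for soybean. Bushels lost
follow one of two conventions: *compensated* (default), which treats
observed production P as post-damage so loss = P·RYL/(1−RYL), or
*simple*, loss = P·RYL. Dollar loss is bushels × a fixed per-bushel
price (default $9.0075).

**Scenario analysis.** Two scenarios (e.g. a business-as-usual
counterfactual "BAU" vs the realised "C19" case) are differenced per
county (perturbed − reference); the report carries regional min/max
ranges, per-scenario totals, production-reduction percentages, the USD
production gain (price × bushel-total difference, bushels summed
first), and the shares of producing counties with increased vs improved
losses.

## Worked example

```python
from ozcrop import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(output_dir="example_run", seed=1))
print(report.regional.to_string(index=False))
print(report.totals_frame().to_string(index=False))
```

prints (abridged):

```
   region  delta_aot40_min  delta_aot40_max  delta_loss_bu_min  delta_loss_bu_max  n_counties
Northeast         0.000000         0.000000           0.000000           0.000000           6
  Midwest        -0.957570         0.000000     -162853.097285           0.000000          26
Southeast         2.596696         2.673543        3860.246376      336855.109214          32
Southwest         0.000000         0.000000                NaN                NaN           6
     West         0.000000         0.000000                NaN                NaN          10

                       quantity           BAU          C19
                  total_loss_bu  1.105797e+07 1.243768e+07
              reduction_percent  8.417009e+00 9.467206e+00
difference_in_reduction_percent -1.050197e+00          NaN
            production_gain_usd -1.242776e+07          NaN
```

This is the reference synthetic study: a −1 ppbV scenario offset over
the synthetic Midwest and +2.5 ppbV over the synthetic Southeast. The
regional rows give each region's range of county-level exposure change
(ppmV·hr) and bushel-loss change; regions growing no soybeans report
exposure only. `reduction_percent` is each scenario's total bushel loss
as a share of total production; the negative `production_gain_usd` says
the perturbation increased domain-wide losses — the Southeast ozone
increase outweighs the Midwest decrease. Counties outside either offset
polygon change by exactly zero because both scenarios share the same
noise realisation.

More narrative walk-throughs are in `examples/` (field generation,
AOT40, area weighting, full report). A thin CLI mirrors the stages:
`ozcrop synth | exposure | aggregate | impact | report | run`, each
accepting `--config config.yaml` and `--seed`.

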