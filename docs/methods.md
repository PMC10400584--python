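# Methods

## Scope and model

`ozcrop` implements an exposure-to-impact chain for ozone damage to a
county-tallied crop:

1. **Inputs.** Two hourly surface-O₃ concentration cubes on a shared
   regular grid — a reference scenario and a perturbed scenario — plus
   county polygons with a region label and production in bushels, and a
   per-bushel price.
2. **Exposure.** Per-cell AOT40: the sum over window hours of
   max(C − 0.04 ppmV, 0). An hour exactly at the cutoff contributes
   zero, so the ≥/​> distinction in the accumulation condition is moot.
   The default window is May 1 – Aug 1 with all 24 hours counted; a
   daylight-only variant (e.g. hours 08–20) is a configuration option,
   since vegetation standards often accumulate daylight hours only.
3. **Aggregation.** Exact polygon–cell intersection areas (shapely),
   normalised over each county's in-domain area, give an area-weighted
   county mean exposure.
4. **Dose–response.** RYL = a·AOT40 (a = 0.0113 per ppmV·hr, the linear
   soybean slope); loss in bushels by the compensated convention
   P·RYL/(1−RYL) by default (observed production is post-damage), or
   the simple convention P·RYL; dollars = bushels × price ($9.0075/Bu
   default).
5. **Report.** Per-county deltas (perturbed − reference), regional
   min/max ranges, per-scenario totals, reduction percentages against a
   reference production, the USD gain, and sign shares of producing
   counties.

## Key parameters

| parameter | default | units | notes |
|---|---|---|---|
| threshold | 0.04 | ppmV | AOT40 cutoff; reflects the anthropogenic ozone component, not a biological threshold |
| window | May 1 – Aug 1, 24 h/day | — | three-month growing season; half-open `[start, end)` |
| a | 0.0113 | per ppmV·hr | linear soybean dose–response slope |
| loss convention | compensated | — | P·RYL/(1−RYL); `simple` = P·RYL available |
| price | 9.0075 | USD/Bu | 2020 marketing-season soybean reference price |
| aggregation mode | exposure_first | — | county-average the per-cell AOT40; `concentration_first` averages hourly concentrations then accumulates |

The internal canonical concentration unit is ppmV everywhere; ppbV is
accepted at I/O boundaries and divided by 1000 on ingestion.

## The aggregation-order choice

County-averaging AOT40 and AOT40-of-the-county-average differ because
thresholding is convex: by Jensen's inequality the concentration-first
value never exceeds the exposure-first value (a property test asserts
this). Both readings are defensible descriptions of "average to the
county by area", so both are first-class; exposure-first is the default
because the exposure index is the quantity the dose–response consumes
and per-cell accumulation preserves subgrid exceedance structure.

## Loss convention

The compensated convention is the default because a dose–response
framework calibrated on relative yields implies the observed harvest is
the post-damage quantity; the simple convention is retained because
reduction percentages quoted as "loss over observed production" are
consistent with either. The two agree to first order in RYL
(relative gap = RYL/(1−RYL)); at the single-digit-percent RYL values
the default study produces, they differ by well under 10% of the loss.
RYL is capped strictly below 1 (at 1 − 1e-9, logged loudly) so the
compensated formula stays finite on degenerate inputs.

## Synthetic study conditions

The generator emulates the statistical structure of air-quality-model
output, not its chemistry or meteorology:

* **Diurnal cycle.** Sinusoid peaking at 15:00 with minimum at 03:00,
  mimicking photochemical ozone production.
* **Levels.** Baseline mean 0.038 ppmV, amplitude 0.012 ppmV, noise sd
  0.004 ppmV: a rural summer ozone climate whose 24-h seasonal AOT40
  lands at ~5–8 ppmV·hr per county and hence single-digit-percent RYL,
  the observed magnitude for the central/eastern U.S.
* **Spatial correlation.** White noise smoothed with a Gaussian kernel
  (default length 3 cells, wrap boundary) and rescaled so the marginal
  standard deviation equals the configured `noise_sd` exactly; only the
  correlation-length parameter is contractual, not the kernel shape.
* **Scenario offsets.** Constant ppmV offsets inside polygons, applied
  by cell-centre containment to the perturbed scenario only;
  overlapping polygons sum. The reference study uses −1 ppbV over the
  synthetic Midwest and +2.5 ppbV over the synthetic Southeast,
  matching the ±1–3 ppbV regionally signed structure of an
  NOₓ-emissions perturbation (rural NOₓ-limited areas lose ozone where
  emissions fall, gain it where they rebound).
* **Counties.** A rectilinear tessellation (10 × 8 in the reference
  study, snapped to cell edges; unsnapped layouts exercise fractional
  overlaps), five positional region labels, lognormal production
  (mean 2 × 10⁶ Bu, σ = 1) in the Northeast/Midwest/Southeast and zero
  production in the West/Southwest, mirroring where soybeans are not
  grown. A configurable fraction of producing counties can be marked
  "combined/withheld" (production unattributable): these are excluded
  from impact totals with a logged count.
* **Determinism.** One integer seed fixes both cubes bit-for-bit; the
  scenarios share the identical noise realisation, so the scenario
  difference is exactly the configured offset field wherever nothing
  was clipped.

What the generator does **not** emulate: chemistry-driven nonlinearity
(VOC- vs NOₓ-limited regime switching), meteorological variability
between scenarios, terrain, urban plumes, or true county geography.
Passing tests therefore demonstrate the correctness of the
exposure/aggregation/dose-response arithmetic and bookkeeping under
controlled conditions — not that any particular real-world impact
number is right.

## Numerical conventions

* Negative synthetic concentrations are clipped to 0 after perturbation
  (concentrations are physical), with a logged count; clipping can be
  disabled, in which case the mean-shift identity between scenarios is
  exact to 1e-12.
* Missing hours are rejected by default; an opt-in policy skips NaNs
  with a logged count and no rescaling — AOT40 is a sum, so gaps bias
  it low, and the policy keeps that bias visible rather than silently
  gap-filling.
* Domain totals use compensated (`math.fsum`) summation, so the domain
  total equals the sum of regional totals exactly, independent of
  grouping order. Money is computed bushels-first (sum, difference,
  then price-multiply) and reported at cent precision; internal
  arithmetic is full double precision.
* Area weights are exact geometric intersections on a planar frame.
  Geographic inputs must be projected to an equal-area planar CRS
  before weighting; the package does not reproject.
* Counties partially outside the grid are renormalised over the covered
  part and flagged via `coverage_fraction`; fully-outside counties get
  an empty weight row and are excluded (logged).
* Output CSVs print floats at 17 significant digits so round-trips are
  lossless and reruns are byte-identical.

## Problem sizes

The reference study runs a 30 × 24 grid for 92 days (2208 hours,
~1.6 M cell-hours per scenario) with 80 counties — about a second end
to end. Unit and property tests use 3 × 3 grids and 48-hour cubes; the
Monte-Carlo area-weight oracle uses 10⁵ points per polygon on 20 random
polygons. These sizes were chosen to make every stage's oracle cheap to
evaluate while keeping the seasonal AOT40 magnitudes realistic.

## Known limitations

* The linear dose–response is crop-specific (soybean) and unbounded in
  AOT40 below the cap; exposures far outside the calibration range are
  flagged only by the cap log.
* Scenario differencing assumes both cubes share grid, window and
  county universe; no interpolation between mismatched grids.
* The five-region scheme is a label, not a geography; real analyses
  should supply their own county→region map.
* No plotting beyond what the CSVs support; choropleth rendering is out
  of scope.
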