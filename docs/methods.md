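# Methods

This note documents the scientific choices behind `lakefcc`: the models it
implements, the parameters that matter, what the synthetic data does and
does not emulate, and the numerical conventions.

## Primary production (VGPM)

Daily production is `PP = 0.66125 · PBopt(T) · E0/(E0+4.1) · Zeu · Chl ·
Dirr`. `PBopt` is the published seventh-order polynomial in surface
temperature with its constant clamps: 1.13 mg C (mg Chl)⁻¹ h⁻¹ below −1 °C,
4.00 above 28.5 °C, zero below −10 °C. The published clamps are *not*
continuous with the polynomial (it evaluates to 1.1055 at −1 °C and 4.0231
at 28.5 °C, i.e. ~2.2% and ~0.6% jumps); we keep the piecewise form exactly
as published rather than smoothing it, and the tests assert the clamp
values and bounded jumps instead of continuity.

The euphotic depth is `Zeu = ln(100)/KdPAR`, with the default broadband
relation `KdPAR = 0.0665 + 0.874·Kd490 − 0.00121/Kd490` (any callable can
replace it, since only the author of the relation, not its exact form, is
fixed by the source literature). `Zeu` is capped at the lake depth (20 m
default) so no production is credited below the lakebed. Daylength comes
from standard solar-declination geometry (valid below 66.5° latitude);
the external photoperiod archive the original workflow used is replaced by
this astronomical computation.

Monthly production evaluates the VGPM on the monthly composite inputs with
the mid-month daylength and multiplies by days-in-month (composite-first,
matching the monthly-composite framing of the processing chain), rather
than averaging per-day production.

## Quality control

* **Unified lake mask**: minimum water extent over the whole archive; the
  excluded fraction of ever-wet cells is reported as a diagnostic.
* **Valid pixel-day**: retrieval flags = 0, straylight risk < 5%, ice = 0.
* **Monthly composite**: per-cell mean over valid days, requiring ≥ 5 valid
  days (configurable; the statistic can be switched to median). Undefined
  is always NaN, never 0 — zero is a legal chlorophyll value.
* **Gap-fill**: per-cell linear interpolation in time, interior gaps only
  (no extrapolation of leading/trailing gaps, no spatial interpolation),
  and only for cells whose missing fraction is below 10%. The "< 10%"
  rule is applied per pixel; a lake-wide reading is also defensible, and
  the choice is surfaced here deliberately.
* **Matchups**: median of a pixel box centred on the station (default 1
  cell on the 1 km grid, 3×3 available for sub-pixel stations), valid
  within ±12 h when box SD/mean < 20% (population SD).
* **Chlorophyll correction**: reduced-major-axis (type II) regression of
  field on satellite values, on untransformed data, fit on the
  chronologically earliest fraction of matchups so calibration and
  validation do not overlap in time. The corrected value is clipped at 0.

## Trophic conversion and the index

`Net FPP = Net PP · aⁿ · (P/B)/E`, with the mg C → g fresh-weight chain
made explicit: carbon converts to energy via `kj_per_mgc` (default 1 kJ per
mg C m⁻², a bookkeeping equivalence inherited from the source parameter
set — it mixes units, which is why it is exposed as its own named factor)
and energy to fresh weight via `E` [kJ/g]. The defaults `a = 0.10`,
`n = 2`, `P/B = 30` (plausible range 30–50), `E = 2.5` give the single
multiplicative factor 0.12. The rendering of the conversion formula in the
source is typographically ambiguous (operator precedence around `aⁿ` and
`P/B / E`); the canonical energy-transfer reading above is the default and
the whole factor is one configurable scalar, so alternative readings are a
configuration, not a fork. The index itself, `FCCI = FP/FPP`, is a ratio
and therefore independent of that interpretation whenever FP and FPP are
supplied externally.

Lake-wide aggregation uses the mean over *defined* cells times the full
lake area (the published aggregation formula), not the sum over defined
cell areas; the composite-coverage fraction is logged so users can judge
the extrapolation. In synthetic runs the lake area is tied to the
generated geometry so the two aggregation routes agree exactly.

Annual FCCI classification uses strict inequalities (> 0.5 high pressure,
< 0.3 underutilised, > 0.6 over benchmark, > 1.0 overexploited); boundary
values fall to the lower-severity class. For spatial maps, lake-wide FP is
allocated proportionally to a supplied density surface (uniform fallback),
an assumption the source workflow leaves unstated; the recommended release
zone is the largest 4-connected underutilised region.

## Monte-Carlo sensitivity

Parameters are drawn independently from `Uniform(baseline·(1−v),
baseline·(1+v))`, default v = 0.20 and 1000 iterations. The baseline FPP
series is inverted to its parameter-free carbon equivalent and
re-converted per draw, which is exact because the conversion is a single
multiplicative factor. Two designs are reported: one-at-a-time relative
RMSE per parameter (relative to baseline FPP, not the iteration mean), and
all-at-once exceedance probabilities `P(FCCI > 0.6)` per year, pooled, and
max-over-years — the aggregation behind a single published summary figure
is not stated, so all three are emitted. For a linearly-entering parameter
(P/B) the one-at-a-time RMSE has the closed form v/√3 (11.55% at v = 0.2),
which is the convergence oracle in the tests. Convergence is assessed on
nested batch prefixes (500/800/1000 by default): CV of batch means and
whether the final step moved the mean by < 0.5%.

Note that published per-parameter RMSE/exceedance tables for this kind of
analysis cannot be reproduced from an annual FP/FPP series alone (they are
internally inconsistent with any single functional form of the conversion
factor); they are therefore not used as test oracles.

## Synthetic data: what it emulates, and what it does not

The generator produces the *statistical structure* the pipeline assumes:

* chlorophyll = base level × (1 + shore gain · shore-distance ramp) +
  Gaussian estuary bumps, all modulated by a sinusoid peaking at
  day-of-year 200 (mid-July); multiplicative lognormal pixel noise
  (CV 0.25 default — a stand-in, since the true error distribution of
  lake chlorophyll retrievals is not established);
* surface temperature: smooth 0–25 °C seasonal curve plus 0.3 °C Gaussian
  noise; PAR: clear-sky solar geometry at 36.9° N; Kd490 = 0.08 +
  0.08·Chl, so estuaries have shallower euphotic depths;
* cloud/flag gaps: independent Bernoulli per pixel-day (fraction 0.15);
  straylight-risk pixels at 2%;
* August survey: gill-net lengths ~ truncated Normal(25 cm, 4 cm), weights
  `W = 0.01·L³` (a generic cyprinid power law; the source states none),
  and 40 transect-segment densities built from the biomass-closing base
  density times mean-one lognormal noise (CV 0.05), so the implied biomass
  equals the configured truth exactly at zero noise.

It does **not** emulate radiative transfer, real retrieval-algorithm error
structure, spatially correlated cloud, ice phenology, fish movement or
density-dependent growth. Passing tests therefore demonstrate that the
*processing chain* is correct (masking, counting rules, compositing,
model algebra, aggregation, recovery at known truth), not that the
physical retrievals themselves are accurate — that is what the matchup /
validation-statistics machinery is for when real data are supplied.
Synthetic FPP magnitudes are likewise not calibrated to the published
lake-wide totals; published-series computations go through the bundled
reference table instead.

## Numerical conventions and problem sizes

* Undefined values are NaN throughout; they propagate through VGPM and
  aggregation and are excluded from means.
* All randomness flows from integer seeds through `numpy` Generators;
  per-date streams are derived from (seed, year, day-of-year), so scene
  generation is order-independent and bit-reproducible.
* RMA regression takes `sign(r)·sd(y)/sd(x)`; zero variance raises.
* Default test and acceptance problem sizes — 8×8 to 20×20 grids, one to
  two years, 200–1000 Monte-Carlo iterations — were chosen as the smallest
  sizes at which every statistical check has comfortable margin (e.g.
  3 MC standard errors on the RMSE oracle); the library itself is
  vectorised and handles full-lake grids.

## Known limitations

* The bundled published series contains one internally inconsistent row
  (2017: the printed index differs from the printed FP/FPP quotient by
  5.02×10⁻⁵, just over half a fourth-decimal ULP); the package reports the
  recomputed quotient and does not patch the table.
* GeoTIFF export is plain single-band TIFF on the local metric grid; no
  CRS/geotransform metadata is written.
* The Kd490→KdPAR default is a broadband empirical relation valid for
  Kd490 ≳ 0.02 m⁻¹; extremely clear water should supply a custom relation.
* Gap-fill is temporal only; a cell missing in every month stays missing.
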