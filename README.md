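# lakefcc

Satellite-style assessment of how much fish a lake's primary production can
sustain, built for single-species fisheries such as the naked carp
(*Gymnocypris przewalskii*) fishery of Qinghai Lake, a ~4500 km², ~20 m deep
high-altitude lake whose open-water season runs May–October. The package
chains quality-controlled chlorophyll/temperature/light grids through a
primary-production model and a trophic energy-transfer chain to an annual
and spatial **Fish Carrying Capacity Index**, the quantity managers use to
decide where and how much restocking a lake can absorb.

## The model

Daily depth-integrated primary production per 1 km² cell follows the
Vertically Generalised Production Model (VGPM):

```
PP = 0.66125 · PBopt(T) · E0/(E0 + 4.1) · Zeu · Chl · Dirr      [mg C m⁻² d⁻¹]
```

where `Chl` is surface chlorophyll-a [mg m⁻³], `PBopt(T)` the published
7th-order polynomial in surface temperature (clamped to 1.13 below −1 °C and
4.00 above 28.5 °C), `E0` daily PAR [mol quanta m⁻² d⁻¹], `Dirr` the
astronomical daylength [h], and `Zeu = ln(100)/KdPAR` the 1%-light euphotic
depth (from Kd490, capped at the lake depth).

Monthly production converts to **fish potential production** through the
trophic chain

```
Net FPP = Net PP · aⁿ · (P/B) / E        [g fresh weight m⁻² month⁻¹]
```

with transfer efficiency `a = 0.10`, trophic level `n = 2`
(zooplanktivore), production-to-biomass ratio `P/B = 30` and energy content
`E = 2.5 kJ/g` (with the 1 kJ = 1 mg C m⁻² equivalence kept as an explicit,
overridable factor). Lake-wide **Gross Monthly FPP** [t] is the cell mean
times lake area ×10⁻⁶, and **Gross Annual FPP** is the May–October sum.

The observed fish population `FP` [t] comes from August hydroacoustic
surveys calibrated by gill nets (`TS = 19.1·log₁₀L − 0.9·log₁₀f − 62`;
`FP = mean density × mean weight × lake volume × 10⁻⁶`), and the index is

```
FCCI = FP / Gross Annual FPP
```

`FCCI ≤ 1` means the food-energy supply exceeds demand; `> 0.5` flags high
demand pressure, `< 0.3` an underutilised zone, and `0.6` is the empirical
benchmark above which fisheries have often tipped into overexploitation.
A Monte-Carlo module propagates ±20% uniform uncertainty in `(a, P/B, n, E)`
into FPP and the exceedance probability `P(FCCI > 0.6)`.

Because the MODIS archive and the field surveys are not redistributable,
a seeded synthetic generator reproduces the statistical structure the
pipeline assumes (shore-high/centre-low chlorophyll with estuary hotspots,
a mid-July seasonal peak, lognormal retrieval noise, cloud gaps, and
surveys that integrate to a known true biomass), so every stage is testable
end to end.

## Worked example

```python
from lakefcc import datasets, workflow

ref = datasets.load_reference_assessment()          # published 2002-2024 FP/FPP series
table = workflow.assess_from_series(ref[["year", "fp_t", "fpp_t"]])
print(table.tail(3).round({"fcci": 4}).to_string(index=False))
print(workflow.report(table))
```

prints

```
 year     fp_t    fpp_t   fcci        status
 2022 114100.0 264900.0 0.4307      moderate
 2023 120300.0 206540.0 0.5825 high_pressure
 2024 127500.0 244581.0 0.5213 high_pressure

Lake carrying-capacity assessment
years: 2002-2024 (n=23)
max FCCI: 0.5825 in 2023
years with FCCI > 0.5 (high pressure): 2
years with FCCI > 0.6 (over benchmark): 0
years with FCCI > 1.0 (overexploited): 0
trend: increasing
```

— the fish population has grown ~50-fold since 2002, the index is rising
but has never crossed the 0.6 benchmark, so production still leaves room
for strategic restocking.

The full raster pipeline runs from the shell:

```bash
lakefcc run --out out/ --seed 42          # synth -> qc -> pp -> fpp -> fp -> fcci -> sensitivity
lakefcc synth --out data/ --seed 42       # or stage by stage:
lakefcc qc --in data/scenes --monthly-out monthly/
lakefcc assess --fp fp.csv --fpp fpp.csv --out assessment.csv
```

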