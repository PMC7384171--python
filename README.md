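# pulsechase

Data reduction for continuous, chamber-based **¹³CO₂ pulse-chase
experiments** on grassland soil: from raw isotopologue concentration
streams to calibrated fluxes, tracer budgets and treatment statistics.

The package is written for ecosystem scientists who label plant canopies
with ¹³CO₂ and then trace the label through belowground respiration with
steady-state flow-through chambers multiplexed to an isotope laser
analyzer. It implements the complete processing chain such experiments
need, and ships a synthetic-data generator (with analytic ground truth)
emulating a drought/rewetting experiment so that every stage can be
validated end to end without field data.

## The processing chain

1. **Calibration** — periodic three-gas cycles (400 / 1,500 / 5,000 ppm
   CO₂ of known isotopic composition) are fitted per isotopologue as
   span–offset lines, `true = span · measured + offset`, and applied with
   time interpolation between cycles (valid ranges 400–5,000 ppm ¹²CO₂,
   4–50 ppm ¹³CO₂).
2. **Segmentation** — each measurement is 250 s at a chamber outlet framed
   by two 100-s inlet (buffer) windows; a configurable dead band discards
   line-switch transients and each window is summarised as mean ± SD.
3. **Fluxes and isotope mixing** — per measurement:

       SR      = f · (CO₂_out − CO₂_in) / A                 (soil respiration)
       χ(¹³C)  = ¹³CO₂ / (¹³CO₂ + ¹²CO₂)                    (atom fraction)
       χ_SR    = (χ_out·CO₂_out − χ_in·CO₂_in) / (CO₂_out − CO₂_in)
       χE_SR   = χ_SR − χ_SR(NA)                            (tracer excess)
       abs¹³C  = χE_SR · SR                                 (tracer efflux)

   with `f` the molar chamber flow, `A` the chamber footprint, and
   χ_SR(NA) the pre-label natural abundance. Uncertainties propagate by
   first-order Taylor expansion; observations with negative SR or χE, or
   a coefficient of variation above 1, are excluded.
4. **Alignment and budgets** — per-monolith series are fitted with lightly
   penalised smoothing splines, predicted on a common 2-h grid (gaps
   longer than 6 h stay masked), and cumulated by the trapezoid rule with
   linear gap bridging (optionally a replicate-mean rule for long gaps).
   Each cumulative value carries a 1,000-draw Monte-Carlo uncertainty.
5. **Partitioning and kinetics** — cumulative tracer efflux divided by the
   monolith's total ¹³C uptake U gives rel¹³C, the fraction of recent
   photoassimilates respired belowground; a single-exponential fit to a
   dark-pulse efflux series gives the mean residence time of physically
   back-diffusing label.
6. **Statistics** — two-way (drought × land use) ANOVA F values plus exact
   p-values from a permutation scheme (restricted label permutation for
   main effects, residual permutation for the interaction; full
   enumeration when feasible).

## Worked example

```bash
python examples/03_cumulative_budgets.py
```

runs the full pipeline on the default synthetic campaign (12 monoliths,
~325,000 analyzer rows) and prints, among other output:

```
co2 over the 120-h chase (mol CO2 m-2):
  abandoned  control:   0.8376 ± 0.0267 (n=3)
  abandoned  drought:   0.4390 ± 0.0371 (n=3)   drought vs control: -47.6%
    managed  control:   1.1268 ± 0.0298 (n=3)
    managed  drought:   0.5381 ± 0.0196 (n=3)   drought vs control: -52.2%
```

The generator suppresses drought-treated soil respiration by 50%; the
pipeline recovers a 47.6% / 52.2% reduction in the cumulated 120-h CO₂
efflux from the noisy raw streams — the deviation from 50% reflects
between-replicate biological variability at n = 3. The same run yields
rel¹³C around 0.10: roughly a tenth of the assimilated label is respired
belowground within five days. The other examples show the calibration and
flux chain row by row, the dark-pulse mean-residence-time fit
(`23.4 min` fitted vs 23 min true), leachate DO¹³C accounting, and the
permutation ANOVA.

A thin CLI wraps the same functions: `pulsechase simulate`,
`pulsechase process`, `pulsechase report` (see `pulsechase --schema` for
the delimited-text schemas).

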