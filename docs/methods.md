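# Methods

This note documents the models, numerical choices and limitations behind
`pulsechase`. It complements the README's overview of the processing
chain.

## Chamber flux model and its assumptions

Steady-state flow-through chambers are flushed at constant volumetric
flow; the soil CO₂ efflux follows from the inlet–outlet concentration
difference,

    SR = f_molar · (CO₂_out − CO₂_in) / A        [µmol CO₂ m⁻² s⁻¹],

assuming (i) steady state within each 250-s outlet window, (ii) perfect
mixing in the chamber headspace, and (iii) dry-air mole fractions (no
water-vapour or pressure-broadening corrections; these belong upstream of
the package). The volumetric flow read by a mass-flow meter is converted
to molar flow at configurable reference conditions, by default 273.15 K
and 101.325 kPa (22.414 L mol⁻¹), because mass-flow meters report at
their calibration reference.

Isotopic source partitioning uses two-member mixing between inlet air and
the soil source in **atom fractions** (χ = ¹³CO₂/(¹³CO₂+¹²CO₂)), which
remains linear at tracer-level enrichments where δ-notation becomes
unsafe. Total CO₂ is taken as ¹²CO₂ + ¹³CO₂; rarer isotopologues are
ignored. The mixing solution is a ratio with the chamber gradient in the
denominator, so a minimum gradient (default 5 µmol/mol) is enforced:
below it the observation is marked `invalid_input` rather than producing
an unstable value. Solutions may legitimately lie outside
[χ_in, χ_out] (the source is an endmember) but are flagged when outside a
sanity interval [−0.1, 1.1].

## Calibration

Each calibration cycle (three gases, roughly every 2 h) is fitted as an
ordinary least-squares line per isotopologue with the *true* value
regressed on the *measured* one, so application is a single affine map.
Between consecutive cycles the span and offset are interpolated linearly
in time — this bounds instrument drift while degrading gracefully to
per-cycle constants — and the nearest curve applies outside the bracket.
Records farther than a staleness horizon (default 6 h) from any cycle are
flagged uncalibrated and left untouched. A `calibrated` flag guards
against double application, which would silently re-scale the data.

## Uncertainty propagation

Standard deviations propagate through each expression by first-order
Taylor expansion with independent inputs (covariances set to zero; each
measured variable is propagated independently). The uncertainty assigned
to a window mean is its **standard error** (sample SD / √n): the measured
variable entering the flux and mixing equations is the mean itself. The
first-order approximation is accurate in the regime the QC filter
retains: the package's tests require agreement with 10⁶-draw Monte-Carlo
references within 5% whenever all input CVs are ≤ 0.2 (2% at CVs ≤ 0.1).

QC applies the negativity and CV > 1 rules **per variable**: `qc_sr`
gates the respiration series and `qc_tracer` the tracer series, with the
overall `qc` the more severe verdict. A single combined verdict would let
low-enrichment (high tracer-CV) periods mask perfectly good respiration
measurements — late in the chase this bridges the cumulative CO₂ integral
across the rewetting pulse and biases it upward. The CV boundary is
strict: exactly 1 is retained.

## Temporal alignment and budgets

Chambers are multiplexed sequentially, so replicates never share
timestamps. Each per-monolith series is fitted with a penalised cubic
smoothing spline (`scipy.interpolate.make_smoothing_spline`); the default
penalty λ = 10⁻³ on an hours-scale time axis is light enough that a
noise-free diel sinusoid is reproduced with RMSE < 0.02 while analyzer
noise is damped. With fewer than 4 points the series falls back to linear
interpolation (flagged); λ = 0 or exactly 4 points give an interpolating
cubic. Predictions are emitted on a regular 2-h grid only where the
bracketing observation gap is ≤ 6 h (boundary inclusive) and never
outside the observation span — splines fill short gaps but do not
extrapolate. Per-grid-point uncertainty is the propagated sd of the
nearest raw observation: splines smooth values, not uncertainties.

Cumulative budgets use the trapezoid rule; masked runs inside a window
are bridged linearly between flanking supported points and the bridged
share is reported as `fill_fraction`. A long gap can instead be filled
with the mean cumulative **increment** of the other treatment replicates
over the same window; the increment is stored on the series (points
marked `gap-filled-replicate`) so integration reproduces the replicate
mean exactly — assigning synthetic point values could not guarantee that.
Monte-Carlo uncertainty redraws each supported grid point independently
from N(value, sd) (n = 1,000 by default, seeded) and integrates every
draw; temporal error correlation is not modelled, which makes the MC
spread an upper bound under positively correlated errors over
sub-grid timescales.

## Kinetics and partitioning

The dark-pulse back-diffusion model is a single exponential
r(t) = r₀·e^(−kt) fitted by nonlinear least squares, initialised from a
log-linear regression on the positive values; MRT = 1/k. Multi-pool decay
models are out of scope for this fit — the dark pulse isolates one
physical process. Non-convergence (or k ≤ 0, e.g. a flat series) raises
an error carrying the log-linear fallback rather than returning a
meaningless fit.

rel¹³C divides the cumulated tracer efflux by the monolith's total ¹³C
uptake U (shoots + roots), which is an **input**; the package never
computes U. Group summaries report replicate mean ± SD and the percent
change of drought versus control within land use,
100·(1 − drought/control), positive meaning a reduction under drought.

## Treatment statistics

Classical two-way ANOVA F values (balanced sums of squares; equal to a
least-squares reference to 10⁻¹⁰ on balanced designs) are reported as
effect sizes. Exact p-values come from permutation: main effects permute
the tested factor's labels within levels of the other factor; the
interaction permutes residuals of the additive least-squares fit
(Freedman–Lane). When the number of distinct arrangements is ≤ 20,000 the
null distribution is enumerated (identity included, p = count/total,
resolution 1/total — with 3 replicates per cell the strongest possible
main effect gives p = 2/400 = 0.005); otherwise n_perm arrangements are
sampled and p = (1 + count)/(1 + n_perm), which cannot be zero. Ties are
counted with a relative tolerance of 10⁻⁹ on F. All-equal responses make
F a 0/0; they are returned as 0 with a degenerate flag. Mixed-effect
models for repeated leachate samplings are deliberately not implemented
(standard packages cover them).

## The synthetic-data generator

The generator is the package's test bed: it emulates the structure of a
drought/rewetting pulse-labelling campaign and emits raw streams plus a
ground-truth record the pipeline never consumes.

Per monolith, true soil respiration is

    SR(t) = B · m(t) · (1 + a_d·cos(2π(t − t_peak)/24 h)) · birch(t)

with baseline B (2.5 / 2.0 µmol m⁻² s⁻¹ for the managed / abandoned
grassland, jittered per monolith by a lognormal with σ = 0.08 as a
realistic between-monolith replicate variability), diel amplitude
a_d = 0.4 peaking at 13:00, drought multiplier m = 0.5 while the drought
lasts, and a rewetting (Birch) pulse `1 + (P−1)·e^(−Δt/τ)` with P = 3 and
τ = 12 h so the pulse decays within ~2 days. Diel amplitudes are damped
to 5% under drought (drought series show no distinct diel fluctuation).

True tracer efflux follows two-pool first-order kinetics scaled by an
asymptotic respired fraction:

    r¹³(t) = U · F · (w_f·k_f·e^(−k_f·s) + w_s·k_s·e^(−k_s·s)) · ramp(s) · diel(t)

with s the time since labelling, w_f = 0.7, k_f = 1/12 h⁻¹,
k_s = 1/96 h⁻¹, and F = 0.12 chosen as the midpoint of the observed
7–19% range of 120-h fractions — the pool weights alone (summing to 1)
would imply ~91% of U respired, which no grassland shows. The onset is a
smooth exponential ramp reaching ~95% at 1.5 h after labelling:
physically, label diffuses gradually through the soil column, and a step
onset would also be impossible to integrate to the package's closure
tolerance from 2-h-gridded data. Drought monoliths additionally release a
small remobilised fraction (1.5% of U, τ = 12 h) at rewetting, so the
rewetting window respires more residual label than controls. Uptake U
defaults to 400 mg ¹³C m⁻² for controls with drought reductions of −30%
(managed) and −15% (abandoned) at peak drought.

Chamber concentrations are reconstructed by inverting the flux and mixing
equations, distorted by the inverse instrument calibration (span 0.98 /
offset 5 µmol/mol for ¹²CO₂; 1.01 / −0.05 for ¹³CO₂), sampled on the
100/250/100-s multiplexed protocol with three-gas calibration cycles
every sweep, and degraded with Gaussian analyzer noise of 0.200 / 0.010
µmol/mol per sample (¹²CO₂ / ¹³CO₂). Scenario combinations implying an
outlet atom fraction outside [0, 1] are rejected with a diagnostic. All
randomness flows from a single seed; identical seeds give byte-identical
outputs. Truth integrals are computed by adaptive quadrature of the
closed-form rates with breakpoints at the schedule discontinuities —
independent of the pipeline's spline/trapezoid path.

What the generator does **not** emulate: soil-moisture dynamics, real
spectra or vendor formats, temporally correlated analyzer drift beyond
the affine distortion, leachate hydrology (leachate tests use constructed
samples), and canopy photosynthesis (U is assigned, not simulated).
Passing tests therefore demonstrate the correctness of the data
reduction, not the realism of any ecological inference from real data.

## Problem sizes and numerical choices

The default campaign simulates ~228 h at a 2-h measurement cadence for 12
monoliths (~325,000 analyzer rows) and processes in well under a minute.
Generator/pipeline closure tests use a noise-free scenario at 0.25-h
cadence and grid, where the whole chain reproduces true SR to 10⁻⁶
relative and the true 120-h tracer fraction to 10⁻³ (trapezoid error at
the default 2-h grid is O(h²) ≈ 2·10⁻³ at the onset kink, which is why
closure is defined at dense cadence). The permutation type-I-error check
uses 500 null datasets; the MRT bias check uses 500 replicate fits; both
are seeded and deterministic. Timestamps are UTC with half-open windows
[start, end); the 2-h/6-h/120-h/72-h defaults, QC thresholds,
calibration staleness, MC draw count and permutation settings are all
surfaced in `RunConfig` and serialised into every run directory.

## Known limitations

- The 72-h rewetting window is one published description of the
  rewetting cumulation period; another table header says 70 h. The
  default is 72 h and configurable.
- Natural abundance must be estimable from pre-label data (default: the
  48 h before labelling); it is never defaulted, so a campaign without
  pre-label coverage fails loudly.
- The permutation scheme is a fixed-n, documented standard; published
  analyses using sequential-stopping permutation packages will not match
  its p-values numerically.
- CO₂ cumulative totals are reported in mol m⁻², tracer totals in
  mg ¹³C m⁻², rel¹³C as a fraction; unit conversions happen at the
  pipeline boundary (3600/10⁶ for µmol s⁻¹ → mol h⁻¹ grids).
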