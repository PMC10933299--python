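# Methods

This note documents the models implemented in punctakit, the conventions
and defaults chosen where the underlying assays leave them open, what the
synthetic-data generators do and do not emulate, and the numerical choices
that matter for reproducing results.

## FRAP recovery model and granule physics

A granule region of interest (ROI) is photobleached and imaged on a fixed
schedule — by default every 5 s for the first minute and every 10 s for the
following four minutes, with the first post-bleach frame defining t = 0 and
pre-bleach frames carrying negative times.

**Normalization.** When a whole-granule channel is available, the
per-timepoint ratio bleached/whole is formed first; this cancels
acquisition photobleaching of the granule as a whole. The series is then
mapped affinely so the mean of the pre-bleach samples is 1 and the first
post-bleach sample is 0. The map is order-preserving and idempotent. A
trace whose pre-bleach mean equals its first post-bleach value has no
bleach depth and is rejected rather than divided by zero.

**Fit.** Recovery is modelled as a single exponential,
`y(t) = A·(1 − e^(−τt))`, with mobile fraction `A ∈ [0, 1.5]` (granules can
mildly overshoot their pre-bleach ratio) and rate `τ ∈ (0, 10] s⁻¹`, fit by
bounded nonlinear least squares. Initialization: `A₀` is the maximum of the
last three samples; `τ₀ = ln 2 / t*` where `t*` is the first time the
series reaches `A₀/2`. Solver tolerances are set so a noiseless model trace
is recovered to better than 1e-6 relative error. An all-zero series leaves
τ unidentifiable and raises an error instead of returning a boundary
value. The reported mobile fraction is the fitted plateau `A`, not the last
observed sample. Multi-exponential and reaction–diffusion recovery models
are deliberately out of scope.

**Derived quantities.** `t½ = ln 2 / τ` (the product `t½·τ` is ln 2 to
machine precision because t½ is computed from τ). The effective diffusion
coefficient uses the circular-spot approximation `D = 0.88·r²/(4·t½)` with
the bleach ROI radius r (default 3.7 µm). Apparent viscosity follows from
Einstein–Stokes, `η = k_B·T/(6π·D·r_s)`, with unit conversions from µm²/s
and nm into SI. Two inputs are assay conventions rather than measurements
and are exposed as parameters: the temperature (default 310 K, live-cell
imaging) and the Stokes radius of the diffusing species (default 4.5 nm).
A helper computes the minimum Stokes radius of a globular protein from its
mass, `R_min = (0.66·M)^(1/3)` ångströms for M in daltons, but the
viscosity chain never derives `r_s` from a mass internally: the formula is
a sphere lower bound and tagged fusion proteins deviate from it, so the
radius is treated as an explicit input.

**Group summaries.** Per-timepoint mean ± SEM across granules, plus a
plateau-normalized variant (each granule divided by its fitted A) that
isolates kinetics from extent. SEM uses the sample SD and is 0 for n = 1.

## CV-based puncta classification

The coefficient of variation of in-mask reporter pixel intensities
(SD/mean) is dimensionless and invariant to illumination scale. Diffuse
cells have low CV; cells with bright puncta over a dim background have high
CV. Classification is strict: a cell is punctate iff CV > threshold, with
0.62 as the default threshold. Population SD (divide by n) is the default
convention, configurable to sample SD; at typical mask sizes (hundreds of
pixels) the difference is negligible, but the choice is recorded because it
changes CVs at third-decimal precision. Constant regions return exactly 0.

When images rather than track tables are the input, the cell mask is taken
from the supplied mask TIFF, or derived by Otsu thresholding of the
morphology channel when absent.

**Event extraction.** Tracks (one row per cell per imaging day) become two
time-to-event records per cell. Death: first day observed dead, otherwise
right-censored at the last observation. Puncta formation: first day the CV
exceeds the threshold. Puncta formation is treated as absorbing — a cell
that crosses and later dips below remains "event occurred" — because a
well-defined time-to-event needs a monotone state, and the same convention
is applied to the per-day percentage curves. Cells dying before crossing
have their puncta time censored at death; this is the standard censoring
treatment and deliberately stops short of competing-risks estimation,
which is out of scope. A cell already above threshold on day 1 is a
prevalent day-1 event and is flagged for the diffuse-vs-punctate subgroup
contrasts. Percentages of punctate cells among the living are computed per
genotype and day, pooled over experiments, with the SEM of per-experiment
percentages when several experiments are present; a day with no living
cells yields a missing value, never 0.

**Granule complexity.** Manually scored granule complexity (blinded visual
scores 1–4) is grouped as low (1–2) versus high (3–4); summaries report
n/mean/median/SD of scores per genotype and of mobile fraction per
genotype-by-class. The scoring itself is a human task and outside the
package.

## Proportional-hazards machinery

Hazards are modelled as `h_i(t) = h_0(t)·exp(β_g)` with one dummy per
non-reference group. Fitting is delegated to lifelines' `CoxPHFitter`
(Efron tie handling — appropriate because daily imaging produces heavy
ties; Breslow would attenuate estimates more on this data). Replicate
experiments enter as strata, i.e. separate baseline hazards per experiment
with shared group effects. CIs and p-values are Wald statistics on the log
scale, matching the symmetric-in-log intervals conventional in this
literature. Correctness is checked in the test suite against an
independent brute-force oracle: exhaustive grid search of the Efron
partial likelihood on small datasets, and parameter recovery, CI coverage
and null calibration on simulated cohorts.

Complete separation (a monotone partial likelihood, e.g. all of one group's
events preceding the other's observations) is detected — divergent
estimates beyond |β| = 15 or solver non-convergence — and raised as an
error rather than silently returned.

**Quintiles.** Day-1 expression (mask-mean reporter intensity; integrated
intensity is a trivial variant) or day-1 CV is binned into five near-equal
rank-based bins within each population, ties resolved by stable rank order
so bin sizes differ by at most one. Hazards of quintiles 2–5 are contrasted
against quintile 1.

**Diffuse-vs-punctate subgroups.** Two families: each genotype ×
{diffuse, punctate} subgroup against the unsplit control group, and
punctate vs diffuse within each genotype. Subgroups that are empty or
carry no events (which would make the likelihood monotone in that
coefficient) are omitted with a warning.

Events detected on a daily imaging grid are treated as exact at the
detection day; interval-censoring machinery is out of scope.

## Optical-pulse-labeling flux

Per well: pre-conversion background `T0`, post-conversion peak `T1`
(t = 0), hourly intensities for 14 h. Two normalizations are exposed. The
"as-printed" convention divides by the conversion depth without background
subtraction, `Tx/(T1 − T0)`; its t = 0 value is `T1/(T1 − T0) ≥ 1` and a
residual offset `T0/(T1 − T0)` remains, so a pure exponential fit to it is
biased upward — it is retained for fidelity to common practice and fit with
a free scale. The "background-subtracted" convention,
`(Tx − T0)/(T1 − T0)`, equals `e^(−kt)` exactly for a mono-exponential
decay and is the recommended estimator; it is fit with the scale fixed at 1
(whether a free scale or plateau should be fitted is genuinely open; both
are available via flags). Fitting is nonlinear least squares, robust to
near-zero late samples; log-linear regression is available as a flag.
Non-decaying series (rate below 1e-4 h⁻¹, a half-life far beyond any 14 h
assay) are flagged as errors. `half_life·k = ln 2` exactly by
construction.

Aggregation is nested: well fits average within an experiment; condition
mean, SD and SEM are computed across experiment means with n = number of
experiments, since wells within an experiment are technical replicates.
SD/SEM are missing for a single experiment.

## Synthetic-data generators

All generators are deterministic given their seed and emit ground truth
sufficient to score the downstream estimator (parameter-recovery closure);
noiseless generation followed by the corresponding fit returns truth to
solver tolerance.

**FRAP traces.** Raw intensities with baseline `scale` (default 1000),
bleach depth 0.8 of baseline, and the exponential model scaled into the
bleached range; additive i.i.d. Gaussian noise in normalized units (the
depth/baseline anchors are part of the emitted truth, so Monte-Carlo
checks can invert the scaling exactly). Default truth A = 0.7,
t½ = 30 s, noise sd 0.02 — mid-range granule behaviour on this assay.

**Cell images.** A uniform disk cell (radius 20 px in a 64×64 frame,
background 100, cell level 1000) in a morphology channel, plus a reporter
channel with Gaussian puncta placed uniformly inside the mask and Gaussian
read noise. When a design CV is requested, the generator solves in closed
form for the puncta amplitude (punctate presets) or read-noise sd (diffuse
presets) that makes the in-mask CV equal it; the realized CV measured on
the emitted pixels is recorded in the truth. Presets use design CVs of
0.35 (diffuse) and 1.0 (punctate), straddling the 0.62 threshold by a wide
margin. No optics/PSF modelling, photon statistics (a Poisson option is
trivial to add at the call site), or realistic morphology — the images
validate the CV statistic and the segmentation plumbing, not a detector
model.

**Cohorts.** Cells are allocated round-robin to genotypes, experiments
(default 3) and wells; day-1 expression is lognormal (meanlog 6.2,
sdlog 0.6 — a bright, right-skewed transfection distribution). Latent death
and puncta times are exponential with rates
`baseline·exp(log-hazard_group + effect·z)`, z the standardized
log-expression; the effect terms default to 0 and are switched on to
emulate dose effects. Baseline death rate 0.13/day leaves ~30% of
reference-arm cells censored at the day-10 horizon; baseline puncta rate
0.15/day makes ~14% of cells prevalently punctate on day 1. Default group
log-hazards span the effect-size range characteristic of UBQLN2 genotype
panels (death vs control ~0.95–1.43-fold; puncta formation vs WT
~0.65–1.63-fold, with the strongest effects for P506T), so a default
simulated cohort exercises realistic effect sizes; the bare-tag control's
puncta log-hazard is −4 (it stays diffuse). The death clock starts at the first imaging day,
guaranteeing a day-1 observation for every cell; the puncta clock starts at
0. Observed per-day CVs are drawn from truncated normal regimes —
punctate: N(1.0, 0.15) truncated above 0.62; diffuse: N(0.35, 0.10)
truncated at 0 — a stipulation, not an estimate: the CV distributions of
real diffuse/punctate neurons are not characterized, so classification
tests on these cohorts demonstrate the machinery, not real-data accuracy.

Two observation modes exist. `simulate_cohort` reports the imaging-day
grid (dead cells appear once, at the first day observed dead), which is
what the track-based pipeline consumes and carries the discretization any
daily-imaging study has. `simulate_event_cohort` emits the latent
continuous event times with administrative censoring — the
proportional-hazards cohort itself — and is used where an estimator
property (bias, coverage, calibration) is being measured, so that the
check isolates the estimator from the observation grid.

**Decay traces.** `(T1 − T0)·e^(−kt) + T0` per hourly sample with
multiplicative Gaussian noise (default truth half-lives 10.35 h vehicle /
7.95 h Torin1-like, noise CV 2%, 6 wells × 3 experiments). Anchors T0/T1
are emitted noiselessly.

## Problem sizes and numerical choices

Simulation-based checks use sizes chosen to make Monte-Carlo bands
decisive at desk scale: 200 traces for FRAP noise recovery; 1000 images
for classifier concordance; 200 replicates of n = 2000 for hazard-ratio
recovery and coverage and 500 replicates of n = 500 for null calibration;
40 replicates for quintile-null coverage and for flux condition-sign
detection. The acceptance script reports each quantity with the problem
size it used. Tables round hazard ratios and CI bounds to 4 decimals;
p-values are kept as floats and serialize to scientific notation below
1e-3. CSV output uses repr-precision floats so written tables round-trip
bit-exactly; all randomness flows from a single seed through
`numpy.random.SeedSequence` substreams.

## Known limitations

- Single-exponential FRAP only; no ROI tracking or registration (inputs
  are assumed registered).
- No competing-risks estimation; puncta times are censored at death.
- The image simulator's noise is Gaussian, not photon-limited, and its
  cells are disks; results on it bound nothing about segmentation quality
  on real neurons.
- The as-printed flux normalization carries a documented upward bias when
  background is nonzero; cross-condition comparisons under one convention
  remain valid.
- The hazard ratios used as generator defaults are effect-size settings
  for simulation, not estimates from any real dataset.
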