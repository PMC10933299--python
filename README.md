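# punctakit

Single-cell analysis pipelines for studying how an aggregation-prone
protein (the ALS/FTD-linked ubiquitin adaptor UBQLN2 and its missense
mutants are the motivating case) behaves in living cells: how fluid its
condensates are, how readily it forms puncta, how its expression relates to
neuronal death, and whether it perturbs autophagic flux. The package is
aimed at labs running longitudinal automated microscopy and
confocal photobleaching assays who want the downstream quantification —
curve fitting, classification, and risk modelling — as tested, scriptable
components rather than one-off analysis scripts.

Because such live-cell datasets are rarely shareable in raw form, the
package ships a first-class synthetic-data module that generates every
input the pipeline consumes together with its ground truth, so each
estimator is verifiable end to end by parameter recovery.

## What it computes

**Granule fluidity (FRAP).** A bleached granule region recovering as
`y(t) = A·(1 − e^(−τt))` is normalized (pre-bleach mean → 1, first
post-bleach frame → 0, optionally after a bleached/whole-granule ratio
correction), fit by least squares, and summarized physically:
half-maximal recovery time `t½ = ln 2 / τ`, effective diffusion coefficient
`D = 0.88·r² / (4·t½)` for a bleach spot of radius `r`, and apparent
viscosity from the Einstein–Stokes relation `η = k_B·T / (6π·D·r_s)` with a
Stokes radius `r_s` for the diffusing species (default 4.5 nm, T = 310 K).

**Puncta classification (CV).** Per cell and imaging day, the coefficient
of variation of in-mask reporter pixel intensity (SD/mean) measures how
punctate the reporter distribution is; cells strictly above a threshold
(default 0.62) are classified punctate. Longitudinal tracks are reduced to
time-to-event records: death at the first day observed dead, puncta
formation at the first threshold crossing (an absorbing state), each
right-censored appropriately.

**Risk modelling (Cox proportional hazards).** Genotype contrasts against a
reference group, day-1 expression and day-1 CV quintile analyses (lowest
quintile as reference), and diffuse-vs-punctate day-1 subgroup contrasts,
with replicate experiments as strata (separate baseline hazards). Ties are
handled with Efron's correction; CIs and p-values are Wald statistics on
the log-hazard scale.

**Autophagic flux (optical pulse labeling).** Photoconverted-reporter decay
per well, normalized by conversion depth `(T1 − T0)`, fit as
`y = e^(−kt)` with half-life `ln 2 / k`, then aggregated
superplot-style: wells → experiment means → condition mean ± SD/SEM with
n = number of experiments.

## Worked example

```python
import math
from punctakit import frap, survival
from punctakit.simulate import (CohortSimParams, FrapSimParams,
                                simulate_event_cohort, simulate_frap_traces)

# FRAP: nine noisy granule traces (truth: A = 0.7, t_half = 30 s)
traces = simulate_frap_traces(FrapSimParams(noise_sd=0.02, seed=42), 9)
for f in [frap.analyze_trace(tr) for tr in traces][:3]:
    print(f"{f.granule_id}  A={f.mobile_fraction:.3f}  t_half={f.t_half_s:.2f}s  "
          f"D={f.diffusion_um2_per_s:.4f}  eta={f.viscosity_pa_s:.3f}")

# Survival: two-arm cohort with a known death hazard ratio of 1.6
params = CohortSimParams(
    n_cells=2000, groups=("control", "mutant"),
    log_hazard_death={"control": 0.0, "mutant": math.log(1.6)},
    log_hazard_puncta={"control": 0.0, "mutant": 0.0}, seed=7)
res = survival.fit_cox(simulate_event_cohort(params),
                       reference="control", strata_col="stratum")[0]
print(f"mutant vs control: HR {res.hazard_ratio:.3f} "
      f"(95% CI {res.ci_low:.3f}-{res.ci_high:.3f}), p = {res.p:.2e}")
```

prints

```
g0  A=0.697  t_half=30.07s  D=0.1002  eta=0.504
g1  A=0.700  t_half=29.89s  D=0.1008  eta=0.501
g2  A=0.710  t_half=31.71s  D=0.0950  eta=0.531
mutant vs control: HR 1.556 (95% CI 1.407-1.721), p = 7.78e-18
```

Each granule's fitted mobile fraction and half-time sit near the simulated
truth (0.7, 30 s); the derived viscosity of ~0.5 Pa·s is what a 4.5 nm
particle diffusing at ~0.1 µm²/s at 310 K implies. The Cox fit recovers the
simulated 1.6-fold death hazard within its confidence interval.

A command-line surface wraps the same stages:

```sh
punctakit simulate cohort --seed 1 --out sim/
punctakit puncta classify --in sim/tracks.csv --out classified.csv
punctakit run --out results/          # full simulate -> analyze bundle
```

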