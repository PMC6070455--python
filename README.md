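# fmisokin

Compartmental kinetic analysis of dynamic ¹⁸F-fluoromisonidazole (FMISO)
PET for tumor hypoxia, with model-adequacy scoring, a Monte-Carlo
bias/precision study, and an AATH perfusion-CT blood-flow model for
cross-validating the PET delivery constant.

## Who this is for

Researchers quantifying tumor hypoxia from whole-tumor dynamic FMISO PET
time-activity curves (TACs): the package fits linear-chain compartment
models to framed TACs against an image-derived arterial input function,
decides which model the data support, quantifies how precisely rate
constants can be estimated at realistic noise levels, and compares the
PET delivery constant K₁ with blood flow measured independently by
perfusion CT. Because clinical TACs are rarely shareable, a synthetic-data
generator reproduces the full study structure (frame schedules, input
function, count-statistics noise, linked perfusion-CT curves) so every
stage runs and is testable without any download.

## The models

**Compartment models (xCyK).** A model with *x* tissue compartments and
*y* rate constants forms a linear chain: blood → free (K₁, k₂) → bound
intermediates (k₃, k₄, …). Irreversible variants (odd *y*) fix the
terminal return rate at zero — FMISO is irreversibly reduced and trapped
in hypoxic cells. The measured signal is
(1 − v_B)·(C_B ⊗ h)(t) + v_B·C_B(t), with v_B the vascular fraction and
h the chain's sum-of-exponentials impulse response. The net trapping
(flux) constant is

    k_flux(2C3K) = K₁k₃ / (k₂ + k₃)
    k_flux(3C5K) = K₁k₃k₅ / (k₂k₄ + k₂k₅ + k₃k₅)

**Fitting.** Weighted least squares with frame weights
w_i = Δt_i·exp(−λt_i)/C(t_i) (λ the ¹⁸F decay constant), minimized from
100 random starting points with a bounded trust-region
Levenberg–Marquardt variant.

**Model selection.** Wald–Wolfowitz runs test on residual signs, AIC
corrected for small samples (AICc), BIC, and leave-one-out mean squared
error of prediction (MSEP).

**Simulation study.** Ground-truth TACs plus 1000 (configurable) Gaussian
noise realizations per truth, with per-frame variance proportional to the
inverse of the fit weight; summaries are the mean bias MB, between-truth
spread σ_B, within-truth precision σ_P, and σ_T = (σ_B² + σ_P²)^½.

**Perfusion CT.** The adiabatic approximation to the tissue homogeneity
(AATH) model: plug-flow capillary with transit time Tc = v_P/BF and
exchange at the venous outlet; extraction fraction E = 1 − exp(−PS/BF)
links delivery to flow through K₁ = BF·E.

## Worked example

```python
import numpy as np
from fmisokin import (CohortConfig, generate_cohort, fit_model,
                      model_spec, tumor_blood_ratio)

bundle = generate_cohort(CohortConfig(seed=1, n_tumors=3, n_scans_per_voi=1))
tac = bundle.noisy_tacs[0][0]
res = fit_model("3C5K", tac, bundle.input_fn, n_starts=100, seed=1)
truth = bundle.truths[0]
print(f"K1 fitted {res.params.rates[0]:.4f} vs truth {truth.rates[0]:.4f}")
print(f"k_flux fitted {res.params.k_flux:.5f} vs truth {truth.k_flux:.5f}")
blood_4h = bundle.input_fn.tac.activity[-1]
print("4-h TBR status:", tumor_blood_ratio(tac.activity[-1], blood_4h))
```

prints

```
K1 fitted 0.4760 vs truth 0.4765
k_flux fitted 0.07040 vs truth 0.07080
4-h TBR status: hypoxic
```

The fitted delivery and flux constants land within a fraction of a
percent of the generating values for this tumor at the default noise
level; how those errors distribute across tumors and noise realizations
is exactly what the Monte-Carlo study quantifies. The final line
classifies the tumor by its 4-h tumor-to-blood ratio against the
standard 1.4 hypoxia threshold.

A command-line interface mirrors the pipeline:

```bash
fmisokin synth --out-dir study --seed 1 --n-tumors 4
fmisokin fit --tac study/tumor00_scan0.csv --input study/blood.csv \
             --model 3C5K --seed 1 --out fit.json
fmisokin select --manifest study/manifest.json --out selection.csv
fmisokin simulate --n-truths 10 --n-reps 100 --seed 1 --out table3.csv
fmisokin aath --tissue study/pct_tumor00.csv --aif study/pct_aif.csv \
              --seed 1 --out aath.json
```

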