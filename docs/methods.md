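# Methods

This note documents the models, numerical choices and defaults behind
`fmisokin`, and what the synthetic studies do and do not establish about
real data.

## Time conventions and data model

Injection defines t = 0; the scanner starts 30 s earlier, so the first
frame of the dynamic sequences begins at −30 s and pre-injection frames
carry zero model signal and zero fit weight (they are kept, rather than
dropped, so frame indices stay aligned with files). Frame times in CSV
files are seconds post-injection; all kinetic computation runs in
minutes, with K₁ in mL·min⁻¹·mL⁻¹ and k's in min⁻¹.

The two dynamic binnings of the first 45 min are S1
(1×30 s, 12×5 s, 6×10 s, 5×30 s, 10×60 s, 6×300 s; 40 frames, 2700 s)
for tumor VOIs and the finer S2 (1×30 s, 60×1 s, 12×10 s, 3×30 s,
10×60 s, 6×300 s; 92 frames) for the blood pool, each followed by single
10-min frames at 2 h and 4 h post-injection.

Activities are assumed decay-corrected to injection time; the
exp(−λt_i) factor in the fit weighting is purely a count-statistics
term, with λ = ln 2 / 109.77 min for ¹⁸F.

## Input function interpolation

The blood curve C_B(t) is piecewise linear through the frame mid-time
samples, rises linearly from 0 at injection to the first positive-time
sample, and is held constant after the last sample. Across the
45 min → 2 h → 4 h acquisition gaps the default bridge is
mono-exponential through the flanking samples (late FMISO blood
clearance is slow and smooth, so a geometric bridge is the natural
shape); linear bridging is available as a configuration alternative.
A gap is any inter-sample spacing above 600 s — twice the widest
in-block frame spacing.

## Forward model evaluation

The tissue response of an x-compartment chain is obtained by
eigen-decomposition of the chain's rate matrix, giving a
sum-of-exponentials kernel. Convolution with the (densified)
piecewise-linear input is evaluated in closed form segment by segment,
so the model curve is exact for the stored input representation — this
matters because a fit evaluates the model ~10⁴–10⁵ times. If the
eigenbasis is ill-conditioned (condition number above 1e8, i.e.
near-degenerate eigenvalues) the curve falls back to exact
matrix-exponential stepping with the input handled by an
augmented-matrix discretization; the result is flagged.

Frame values are Gauss–Legendre 5-point averages over each frame;
sub-frame accuracy matters for the 5-s frames spanning the bolus peak.
The blood contribution uses the spill-in mixing convention
(1 − v_B)·C_tissue + v_B·C_B (the form used by common kinetic-analysis
software); an additive convention is switchable.

## Fitting

Weights follow w_i = Δt_i·exp(−λt_i)/C(t_i) with Δt in seconds. Because
early frames can be zero or negative, the denominator is floored at
1e-3 of the TAC maximum. Bounds on the free parameters — v_B ∈ [0, 0.5],
K₁ ∈ (1e-4, 2], k's ∈ (1e-5, 2] min⁻¹ — cover physiological ranges for
thoracic tumors; starting values are drawn log-uniformly over the rate
bounds (uniform for v_B) so all scales are represented, 100 starts by
default. Each start runs a trust-region reflective least-squares
minimization (the bounded trust-region variant of Levenberg–Marquardt;
chosen because classic unconstrained LM cannot honor the bounds), capped
at 400 residual evaluations; the best converged start is polished at
near-machine tolerance. Ties within 1e-10 relative WSS are broken by the
smaller parameter-vector norm for reproducibility. All randomness flows
through one seeded generator, so a fit is bit-reproducible given its
seed.

Leave-one-out refits are warm-started from the full-data solution plus
random restarts (9 by default) to keep cross-validation affordable.

## Model selection

* **Runs test** on residual signs (zero residuals inherit the previous
  sign; they have measure zero for continuous data). For n ≤ 20 the
  run-count distribution is enumerated exactly and reported as a
  two-sided mid-p — half the observed count's probability weight in each
  tail — which removes the conservatism of the discrete statistic; for
  larger n the plain normal approximation is used, which tracks the
  mid-p within ~0.01 for balanced counts ≥ 10 and gives a type-I error
  near the nominal 5% at T = 40. "Pass" means not rejected at
  α = 0.05 (two-sided; standard choice).
* **Information criteria** use the Gaussian weighted-least-squares
  forms AIC = T·ln(WSS/T) + 2k, AICc = AIC + 2k(k+1)/(T−k−1),
  BIC = T·ln(WSS/T) + k·ln T, with T the number of frames carrying
  nonzero weight and k the free-parameter count (v_B plus rates:
  4, 5, 6, 7, 8, 9 for 2C3K … 4C8K). Weights are normalized to mean 1
  over the contributing frames before WSS enters the criteria; this adds
  the same constant to every model's score on a given TAC, so rankings
  are comparable across models and invariant to rescaling the data.
* **MSEP** is the unweighted mean over frames of the squared difference
  between each omitted value and the refit model's prediction at that
  frame ("squared error of prediction" carries no weighting). Failed
  folds are skipped and counted.

## Monte-Carlo bias/precision study

Ground-truth TACs (from fits to measured data, or from the synthetic
sampler) are perturbed with independent per-frame Gaussian noise of
variance s²·C(t_i)·exp(λt_i)/Δt_i — the inverse of the fit weight —
with the same activity floor as the weighting, so pre-injection frames
keep a small nonzero variance (they are real measured frames). The
scale default s = 0.6 matches the average level observed on whole-tumor
data, with a spread of 0.3 across tumors; both a global scale and
per-tumor sampled scales are supported.

Per truth j and parameter: bias b_j = mean(fitted) − truth_j, then
MB = mean_j(b_j), σ_B = std_j(b_j), σ_P² = mean_j var(fitted), and
σ_T = (σ_B² + σ_P²)^½, all as percentages of the mean ground-truth
value. When the fitted model has a different chain length than the
truth, its rate constants lump several truth processes (e.g. K₁ of a
two-tissue fit mixes K₁ and k₃ of a three-tissue truth); such split
parameters report σ_P only, referenced to their mean fitted value. A
nominal mean bias against the closest truth parameter is retained in a
diagnostic column, since the self- vs cross-model bias contrast is the
study's point. v_B and k_flux always have direct counterparts.

Study sizes: the full design is 30 truths × 1000 realizations; the test
suite and acceptance script use desk-scale presets (10 × 100 and
6 × 50) with warm-started fits (the fit to the noise-free truth TAC
plus a few random restarts per realization) — the summaries are
averages, so the presets trade Monte-Carlo resolution, not correctness.

## AATH perfusion-CT model

Tissue enhancement is C(t) = BF·(AIF ⊗ R)(t − t0) with the plug-flow
residue R(τ) = 1 for τ < Tc = v_P/BF and E·exp(−(E·BF/v_e)(τ − Tc))
after, E = 1 − exp(−PS/BF). Attenuation is taken proportional to iodine
concentration; the proportionality cancels between tissue and AIF, and
baselines are estimated from the first 3 s of each curve. The two
residue terms are integrated exactly against the piecewise-linear AIF
(a sliding-window integral and a closed-form exponential convolution).
Fitting uses uniform weights (CT noise carries no count-statistics
structure), bounds BF, PS ∈ (0, 3] mL·min⁻¹·mL⁻¹, v_P, v_e ∈ (0, 1],
t0 ∈ [0, 15] s (the delay is fittable and switchable off), and a
30-start multi-start. P and S never appear separately — only the
product PS is estimable.

**Known limitation.** When the capillary transit plateau is short
relative to the 1-Hz cine sampling (Tc ≲ 5 s) or extraction is high,
the likelihood develops a ridge toward high BF: the limit curve
v_P·AIF + PS·(exp-conv) fits noisy data as well as the truth, and BF
becomes unidentifiable even though K₁ = BF·E and v_P remain stable.
Noisy-recovery figures are therefore quoted for tumors with resolvable
plateaus (Tc ≈ 14 s); the noise-free recovery is exact regardless.

## Synthetic studies

The generator emulates: a Feng-type bolus-plus-washout arterial input
(peak ~40 kBq/mL within 30 s of injection, slow late tail ~6 kBq/mL at
4 h) frame-averaged onto S2; tumor truths sampled uniformly from
v_B ∈ [0.02, 0.2], K₁, k₂ ∈ [0.1, 0.6], k₃, k₄ ∈ [0.005, 0.1],
k₅ ∈ [0.005, 0.05] min⁻¹ (ranges that make a subset of tumors exceed
the 4-h TBR 1.4 hypoxia threshold); frame noise per the inverse-weight
model with per-tumor scales ~N(0.6, 0.3²) truncated at 0.1; and
perfusion-CT curves generated by the AATH model with BF_j = K₁_j/E_j
inverted from a sampled PS/BF ratio in [5, 10], so the flow-delivery
link holds by construction. The default cohort is 15 VOIs imaged twice.

What passing tests show: the estimators, selection scores and summary
statistics are implemented correctly and behave as designed under the
assumed noise model. What they do not show: real TACs add effects the
generator omits — patient motion, reconstruction correlations between
frames, plasma-metabolite differences from whole blood, VOI
delineation error — so absolute bias/precision percentages on clinical
data can differ even when the qualitative contrasts (self- vs
cross-model bias, K₁-vs-flow correlation beating static uptake) carry
over.

## Degenerate inputs and edge rules

All-zero TACs are rejected for weighting (no signal); non-positive
blood values are rejected for TBR; flux constants with vanishing
denominators raise rather than return NaN; BF = 0 yields the limiting
extraction E = 1; reversible models have no flux constant by
construction. CSV I/O is a fixed dialect (comma, dot decimal, UTF-8,
mandatory header) and validates ordering/overlap, naming the offending
row.
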