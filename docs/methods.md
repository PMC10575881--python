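# Methods

## The models

Two-choice change-detection decisions are modelled as a one-dimensional
Wiener process with drift ν (evidence quality), within-trial diffusion
coefficient s, absorbing boundaries at 0 and a (response conservativeness),
an unbiased start point at a/2 and a nondecision offset T_er added to the
first-passage time. Continuous-report (delayed-estimation) decisions use the
circular extension: a two-dimensional Wiener process starts at the center of
a disk of radius a, with a drift vector of magnitude ν pointing at the target
feature angle; the response is the hitting angle and the decision time the
hitting time. In the circular model the hitting angle is von Mises around
the target with concentration κ = aν/s², independent of the hitting time.

The diffusion scaling s is not identifiable from behaviour; it is fixed at
s = 1 throughout (configurable). Parameter magnitudes of the built-in group
means (a ≈ 1.1–2.1, ν ≈ 0.2–1.3, in evidence units consistent with RTs in
seconds) presuppose this unit-scaling convention.

## Simulators

Trials are simulated by Euler–Maruyama with step dt = 0.001 s plus a
Brownian-bridge boundary-crossing test between steps: with surviving
distances d0, d1 to the boundary at consecutive step endpoints, the trial is
absorbed mid-step with probability exp(−2 d0 d1 / (s² dt)). Discrete
monitoring alone acts like a boundary displaced outward by ≈ 0.5826·s·√dt,
which at dt = 10⁻³ would bias choice probabilities by ~0.6% and disk exit
times by ~4%; with the bridge correction the residual discretisation bias is
O(dt) and sits well inside the Monte-Carlo error of every check in the test
suite. Decision times exceeding 30 s are resampled and counted in the
cohort diagnostics. Kernels are numba-compiled per-trial loops; all
randomness derives from explicit integer seeds, and identical seeds
reproduce cohort tables bit for bit.

## First-passage numerics for the circular model

In scaled units (a = s = 1) the zero-drift exit-time density from the disk
center is the classical Bessel-zero series f0(t) = Σ_k c_k exp(−j²_{0k} t/2)
with c_k = j_{0k}/J₁(j_{0k}); with drift the decision-time density is
f(t) = I₀(κ) e^{−κ²t/2} f0(t). Rather than summing the series for the
moments — its alternating terms cancel catastrophically beyond κ ≈ 15 —
the package evaluates the closed forms implied by the Laplace transform
E[e^{−uT}] = 1/I₀(√(2u)):

    m_k(κ) = I₁(κ) / (κ I₀(κ)),      v_k(κ) = (R² − 1 + 2R/κ) / κ²,

with R = I₁/I₀ evaluated through exponentially scaled Bessel functions
(stable past κ = 500); m_k(0) = 1/2 and v_k(0) = 1/8 exactly. The truncated
series (up to 500 zeros, with Euler-type iterated-averaging acceleration of
the alternating partial sums) is retained as an independent validation path:
tests verify the Laplace normalisation identity Σ_k c_k·2/(j²+κ²) = 1/I₀(κ)
to 10⁻⁸ and series/closed-form agreement to 10⁻⁸ for κ ≤ 10. Decision-time
quantiles come from the termwise-integrated CDF (root-finding), with a
normal fallback above κ = 15. Physical decision times scale as
(a/s)² × (dimensionless function of κ).

## Preprocessing

RT trimming runs per participant × task × condition cell: absolute bounds
first (CD: 0.1–7.5 s; DE: 0.25–15 s, cuts strictly outside the bounds), then
one non-iterated 3-SD pass around the cell mean of the surviving trials.
For CD, every RT-based step uses correct trials only; incorrect trials are
always retained (their RTs are unused) so the proportion correct keeps its
denominator, and trials removed by trimming leave the table entirely, so the
edge-correction n equals the post-trim cell count. Summary statistics:
CD — proportion correct over the trimmed cell, median and n−1 sample
variance of correct RTs; DE — circular variance (1 − mean resultant length)
and mean absolute deviation of the wrapped report errors, median RT, and a
robust RT variance (IQR/1.349)² with linear-interpolation quartiles.
Accuracies of 0, 0.5 or 1 are nudged by 1/(2n) into the logit's domain.

## EZ estimation

The two-choice inverse is the standard closed form: L = logit(pc),
ν = sign(pc−½)·s·[L(Lpc² − Lpc + pc − ½)/vrt]^{1/4}, a = s²L/ν. The
circular inverse solves I₁(κ)/I₀(κ) = 1 − cv for κ by bracketed
root-finding, scales the boundary from the RT dispersion and sets
ν = κs²/a.

Because the pipeline feeds *robust* statistics (median RT; IQR-based
variance for DE), the inverse matches the model statistic of the same kind
rather than the raw moment:

- T_er is the observed median RT minus the model-implied **median** decision
  time (Wiener or circular FPT CDF, root-found). Subtracting the mean
  decision time from a median RT would push the median–mean gap of the
  right-skewed first-passage law (≈ 10% of the decision time at typical
  parameter values) into T_er, and — because the gap varies with κ and a —
  leak spurious condition effects into the nondecision parameter.
  `ter_reference="mean"` restores the exact algebraic inverse of the mean
  equations.
- For DE, the boundary matches the model's decision-time IQR:
  a = s·√(1.349·√vrt / iqr_k(κ)). Equating a normalized-IQR variance with
  the true variance v_k would bias a low by ≈ 9% and ν high by ≈ 12%.
  `scale_reference="variance"` restores the plain moment match.

With these conventions, forward∘inverse is an identity to numerical
precision, and single-cell recovery from simulated trials is within 0.5%
(CD, 10⁵ trials) and ~3% (DE, 10⁴ trials) at the built-in group means.
Estimation failures (no correct trials, pc at ½ after correction, cv = 1)
become status-coded missing rows, keeping the parameter table rectangular;
negative T_er estimates are preserved and flagged, never clipped.

## Fit assessment

For every participant × condition cell, trials are regenerated from the
fitted parameters at the observed post-trim trial counts, and
participant-level statistics (PC or CV, and the 0.25/0.50/0.75 RT quantiles
of correct RTs for CD, all RTs for DE) are correlated between observed and
generated data within each task × age group. By default the two cue
conditions are concatenated (each participant contributes one point per
condition); a per-condition mode with Fisher-z averaging is available.
At 40–50 trials per cell, sampling noise alone bounds the accuracy-statistic
correlations near 0.85 even when the model is exactly true (both the
observed and the regenerated proportions carry independent binomial noise);
RT-quantile correlations, driven by large between-person nondecision-time
differences, reach 0.93–0.99. Passing this check therefore certifies that
the fitted parameters reproduce individual differences up to the information
actually present in a cell, not that accuracy statistics can be matched to
arbitrary precision.

## Synthetic cohorts

The generator emulates a two-session ageing study: younger and older adults,
four tasks (color/orientation × CD/DE), 80 test trials per CD task and 100
per DE task, randomly intermixed 50/50 cue split, group-specific memory
loads carried as metadata (fractional loads realised as mixtures of the two
adjacent set sizes, ceil-share equal to the fractional part). Cell means
default to the built-in group-level posterior means (no-cue mean plus signed
retro-cue effect); between-participant heterogeneity is a truncated-normal
deviation per participant × task (SDs: ν 0.25, a 0.30, T_er 0.15 — chosen to
reproduce the published between-person spread, e.g. a PC SD of ≈ 0.10 in
color CD), shared across the two cue conditions so that cohorts carry a
genuine random-intercept structure. Sampled parameters violating
invariants are clipped to the valid range with a warning (a ≥ 0.05,
ν ≥ 0.05, T_er ≥ 0). What the generator does *not* emulate: guessing/swap
mixtures in continuous report, across-trial parameter variability (the full
DDM's η, s_z, s_t), load-dependent parameter changes, fatigue or practice
drift. Green tests therefore certify the estimators and inference under the
three-parameter data-generating process, not robustness to those real-data
contaminants.

## Group-level inference

Each diffusion parameter is analysed separately with a Bayesian linear
mixed model on the per-cell EZ estimates: a saturated fixed-effect design in
the four ±0.5 effect-coded predictors (age group, paradigm, material, cue),
so that every fixed effect reads directly as a raw-parameter-scale
difference; by-participant random intercepts and random slopes for paradigm
and material (independent variances). Priors: normal(0, 0.5) on all
non-intercept fixed effects (a N(0, 0.5) grand-mean prior would bias every
cell mean, so the intercept gets a vague normal(0, 5); no tested contrast
involves it), inverse-gamma(2, 0.05) on the residual and random-effect
variances. The model is conditionally conjugate; sampling is blocked Gibbs
with a collapsed fixed-effect update (random effects marginalised per
participant via Woodbury), which brings split-R-hat from ~1.03 to ~1.001 at
4 × 2000 draws. Convergence is asserted via classic split-R-hat against a
1.05 threshold; non-convergence raises with the full R-hat table. The
default budget is 4 chains × (500 warmup + 2000 draws) — posterior means of
cohort-level contrasts are stable to ±0.005 at this size; a 4 × (2000 +
10000) configuration is available for full-scale reruns.

Contrasts (per-task or overall cue effects, age differences on baselines or
on cue effects, paradigm/material moderators) are linear combinations of the
fixed-effect draws. Savage–Dickey Bayes factors divide the implied prior
density at zero — normal with SD 0.5·‖c‖ for contrast weights c — by the
posterior density at zero, estimated by a normal approximation to the draws
(default; stable at extreme BFs) or a Gaussian KDE. The HDI is the shortest
sliding window over the sorted draws. Evidence bands: BF₁₀ < 0.1 strong
against, 0.1–0.3 moderate against, 0.3–3 ambiguous, 3–10 moderate for, > 10
strong for. Very large BFs are reported at the numerical cap (posterior
density floored at 10⁻³⁰⁰) and are seed-sensitive in their exact magnitude,
as density-ratio BFs far in the tail always are; their band is not.

## Numerical and degenerate-input policy

- Quartiles: linear interpolation; normalized-IQR constant 1.349 (Gaussian
  IQR/SD ratio).
- kappa solve: Brent on [0, 2^k] with bracket doubling, xtol 10⁻¹².
- Decision-time quantile solves: Brent, xtol 10⁻¹⁴.
- Cells with < 2 varying points make fit-check correlations undefined — an
  error, not a NaN.
- Empty cells after trimming are dropped with a warning; zero-correct or
  single-correct CD cells yield status-coded rows.
- Fit-check with one participant raises; parameter cells with error status
  are excluded and counted in the report.

## Problem sizes used by the shipped checks

Distributional simulator checks run at 10⁵ trials (3 Monte-Carlo SEs, or 1%
for the zero-drift exit time); unit-level variants at 2–3 × 10⁴. The
closed-loop fit check and the injected-effect recovery use cohorts of 150
participants per age group at the full task battery; the null-calibration
replicates 20 trial-level cohorts at 40 per group with a reduced MCMC budget
(2 × (200 + 600)). These sizes give the report stable second decimals while
keeping a laptop run in minutes.

## Known limitations

- The EZ estimators are method-of-moments fits; they inherit EZ's bias under
  contaminant RTs and mixture responding, which the trimming rules only
  partially remove.
- The circular estimator ignores the mean absolute deviation (computed and
  reported, but redundant given cv for identification).
- Random-effect covariances are not modelled (independent variances).
- BF magnitudes beyond ~10³⁰⁰ saturate at the floating-point cap.
- The series evaluation path for the circular first-passage law loses
  precision beyond κ ≈ 15 and is only used for cross-validation; the closed
  Bessel-ratio forms have no such limit.
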