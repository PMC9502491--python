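# Methods

This note documents the models, algorithms and numerical choices behind
`nebpk`, and what the synthetic-data experiments do and do not establish.

## Structural model and unit convention

The core model is two-compartment disposition with first-order oral
absorption, an absorption lag time and linear elimination, parameterised
by apparent constants (Tlag, ka, CL/F, V1/F, Q/F, V2/F). Oral
bioavailability F is not a separate parameter: all data are oral, so only
the F-scaled quantities are identifiable. The closed-form solution is the
triexponential in the README; multiple dosing is handled by superposition,
with a fast path for profiles over the final dosing interval that folds
the dose history of each exponential mode into a single accumulation
weight (cost O(subjects × grid) instead of O(subjects × grid × doses)).

The source estimates carry no units. Taking doses in mg and
concentrations in ng/mL, volumes must be read in 10³ L and clearances in
10³ L/h for the numbers to cohere: with CL = 0.22 (10³ L/h), a 5 mg daily
dose gives a steady-state average of D/(CL·τ) ≈ 0.95 ng/mL and a day-15
peak of ≈1.6 ng/mL — consistent with the 1.0–2.0 ng/mL efficacy window
and with observed single-dose peaks near 2.4 ng/mL, whereas face-value
litres would be off by three orders of magnitude. This inference is a
package-level convention, recorded here once; nothing else depends on it.

Degenerate absorption (ka numerically equal to a disposition exponent,
relative distance < 1e-8) is handled by perturbing ka by 1e-6 relative
rather than implementing the repeated-root limit; continuity across the
degeneracy is tested. The transit-absorption variant (three stages,
shared ktr, replacing the lag time) produces a defective compartment
matrix at equal rates, so it is propagated with the matrix exponential
instead of an eigendecomposition.

## Synthetic cohorts

The generator reproduces the statistical structure the analysis assumes,
at the documented study conditions: thirty subjects (one on 20 mg daily
for 27 days, five on a single 5 mg dose, twenty-four on a single 10 mg
dose), age ~ Normal(26.70, 1.40²) truncated to 20–34 years,
BMI ~ Normal(25, 1), CYP2D6 classes EM/IM/PM with probabilities
17/30, 12/30, 1/30, and a rich sampling schedule
(0.25–48 h after the last dose). Individual parameters are lognormal
around the population values; the source text states that parameters
"follow normal distributions, with no random effects", which cannot
produce the between-subject spread its own simulations display, so
lognormal IIV (the field default; guarantees positivity) with default
SD 0.2 per parameter is used and exposed in configuration. Covariate
coefficients are never reported; they default to zero, and the
covariate-search experiments set non-zero values explicitly. Residual
error is proportional, y = f·(1 + b·ε) with b = 0.13; draws below zero
are truncated to zero (physical concentrations; negligible probability
at b = 0.13).

What passing tests on these cohorts show: the estimator and the
attainment machinery are correct and calibrated *under the assumed
statistical model*. What they do not show: robustness to features of
real digitised data — model misspecification, censoring at the assay
limit, correlated random effects, digitisation error — none of which the
generator emulates.

## SAEM estimator

Individual log-parameters are φᵢ = Xᵢβ + ηᵢ with ηᵢ ~ N(0, diag(ω²)); the
design matrix carries an intercept per parameter plus optional covariate
columns (log(age/26.7) on CL; IM/PM indicators on CL, V1, Tlag;
log(BMI/25) available). The E-step is Metropolis-within-Gibbs on η,
vectorised across subjects, with three kernels per sweep: an independence
proposal from the prior, a component-wise random walk and a joint random
walk, the last two with acceptance-rate adaptation toward ~0.4. Two
chains run by default. Because φ enters the Gaussian layer linearly, the
M-step is exact: per-parameter least squares of the stochastic φ-averages
on the design, closed-form ω², and a closed-form proportional-error
update. Step sizes are γ = 1 for the first K1 = 300 iterations
(exploration, with simulated-annealing lower bounds 0.95 per iteration on
the variance terms) and γ = 1/(k−K1) for K2 = 200 smoothing iterations.

Numerical choices that matter:

* The residual SD carries an additive floor of 1e-3 ng/mL. Under a pure
  proportional model the likelihood of a pre-lag observation (prediction
  exactly zero) is ill-defined; the floor makes it finite and continuous
  in the parameters.
* Predictions below 1e-3 ng/mL are excluded from the proportional-error
  M-step statistic. Their ratio residuals are uninformative about b and
  otherwise explode when a transient parameter state puts an observation
  just inside the lag; without the exclusion the b update can run away,
  after which −log(b·f) rewards pushing all predictions to zero and the
  fixed effects diverge.
* Conditional log-likelihoods are recomputed at the start of every sweep
  (the M-step moved the population parameters; cached values would make
  acceptance ratios compare different posteriors), log-parameters are
  clipped at |φ| ≤ 30, and non-finite likelihoods are mapped to −1e100.
* Starting values are crude data statistics (dose/AUC for CL, dose/Cmax
  for V1, half the earliest positive sampling time for Tlag), overridable
  in `SAEMConfig`.

A fit is flagged non-converged when estimates leave a generous physical
range, when the smoothing-phase trace still drifts by > 0.5 log units, or
when the design has fewer pooled distinct observation times than the
structure has parameters (a two-compartment model against two sampling
times cannot be identified, and SAEM would wander rather than fail).

OFV = −2 log L̂ comes from per-subject importance sampling (Gaussian
proposals moment-matched to the conditional MCMC draws, inflated 1.5×),
with the Monte-Carlo SE reported; with all ω at the floor the integral is
collapsed analytically. AIC = OFV + 2k, BIC = OFV + k·ln N with N = the
number of subjects (population-level parameters; configurable to
observation count). Standard errors use Louis' identity with analytic
complete-data scores/Hessians evaluated over conditional draws;
population values, omegas and error coefficients are estimated on the log
scale, so RSE% = 100·SE(log estimate). Model selection minimises BIC,
with ties (< 0.01) resolved toward fewer parameters.

The covariate search operates on the EBEs (conditional modes): Pearson
correlation tests for continuous covariates, one-way ANOVA for the
genotype class, candidates residualised on already-included terms;
forward inclusion at p < 0.05 and backward elimination at p > 0.05 until
stable. Calibration experiments use EBEs computed at the known generating
values, which exercises the identical search path without re-estimating
the model hundreds of times.

One stated property is deliberately not asserted at face value: estimate
invariance under subject reordering to 1e-6. The samplers draw random
numbers by array position, so permuting subjects permutes the draws;
estimates are reorder-invariant only in distribution. Determinism under a
fixed seed is asserted instead.

## Attainment and calibration

A regimen's cohort is scored on the final dosing interval of the 15-day
course: "peak" is the maximum and "trough" the minimum over that interval
(grid step 0.05 h, earliest-time tie-break), efficacy is peak ∈ [1, 2]
ng/mL and safety is trough < 0.5 ng/mL. Attainment uses noise-free
individual predictions: residual error is assay noise, not exposure (a
flag enables noisy attainment).

The published attainment was computed by resampling the thirty real
subjects' individual parameters, which are not available. The stand-in is
a single lognormal subject-level exposure factor applied jointly to CL,
V1, Q and V2 — a common scaling of those four leaves every micro rate
constant unchanged and multiplies the whole concentration profile, which
is exactly how unexplained bioavailability variability acts, and is apt
for a drug whose F spans 12–96% by CYP2D6 class. Its location δ and
spread σ are solved so that the simulated efficacy of 5 mg and 10 mg once
daily equals the published 72.2% and 22.6%. Under dose-linearity the log
peak is exactly Normal(log P(d) + δ, σ²), so the two-anchor system is
solved analytically with normal quantiles (nested Brent root-finding:
inner on δ along the branch with the median peak below the window's
geometric centre, outer on σ), then verified by simulation at n = 10⁵ to
±0.5 points. The solution is δ = −0.241, σ = 0.291. The 2.5 mg and 20 mg
once-daily efficacies are then predictions, not fits.

The published *safety* percentages cannot be reconciled with any single
trough-based reading (e.g. 100% "safe" for an accumulating 2.5 mg q6h
regimen, or 95.5% for 5 mg daily whose model troughs sit near 0.66 ng/mL
for the typical subject); safety is implemented exactly as the stated
definition (trough below 0.5 ng/mL), its dose-monotonicity holds, and the
numerical discrepancy with the published table is reported rather than
chased. The regimen table reuses one cohort's random effects across
regimens, so between-regimen contrasts are paired.

## Diagnostics

IWRES = (obs − ipred)/(b·ipred); entries at ipred = 0 are flagged NaN.
Against the true individual parameters IWRES are exactly standard normal
(tested); against EBE predictions shrinkage absorbs part of the noise and
deflates the variance toward ~0.8 at this design's richness — expected,
and asserted only within a sane band.

NPDE follows the rank-based probability integral transform with
per-subject decorrelation (Cholesky of the simulated covariance, ≥ 100
replicates) and probit. Concentration data under a lag-time model carry
an atom at zero (pre-lag samples); ranks are ill-defined on atoms, so
exact zeros in both observations and replicates are spread with seeded
uniform jitter just below zero, which makes the PIT exactly uniform under
the model and touches nothing quantifiable.

VPC uses equal-count time bins (default 8; robust to dense-early,
sparse-late PK sampling), type-7 percentiles (10/50/90 by default), and
prediction bands from whole-study replicates; empty bins are dropped with
a warning. Coverage tests run the band at 95% so that the ≥ 90%-of-bins
acceptance bound sits strictly inside the expected coverage rather than
on it.

## Problem sizes

Defaults were chosen as the analysis's own conditions: 30-subject
studies for estimation experiments, 10 seeds for recovery/selection
replications, 1000-subject cohorts for regimen tables, 10⁵ subjects for
calibration verification and for measuring small attainment percentages
(Monte-Carlo SE ≈ 0.1 points), 200–500 replicates for NPDE/VPC. The full
test suite runs in roughly ten minutes on a single CPU.

## Known limitations

* Elimination is strictly linear; no active-metabolite kinetics, no
  transdermal/IV routes, no enterohepatic recirculation.
* The calibrated exposure model compresses all between-subject
  variability into one factor: it reproduces peak-window attainment by
  construction but understates shape variability (e.g. in Tmax).
* The covariate search tests association on EBEs; it does not refit the
  full model per candidate, so heavily shrunk designs lose power.
* Safety percentages are not comparable to the published table (above).
* SEs assume the Fisher information is well-conditioned; sparse designs
  fall back to a pseudo-inverse with a warning.
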