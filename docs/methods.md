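# Methods

## Problem and data

A two-arm randomized trial (balanced 1:1:1 vs RBC-heavy 1:1:2 transfusion
strategy, 338 vs 342 trauma patients at 12 level-I trauma centers) reported
24-hour and 30-day mortality as arm-level *rates*, not counts, and the
patient-level data with site allocations are not public. The package
therefore works from three kinds of input: patient-level CSVs (real or
synthetic), per-site count tables, and reconstructed aggregates.

**Count reconstruction.** Deaths are recovered from a printed rate as
`round(rate * n)` with ties rounded half away from zero: 0.127 × 338 =
42.93 → 43 and 0.170 × 342 = 58.14 → 58, and 43/338, 58/342 print back as
12.7% and 17.0%. The 30-day rates are *not* exactly reproducible by any
integer count over 338/342 (76/338 prints as 22.5%, not 22.4%); the nearest
counts 76 and 89 are the documented default, and the classical 30-day point
estimates are additionally computed directly from the printed rates via
non-integer "effective counts" (that path yields the published −3.7%
difference and RR 0.86; integer counts give −3.5% and 0.86). The published
30-day difference interval (−10.2% lower bound) is 0.1 pp wider than the
Wald interval on the printed rates (−10.1%); its exact recipe is not
recoverable from the printed aggregates.

## Frequentist side

Risk difference with the Wald interval, risk ratio with the Katz log
interval, odds ratio with the Woolf log interval (all via statsmodels'
2×2 machinery), and the stratified two-sided Mantel–Haenszel chi-square
without continuity correction. The normal quantile is used at full
precision (1.959964…), not 1.96. Zero cells in ratio estimates receive the
Haldane–Anscombe 0.5 correction and the result is flagged; strata with an
empty margin are dropped from the MH test with a warning. With the standard
hypergeometric variance (denominator n²(n−1)), the single-stratum MH
statistic equals the Pearson chi-square only up to order 1/n; at the
trial's n = 680 the difference is below 0.01 and the test suite pins that
bound. For the same reason, splitting one stratum evenly into k strata
changes the statistic at order k/n (the (n−1) term becomes (n−k)); the
"invariance" is asserted as approximate.

## Bayesian side

Hierarchical Bernoulli logistic model: `logit P(death) = alpha + beta*x +
u_j`, `u_j ~ Normal(0, sigma^2)`. Patient records are aggregated to
site×arm binomials (identical likelihood). Priors: improper flat on alpha
and beta ("noninformative… uniform" is the stated intent of the original
analysis); on sigma a half-Student-t(3, 2.5) by default — the hyperprior
the original software family uses by default is not stated in the
publication, so the choice is treated as a sensitivity question: switching
to HalfNormal(1) moves P(effect < 1) by less than one percentage point on
trial-scale data (tested). With one stratum the site layer is dropped
entirely rather than degenerately estimated.

**Sampler.** Hamiltonian Monte Carlo, hand-authored and validated rather
than delegated: the posterior's gradient is analytic, a Laplace
approximation at the mode (L-BFGS, central-difference Hessian) supplies a
dense mass matrix, and the step size is tuned to 0.8 acceptance by
Nesterov-style dual averaging during burn-in, then frozen so the saved
draws form a valid Markov chain. Leapfrog paths are 12–16 steps, jittered
to avoid resonance. Chains are initialized at the mode plus half-Laplace-
scale Gaussian jitter (dispersed starts so split-R̂ is meaningful) and all
chains advance in one vectorized numpy stream keyed by the master seed,
which makes runs bit-reproducible on a platform. The hierarchical layer is
sampled in the non-centered parameterization (z_j, log sigma), which keeps
the geometry benign as sigma → 0. Divergent trajectories (energy error
< −50) are counted and reported; split-R̂ and ESS come from arviz, and any
R̂ > 1.05 flags the result with a warning rather than raising. The chain
plan follows the original analysis (4 × 1000 burn-in + 2000 saved = 8000
draws); at that size the Monte-Carlo SE of a probability near 0.93 is
≈ 0.3 pp, while the implied SE of the Bayes factor p/(1−p) is ≈ 0.8 — BF
values should be read with that noise in mind.

**Effect-scale identification.** The publication labels its Bayesian
effect "RR", but its printed values (0.72 and 0.82, and the whole
threshold-probability spectrum) are reproduced by exp(beta) — the odds
ratio from the logistic model — and not by the typical-site risk ratio
invlogit(alpha+beta)/invlogit(alpha): at the 24-h counts, P(effect < 0.7)
is ≈ 46% on the exp(beta) scale (matching the printed 46%) versus ≈ 36% on
the risk-ratio scale. The package computes odds-ratio, risk-ratio and
risk-difference scales; the exp(beta) scale is used wherever published
values are compared, and this identification is itself a tested property.

**Evidence summaries.** Credible intervals are empirical 2.5/50/97.5
percentiles with linear interpolation between order statistics. Threshold
probabilities use strict inequality (draw < t; a measure-zero convention
stated for reproducibility) and carry a binomial Monte-Carlo SE. The Bayes
factor is operationalized as posterior odds p/(1−p): under the uniform
prior the prior odds of the superiority hypothesis are even, and this is
the only reading that reproduces the published evidence table (85% → 5.7,
68% → 2.1, 46% → 0.9, 22% → 0.3). It is always computed from the unrounded
probability. Jeffreys bins: [1, 3.2) anecdotal, [3.2, 10) substantial,
[10, 31.6) strong, [31.6, 100) very strong, ≥ 100 decisive; BF < 1 is
classified by its reciprocal with the direction flagged.

## Validation oracles

Two independent routes check the sampler on the pooled (single-stratum)
flat-prior problem: (1) a conjugate beta-binomial posterior per arm,
sampled with 10⁶ Monte-Carlo pairs (fixed seed 20230421, MC SE ≤ 0.0005),
on both the risk-ratio and odds-ratio scales; (2) the closed-form normal
approximation Φ((ln t − ln OR)/SE) with the Woolf standard error. At the
trial's counts the two oracles agree within 0.01 and the sampler agrees
with both within three Monte-Carlo SEs. Note the oracles' Beta(1,1) prior
is flat on the risk scale while the sampler's prior is flat on the logit
scale; at these sample sizes the induced difference (≤ ~1 pp at
intermediate thresholds) stays inside the stated tolerance.

## Synthetic cohorts

The generator emulates the trial's design: fixed arm sizes (338/342),
12 sites with round-robin allocation (balanced within arm up to ±1),
Bernoulli outcomes from the same logistic model the analysis fits, and a
shared site intercept for both endpoints. Endpoint nesting (every 24-hour
death is a 30-day death) holds by construction: 30-day status is drawn at
the 30-day risk, then 24-hour deaths are subsampled at conditional rate
p24/p30. The trial-like preset sets baseline risks to the control-arm
printed rates (0.170, 0.261) and effects to logit(0.127) − logit(0.170) =
−0.342 and logit(0.224) − logit(0.261) = −0.202, so expected treatment
rates match the printed aggregates; the site-intercept SD defaults to 0.3,
an assumption — the trial reports no site-level counts — that pooled
aggregates are insensitive to. Draw order (site effects, then per arm one
uniform vector for 30-day and one for 24-hour status) is fixed so ports
can match summary statistics.

What the generator does *not* emulate: the trial's real (unbalanced) site
sizes and site-level event rates, covariates, enrollment over time, or
correlated endpoint structure beyond nesting. Passing tests therefore
demonstrate calibration of the method under its own assumptions, not
agreement with the trial's unpublished patient-level data.

## Problem sizes and numerical choices

Default analyses fit the pooled single stratum (the published aggregates
are arm-level; spreading counts over synthetic balanced sites and fitting
the full hierarchy moves every reported summary by well under the
agreement bound of 2 pp / 0.03 asserted in the tests). The calibration
study uses 100 trial-sized cohorts (β = −0.34, σ = 0.3) and checks 95%
credible-interval coverage against a binomial [90, 99] band plus
posterior-mean bias < 0.05. Laplace Hessians get an escalating diagonal
jitter if ill-conditioned; percentile and threshold conventions are stated
above; displayed values are rounded only at render time (probabilities to
whole percent, ratios to two decimals, BF to one decimal, infinite odds as
">999").

## Known limitations

- The original site-level allocations are unavailable; reconstructed
  pooled counts reproduce the published probabilities to within ~2 pp, but
  quantities that are steep functions of them (the superiority Bayes
  factor, posterior odds near p = 0.93) can differ by more: the exact
  flat-prior posterior odds at the reconstructable counts is ≈ 15.9 versus
  the published 13.7.
- Time-to-event endpoints (Kaplan–Meier, log-rank) require data the
  publication does not print and are out of scope, as are informative
  (skeptical/enthusiastic) prior analyses and covariate adjustment.
- The Bayes factor here is a posterior-odds summary, not a marginal-
  likelihood ratio; with non-uniform priors the two diverge.
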