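# Methods

## Data model

The unit of evidence is the (study, arm, outcome) cell of a long-format
table.  Treatments are dense integer codes `1..T` with treatment 1 the
network reference; a sidecar label map can carry display names.  Each arm
stores the number randomized `n`, its total person-years at risk `E`
(outcome-independent, shared by all outcomes of the arm) and/or the mean
per-patient follow-up `T̄ = E/n`; whichever of the two is absent is derived
from the other, and when both are present they must agree to a relative
tolerance of 1e-6.  Outcome missingness is at study level: a study either
reports an outcome on all arms or on none, and a missing outcome is an
absent row, never a zero.  Validation is total — every invariant
(format-1 first-event counts summing to at most `n` per arm, format-2
counts bounded by `n`, positive exposure, connected treatment network,
consistent arm metadata) is checked with study/arm coordinates in the
error message.  Arms are ordered, and the first arm's treatment is the
study's baseline `t_i1`; the consistency equation subtracts that
treatment's effect, which is what lets trials without a reference-treatment
arm (e.g. a 2-vs-3 comparison) contribute.

## The two models

Both are fixed-effect consistency models; preliminary-analysis support for
fixed rather than random effects in the motivating application is taken as
given, and random-effects extensions are out of scope.

**Simple odds-ratio model.**  Every count, whatever its format, is treated
as "patients with the event out of n": `r ~ Bin(p, n)`,
`logit(p) = mu_im + d_{t,m} - d_{t1,m}`, priors `mu, d ~ N(0, precision
1e-4)` (sd 100).  Counts above `n` — possible for format-3 data at high
rates — raise an error rather than being clipped: the model simply cannot
describe such data, and silently repairing them would hide exactly the
regime the package exists to expose.  (The one deliberate exception is the
constructed-data inflation procedure, whose capping rule is part of its
definition.)

**Shared-parameter hazard-ratio model.**  One hazard per cell,
`log lambda_ikm = omega_im + h_{t,m} - h_{t1,m}` with `h_1m = 0`, feeding a
per-format likelihood: Poisson total + multinomial first-event split
(format 1), binomial with complementary log-log link
`cloglog(p) = log T̄ + log lambda` for format-2 non-mortality outcomes with
Poisson(E·lambda) for a designated mortality outcome (death can occur at
most once, so "patients with at least one event" and "total events"
coincide and exposure-based Poisson counting is exact), and Poisson
products for format 3.  When no mortality outcome is designated — as in
the simulation scenarios, where neither outcome is death — every format-2
outcome uses the binomial/cloglog block.  All outcomes a format-1 study
reports enter its competing-risks block jointly; the module is generic in
the number of outcomes.  Priors are mean-zero normals parameterized by
*precision* (inverse variance) throughout: 0.5 (sd ≈ 1.41) for both
baselines and effects by default, 0.05 (sd ≈ 4.47) as the vague variant.
Hazards are modelled on the log scale and exponentiated inside the
likelihood, so positivity is structural and no clipping constants exist
anywhere.

**A useful identity.**  The format-1 block factorizes exactly:
Poisson(R; E·Σλ) × Multinomial(r; R, λ/Σλ) = Π_m Poisson(r_m; E·λ_m),
including all normalizing constants.  The vectorized engine exploits this
(format-1 cells are ordinary Poisson cells), and the test suite asserts
the equality against independently computed pmfs.  Two consequences are
worth spelling out.  First, the competing-risk "adjustment" for format-1
studies lives entirely in the *data* — first-event-only counts and the
realized, censoring-shortened person-years — not in an exotic likelihood.
Second, the conventional kernel bookkeeping in which the two formats'
likelihood kernels differ by a factor (1/Σλ)^R refers to kernels with the
total-count term absorbed; `equivalence.kernel_log_ratio_f1_f3` implements
that conventional ratio, whose hazard-dependent part is −R·log Σλ (zero
when R = 0, shrinking as events get rarer), and the tests verify the
remainder is hazard-free on a grid.

## Posterior computation

There is no external probabilistic-programming dependency; the sampler is
part of the package and operates on a flattened model: a cells × parameters
design matrix (entries ±1 from the consistency equation), per-cell family
codes (Poisson/log, binomial/cloglog, binomial/logit), offsets (log E or
log T̄) and count-dependent constants, so the flattened log-posterior equals
the reference pmf-based one to machine precision (asserted in tests).

All three families are log-concave in the linear predictor and the priors
are Gaussian, so the log-posterior is strictly concave.  A damped Newton
iteration with analytic gradient and Hessian therefore finds the unique
mode from any start; the negative inverse Hessian gives the Laplace
covariance.  Starting values are the empirical log crude rates with a
0.5-event continuity correction for baselines (used only for
initialization) and zero for effects.

Sampling is Metropolis–Hastings with two kernels:

* **independence** (default): multivariate Student-t proposals (df 8)
  centred at the mode with the Laplace covariance.  For these near-Gaussian
  concave posteriors acceptance is typically 0.3–0.6 and accepted draws are
  nearly independent, so a few thousand iterations give large effective
  sample sizes;
* **rwm**: random-walk Metropolis preconditioned by the Laplace Cholesky
  factor with the classic 2.38/√P scaling, kept as an independent
  cross-check (the suite verifies the two kernels agree, and verifies the
  sampler against an ensemble sampler and against 2-D quadrature on a
  two-parameter model).

Both kernels target the *exact* posterior; the Laplace fit only shapes
proposals.  Chains (≥ 2, default 2) run in parallel, and — the key to the
simulation study — independent replicate datasets sharing a design matrix
are batched into one vectorized run, which is what makes hundreds of
replicate fits per scenario affordable on one CPU.

Defaults are 500 burn-in and 4000 kept iterations per chain, reflecting
the independence kernel's efficiency; `BUGS_ANALYSIS_PRESET` (2 chains,
60k/30k, random-walk) and `BUGS_SIMULATION_PRESET` (30k/10k) reproduce the
long protocols traditional Gibbs-sampling software needs, for
compatibility experiments.  Convergence is monitored with the
Brooks–Gelman–Rubin potential scale reduction statistic for every
parameter (non-split form: within- vs between-chain variance); any value
above the threshold (default 1.05) flags the fit as non-converged — it is
reported, never silently re-run.  A mandatory seed in the config makes
every run reproducible, and CLI runs write a manifest (config hash, seeds,
versions).

Point estimates are posterior means; intervals are equal-tailed 2.5/97.5%
quantiles.  Ratio-scale summaries are statistics of exp(draws) — the mean
of the exponentiated draws, never the exponential of the mean — and
cross-outcome correlation matrices of each treatment's effect draws are
reported (degenerate, zero-variance draws yield NaN correlations rather
than invented values).

## Synthetic-data generator and simulation study

The study design is fixed: 10 two-arm trials on 3 treatments and 2
outcomes, 100 patients per arm, 1 year of follow-up; trials 1–4 report
format 1, trials 5–7 format 2, trials 8–10 format 3, with treatment pairs
(1,2), (1,3), (1,2), (2,3), (1,2), (1,3), (1,3), (2,3), (1,3), (1,2).
True log hazard ratios are h₂ = (−0.25, +0.25) and h₃ = (+0.25, −0.25) on
the two outcomes.  Per-trial baselines are calibrated deterministically and
exactly: for a trial comparing treatments (a, b),
ω = log(2·rate) − log(1 + e^(h_b − h_a)) per outcome, so the mean of the
two arm hazards equals the target rate to machine precision (the
alternative convention ω = log(rate), ignoring the ±0.25 offsets, is a
one-line change; the exact-mean choice is the package's).  The full grid
crosses average rates {0.05, 0.1, 0.2, 0.3, 0.4} per outcome — 25 cells.

Replicates are generated from the shared-parameter model's own generative
story:

* **format 1**: a latent cohort with independent exponential event times
  per outcome (the unique continuous-time mechanism whose first-event
  summaries match the Poisson/multinomial block and whose marginals match
  the cloglog link); each patient is censored at min(first event, 1 year),
  and the reported person-years are the *realized* censored exposure;
* **format 2**: per outcome, Binomial(n, 1 − e^(−λT)) patients with ≥ 1
  event, exposure nT;
* **format 3**: per outcome, Poisson(nTλ) total events, exposure nT.

Replicate seeds are spawned from the master seed by a counter-based
scheme, so any scenario is reproducible in isolation; identical master
seeds give bit-identical results.

What the generator does *not* emulate: multi-arm trials, varying sample
sizes or follow-up, more than two outcomes, a death outcome (so no
semi-competing censoring in formats 2/3), between-study heterogeneity,
within-study correlation beyond the first-event competition, and reporting
artefacts (rounding, zero-cell corrections).  Passing tests therefore show
correct behaviour of the estimators under a clean, correctly specified
competing-risks world — not robustness to the messiness of real extracted
trial tables.

Performance is scored per (model, outcome): **bias** is the mean of
(estimate − truth) pooled over the two non-reference treatments and all
replicates, with the per-replicate-sum normalization (sum over the two
treatments divided by the replicate count — twice the pooled mean when both
treatments complete) also reported as `bias_paper`; **coverage** is the
pooled proportion of 95% credible intervals containing the truth, with
binomial Monte-Carlo standard error √(c(1−c)/N) over the N pooled
intervals.  Replicates the simple model cannot describe (a count above n)
are excluded for that model only, counted, and logged with their seeds;
non-converged replicates are flagged and retained.  `required_nsim`
implements the standard sizing rule n ≥ max(sd²/target², p(1−p)/target²).

**Problem sizes.**  The package's own quantitative checks run the two
extreme diagonal cells at 300 replicates and the middle (0.2, 0.2) cell at
100, fitted with 2 chains × (500 + 4000) iterations — the batched engine
completes each cell in well under a minute.  The full 25-cell grid at 2500
replicates is the same call with different arguments.

## Constructed-data inflation

`inflate` multiplies every count by a factor (the canonical set is 1, 2,
5, 10, 20), capping each outcome at the arm's patient count, while leaving
n, E and T̄ untouched — holding person-time fixed is precisely what drives
the average event rates upward.  The per-outcome cap can leave a format-1
arm's first-event counts summing above n; such arms are reconciled by
proportionally scaling the capped counts back with largest-remainder
rounding (preserving relative outcome composition) and a loud log message.
This reconciliation is this package's rule; at extreme factors those cells
are exactly where any analysis becomes anomalous.  `average_event_rate` is
the unweighted mean of r/n over all reporting arms.

## Rare-event equivalence checks

Three exact numerical probes, with no asymptotic hand-waving:

* the conventional format-1/format-3 kernel log-ratio −R log Σλ (above);
* the total-variation distance between Binomial(n, 1 − e^(−λT̄)) and
  Poisson(nλT̄), computed by exhaustive summation over the finite support
  plus the Poisson tail — total variation is chosen because it is exact,
  symmetric and bounds the error of any event probability; the law-of-
  rare-events bound tv ≤ n·p² is verified on a grid;
* the odds ratio implied by a fixed hazard ratio at a given control
  hazard, with the discrepancy reported on the effect (log) scale,
  |log OR − h| / |h| — the scale on which an odds-ratio analysis is biased
  as an estimate of a log hazard ratio, which is the quantity the
  simulation study scores.  The event-rate threshold at which the
  discrepancy crosses any tolerance is an emergent output of the scan;
  no threshold constant is hard-coded anywhere.

## Numerical and design choices

* Newton damping halves the step per batch element until the log-posterior
  is non-decreasing; convergence at max |gradient| < 1e-9 (relative to the
  log-posterior scale), 100-iteration cap; the Laplace covariance is
  symmetrized before Cholesky.
* Degenerate inputs: r = n in binomial blocks is legal (p < 1 always);
  zero counts everywhere are legal (the Poisson zero term survives);
  zero hazards are structurally impossible; an arm with no exposure
  information raises.
* Interval-overlap flagging in comparison reports uses closed intervals —
  touching endpoints count as overlap — the conservative reading of
  "shaded if the intervals do not overlap".
* Coverage is pooled-marginal over (treatment, replicate) pairs, not joint
  over treatments within a replicate.
* Exposure is mandatory for every arm (there is no rescue path for a
  format-1 study reporting zero events with unknown person-years).
* The bias normalization ambiguity (mean over pairs vs per-replicate sum)
  is resolved by reporting both.

## Known limitations

* With the default precision-0.5 priors, the exact posterior at genuinely
  rare rates (≈ 0.05 events/person-year, ~5 events per arm) is materially
  prior-influenced: baselines sit 2+ prior standard deviations from the
  prior mean, so they are pulled upward, and the arm-level fit compensates
  by shifting treatment effects downward.  The simulation tests measure
  the resulting bias and sub-nominal coverage directly.  This is a
  property of the model at those sample sizes, not of the sampler (which
  is cross-checked against an independent ensemble sampler and
  quadrature); under the vague precision-0.05 priors the effect largely
  disappears.  Analysts applying the shared model to very sparse networks
  should treat the default priors as informative and say so.
* Fixed effects only; no heterogeneity, inconsistency or node-splitting
  diagnostics; no ranking probabilities or model-fit statistics (DIC).
* The simple model's intervals at high event rates are honest posterior
  intervals for the *wrong* estimand (an odds ratio standing in for a
  hazard ratio); the package quantifies, but does not correct, that
  divergence.
* The independence kernel's efficiency rests on posterior concavity and
  near-Gaussianity, which hold for these GLM-like likelihoods; for very
  sparse data its acceptance rate drops and the random-walk kernel or
  longer chains are the fallback (low acceptance and high R̂ are both
  reported).
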