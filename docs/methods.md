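# Methods

## Generative model

A trial is a two-timestep partially observable Markov decision process
over three hidden states (`start`, `high`, `low`) and three observations
(`start_obs`, `high_cue`, `low_cue`). The initial-state vector D is
degenerate at `start`; the transition matrix B sends `start` to `low`
with probability pB and `high` with 1−pB, and makes both bounce states
absorbing; the likelihood matrix A emits the matching cue with
probability SP in either bounce state. Only the perceptual-inference
half of active inference is used — there is no action selection, and the
horizontal (left/middle/right) response dimension is not modelled.

The direction of pB deserves a note: pB is the probability of the
*low*-bounce transition, so values above 0.5 encode a prior that low
bounces are more likely. Both free parameters live on the open interval
(0, 1); boundary values are rejected.

The cue presented at t = 2 is always the clip's veridical outcome, the
same in every occlusion condition. Occlusion is treated as a fitting
cell, not an observation-level manipulation: poorer viewing conditions
are expected to express themselves as lower fitted SP in that cell.

## Belief updating

The implementation iterates the two softmax update equations
(s̄₁ = σ(½(ln D + ln Bᵀs̄₂) + ln Aᵀo₁), s̄₂ = σ(ln B s̄₁ + ln Aᵀo₂)) to a
fixed point with tolerance 1e-9 (maximum 100 sweeps; one pass suffices
because D is degenerate). Exact zeros produce −∞ log-messages that are
carried through and excluded by the softmax — equivalent to restricting
inference to the feasible states analytically, with no finite log-floor.
A grouping ambiguity in how the ½ factor applies to the t = 1 equation
is moot here: with D degenerate, s̄₁ is forced to (1, 0, 0) under either
reading. The resulting posterior equals the two-state Bayes closed form
P(high | high cue) = (1−pB)SP / [(1−pB)SP + pB(1−SP)], and the test
suite holds the iterative path to that closed form at 1e-9 over random
parameter draws.

Responses are probability matching: P(respond "high") is the posterior
itself, not an argmax-plus-lapse rule. The likelihood of a trial clips
the response probability to [1e-8, 1−1e-8] before the logarithm so that
contradictory data under extreme parameters stay finite.

## Estimation

(SP, pB) are estimated per participant by MAP. Parameters are mapped to
the real line by the logit transform, given independent Gaussian priors
with mean 0 (= logit 0.5) and precision 1/2, and the penalized
log-likelihood is maximized by L-BFGS-B from five deterministic start
points (the origin plus four seeded N(0, 2) perturbations, guarding
against plateaus from clipped likelihoods). The logit parameters are
bounded at |θ| ≤ 8 (native ≈ 0.99966) so perfectly separable data
cannot diverge. Convergence is judged by the projected gradient at the
returned optimum (norm < 1e-4 per coordinate, with active bounds
allowed a one-sided gradient) rather than the raw optimizer status,
which can report an abnormal line search after the gradient is already
at finite-difference resolution. The choice of MAP point estimation —
rather than a full variational-Laplace posterior — reflects that only
point estimates are consumed downstream; posterior covariances are a
non-goal. The prior precision of 1/2 is applied on the logit scale, the
standard scale for this estimation scheme.

The dataset log-likelihood depends on the data only through the 2×2
cue × response counts, and on the trial only through its cue, so
objective evaluations cost a handful of float operations. A grid-search
oracle (exhaustive evaluation at configurable resolution, ties broken
toward (0.5, 0.5)) validates the optimizer; the suite requires agreement
within 0.005 on the native scale at 0.001 resolution.

Per-cell fits partition trials by kick type × occlusion (six cells; the
smallest, chip × PC, has 14 trials) and fit each independently with the
same settings. Cells with a single response class are handled by the
shrinkage prior rather than special-cased.

## Synthetic data

No participant data are deposited, so the generator stands in for them.
It reproduces the stimulus design exactly: 23 grubber and 14 chip clips,
each shown at three occlusion points (111 trials), with 16 low / 7 high
grubber clips and 7 / 7 chip clips — the only clip-level composition
consistent with the reported 48/21 and 21/21 trial totals. Trial order
is a seeded shuffle, rejection-sampled (up to 1,000 tries) so no clip
appears on consecutive trials, mirroring the sequencing check applied to
the real test video.

Simulated responses are Bernoulli draws from the model posterior, so a
simulated responder is exactly the model plus binomial noise. Real
observers differ in ways the generator does not emulate — lapses,
response biases unrelated to the cue, learning across the session, and
any use of kinematic information beyond a binary cue — so passing tests
demonstrate internal consistency of the pipeline, not validity of the
model for human data.

Default cohort distributions (all configurable) were fixed once to a
qualitatively realistic pattern: expert SP centred at 0.66/0.78/0.80
across PC/BF/PC&BF versus novice 0.56/0.64/0.66 (SD 0.06), expert pB
centred at 0.40/0.45/0.48 — prior weight attenuating as later cues
emerge — versus a flat novice 0.45 (SD 0.05), sampled from normals
truncated to (0.02, 0.98). These defaults are illustrative of the
expected group pattern, not estimates of any real participants.

## Parameter recovery

Recoverability draws true parameters uniformly — SP from (0.4, 0.95),
the informative regime, and pB from (0.2, 0.8), symmetric about
indifference — simulates one 111-trial responder per draw, refits, and
summarizes agreement as the squared Pearson correlation (equivalent to
simple-regression R²). The default run uses 100 simulations with
overall (not per-cell) fits. Non-converged fits are excluded with a
logged count. Under these conditions recovery is strong for both
parameters (r² ≈ 0.9); the exact value depends on the sampler, which is
a free choice of the analysis since no canonical grid exists.

## Screening and reporting

Fitted parameters are screened per parameter per cell across
participants: values more than 3 sample SDs from the mean (z computed
once, non-iteratively) are Winsorized to 1% beyond the next most
extreme non-outlying score on the same tail — "beyond" meaning 1%
larger in magnitude away from the centre, which matters only if a
parameter could be negative (here it cannot). On near-constant vectors
a second screening pass can flag the replacement again, but it maps to
the same value, so the output is stable under re-screening.

The summary table reports per group × cell the mean, sample SD, t-based
95% CI and n for SP, pB, the absolute prior strength |pB − 0.5|, and
the SP/pB ratio. Group-level inferential statistics (mixed models,
Bayes factors, model selection, power analysis) are deliberately out of
scope; the tidy table is the hand-off point.

## Reproducibility

Every stochastic stage takes an explicit seed. The command-line
pipeline fans a single master seed out to stages through fixed
per-stage counters (`SeedSequence([master, counter])`), so any stage
can be rerun independently and byte-identical artifacts (tracked by a
SHA-256 manifest) result from identical configs.

## Known limitations

- SP and pB are relative, bounded quantities; their absolute values
  depend on the shrinkage prior and are not interpretable as calibrated
  probabilities.
- With only two distinct cues per cell, the two parameters are
  identified through two response rates; small cells (14 trials) give
  noisy per-cell estimates, and the absolute prior strength |pB − 0.5|
  of noisy estimates is biased upward.
- The recovery r² exceeds the high-0.8 range reported for the original
  MATLAB estimation pipeline; with the sampler unstated there, exact
  agreement is not expected, and the analysis treats r² ≥ 0.75 as the
  substantive claim (parameters are recoverable at the study's trial
  count).
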