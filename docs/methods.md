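# Methods

This note documents the models implemented in `asrc`, the defaults of the
synthetic-data generator, the numerical choices made where the design was
genuinely open, and the limits of what the test suite establishes.

## 1. The agent model

An agent carries a scalar skill belief `s` (unbounded) and experiences
binary outcomes `o ∈ {0, 1}`.  Two coupled mechanisms define the dynamics:

- **Attribution generation.**  The probability of an internal attribution
  is `σ(β_w (s − x_0w))` after a win and `1 − σ(β_l (s − x_0l))` after a
  loss.  The indifference points `x_0w, x_0l` encode valence-specific
  biases; the slopes `β_w, β_l ≥ 0` encode sensitivity of attribution to
  the current belief.  Negative slopes are rejected: they would invert the
  postulated direction of the coupling, and no analysis here uses them.
- **Belief updating.**  `s ← s + α_{a,o} (o − σ(s))`, with four learning
  rates indexed by the (attribution, outcome) cell, each in [0, 1].  The
  expectation entering the prediction error is `σ(s)`, so beliefs saturate
  naturally at extreme values.

Ensembles share one fixed outcome schedule (a fair coin drawn once per
experiment and reused across runs), so all run-to-run variability is
attributable to the stochastic attribution draws.  Three named parameter
sets are bundled: `control` (x₀ = 0, 0; β = 2, 2; α = 0.1/0.05 internal/
external for both valences; s⁰ = 0), `amplifying` (x₀w = −0.03, β_w = 100,
β_l = 1, internal α = 0.15, external α = 0) and `vulnerable` (β_w = 0.5,
β_l = 5, α internal-win 0.12, internal-loss 0.15, otherwise control).

The decoupling ablation replaces the sigmoid attribution rule with i.i.d.
draws at the *coupled* ensemble's empirical internal-attribution rate,
matched separately for wins and losses (the rule conditions on outcome, so
propensity matching is done per valence).  The default trial count is 150
(the regime figures do not pin it down; it is configurable everywhere),
100 runs per ensemble, 300 for the amplification regime, and a 25-loss
streak for the vulnerability contrast.

Skill quintiles in the attribution-by-skill summary are computed from the
pooled distribution of pre-update beliefs across all runs and trials, with
ties broken by rank order; whether pooling or per-run binning is used is a
free choice and pooling gives the better-populated cells.

## 2. Synthetic task and generator

The experiment structure being emulated: trials come in pairs; after every
second trial the participant gives an attribution (ability, maze,
rotations, luck — or no answer) and then a skill report on a [0, 1]
slider; the first half of the probes form session 1, the second half
session 2.

- **Difficulty control.**  A double staircase: two interleaved 1-up/1-down
  tracks over a scalar difficulty in [−3, 3] with step 0.25, alternating
  between trials.  One-up/one-down tracks converge on the 50% point of the
  psychometric function, so the population win rate sits near 0.5
  regardless of where abilities lie (verified by simulation); the
  interleaving mirrors the original design's resistance to participants
  gaming the adaptation.  The detailed staircase of the original task is
  not public, so this is a deliberately generic stand-in reproducing its
  stated behaviour.
- **Outcome model.**  `p(win) = σ(κ (ability − difficulty))`, κ = 2 by
  default.  This is plumbing invented for the generator, not measured task
  psychophysics; κ sets how sharply the staircase sees ability.
- **Features.**  Path length and non-UP orientation time increase affinely
  with difficulty (plus noise, clipped); key-press accuracy is
  `σ(ability + noise)`; pauses are bounded Beta(2, 10) noise.
- **Probe responses.**  The attribution is sampled from the participant's
  softmax attribution model and replaced by `missing` with probability
  `missing_prob` (default 0.1); the latent skill then advances by the
  Rescorla–Wagner rule using the attribution class just produced, and the
  report is the latent value plus N(0, 0.1) noise, clipped to the slider.

Only probed trials enter the fitted recursions: attribution-dependent
learning rates need an attribution label per update, and unprobed trials
have none.  Within a probe the attribution precedes the report, so the
response series alternates A, S, A, S, … and "previous skill estimate"
always means the report preceding the current attribution.

One intentional approximation: fitted attribution models z-score the skill
feature within participant, which requires the full series, while the
generator runs forward in time; it therefore standardises the previous
report with fixed constants (location 0.5, scale 0.2).  The other features
are z-scored identically in generation and fitting.  The mismatch is a
monotone affine one and leaves weight signs untouched; sign-recovery
experiments confirm this.

The default cohort is 40 participants × 120 probes (two sessions);
recovery experiments in the test suite use 20 × 120.  Population defaults:
abilities N(0, 1); learning rates Beta with mean 0.15 (concentration 40)
with internal rates 0.1 above external ones for attribution-aware
generators; initial skill Beta with mean 0.5; session offsets N(0, 0.02);
attribution biases +0.5 (internal, wins) and −0.5 (internal, losses) and
skill-feature weights +0.8 / −0.8 around which individual weights scatter
with s.d. 0.3.  These are one-off choices of plausible magnitudes for a
learning task of this kind, fixed before any recovery run.

Beware a selection artefact when analysing generators whose attributions
depend on the skill feature: conditioning on (say) internally attributed
losses selects low previous reports, and regression to the mean then
biases the following z-scored update upward, competing with the
learning-rate contrast.  This mirrors the non-orthogonality of attribution
and outcome in real data; the model-based analyses (which condition on the
whole trajectory) are the appropriate tool there, and the README's
model-agnostic example uses a bias-only generator for exactly this reason.

## 3. Skill-report models

`δ_t = o_t − s_{t−1}`; `s_t = s_{t−1} + α δ_t`, plus an offset β at the
first probe of session 2.  The learning rate is indexed by any subset of
{session, outcome, attribution class}, giving the family b, S, O, A, SA,
SO, AO, SAO with 1–12 rates; the A factor has three levels because
missing-attribution outcomes get their own rate.  For specs without the A
factor, probes with missing attributions still update the skill using the
spec's relevant rate.  Reports are N(s_t, 0.1) readings; "0.1" is read as
a standard deviation (a variance of 0.1 would mean slider noise of ±0.32,
implausibly coarse).  The latent state is clipped to [0, 1] after each
update to respect the slider range (the recursion itself is otherwise
unbounded); missing reports drop out of the likelihood while the recursion
advances through them.

## 4. Attribution-choice models

Scores `s_o = w_o · f` for ability, maze and rotations; the luck score is
the negative sum, so the four scores sum to zero for every feature vector
and the softmax is identified.  Weights are valence-specific throughout.
Feature sets: bias-only (6 parameters per participant), bias + skill (12),
bias + performance (18), bias + performance + task (30), bias + skill +
task (24), full (36).  Continuous features are z-scored within participant
before fitting (the same convention as the model-agnostic pipeline; raw
scaling is not recoverable from choices anyway).  The skill feature at
probe t is the z-scored report from probe t−1, 0 at the first probe.

Transforms: baseline preferences are the softmax of bias terms alone; the
average marginal effect of feature x on option A after outcome o is the
analytic softmax derivative `p_A (w_{A,x} − Σ_B p_B w_{B,x})` evaluated at
x = 0 with other features at trial values, averaged over the trials whose
outcome matches the valence — weights are valence-specific, so the
derivative is only defined on valence-matched trials.  The analytic form
is verified against central finite differences to 1e−6.

## 5. Posterior sampling

No probabilistic-programming backend is assumed; the sampler is an
adaptive Metropolis-within-Gibbs scheme written for exactly these two
model shapes (smooth likelihoods, 5–36 parameters per participant):

- individual parameters are updated one at a time by Gaussian random-walk
  proposals in their native space, with per-coordinate scales adapted
  during warmup toward 44% acceptance and frozen afterwards;
- in hierarchical mode, unit-interval parameters get Beta(a, b) population
  distributions (the session offset is mapped to (0, 1) via (β + 1)/2 so
  the same family applies) and unconstrained weights get Normal(μ, σ);
  hyperparameters are Metropolis-updated per sweep — a, b and σ on the log
  scale — under Gamma(2, 2), Normal(0, 5) and half-Normal(2.5) hyperpriors;
- independent mode uses flat priors over bounded supports, Normal(0, 1)
  for the skill session offset and Normal(0, 2.5) for attribution weights.

Sampler correctness is checked on conjugate toys (Normal–Normal and
Beta–Bernoulli closed forms, agreement within Monte-Carlo error) and
cross-checked against an affine-invariant ensemble sampler on a shared
posterior.  Split-R̂ and bulk ESS are computed for every scalar parameter;
R̂ > 1.05 raises a warning, not an error — short desk-scale chains
(default 2 chains × 300 post-warmup sweeps, equal warmup) trade polish for
speed, and the documented full setting is 4 × 1000.  Seeded runs are
bitwise reproducible.

## 6. WAIC and comparison

WAIC is computed at the participant grain: minus the average over
participants of the log posterior-mean likelihood (log-sum-exp), plus the
average posterior variance of the per-participant log-likelihood.  The
variance uses the n−1 convention (the convention is not dictated by the
formula; with hundreds of samples the difference is negligible but a
definite choice is needed for the exactness tests).  Smaller WAIC is
better.  Comparisons refuse fits whose data fingerprints differ.

The shuffle refit permutes each participant's attribution labels
(preserving counts), refits an A-containing spec, and records the across-
participant mean internal−external learning-rate contrast per session ×
outcome cell, yielding a null distribution against which the observed
contrast is compared.  The desk default is 50 permutations; the full
published-scale analysis would use 1000.

## 7. Permutation statistics

- Updates are first differences of within-participant z-scored reports
  (n−1 s.d.; a constant series warns and yields zeros rather than failing
  a whole cohort).
- The paired test shuffles condition labels within participant, recomputes
  per-participant cell means and takes the paired t across participants;
  p-values use (k + 1)/(n + 1) two-sided, and the zero-exceedance case is
  reported alongside as "p < 1/n_perm".
- Hedges' d follows the bias-corrected formula with pooled (l − 1)-weighted
  s.d.
- Quartiles of continuous factors are assigned by rank on the z-scored
  values, giving balanced bins under ties; proportions are taken out of
  non-missing attributions per cell.
- The interaction F is the classical two-way repeated-measures
  decomposition (interaction mean square over the interaction × subject
  residual mean square), verified against an explicit sums-of-squares loop
  and against an independent ANOVA implementation.  The permutation null
  shuffles each participant's raw factor values before re-binning; since
  rank bins are a deterministic function of the value multiset, this is
  implemented as a shuffle of the precomputed bin labels.  A cell left
  empty by a permutation (rare; only possible when a bin draws a single
  outcome) is filled with the participant's outcome-marginal rate, which
  is permutation-invariant.
- Benjamini–Hochberg runs through the standard step-up procedure.

Both permutation tests are calibrated: over 500 null simulations the
rejection rate at α = 0.05 stays within [0.03, 0.07] (checked in the test
suite at 200 permutations per test).

## 8. Problem sizes and limitations

The test suite and acceptance checks run at deliberate desk scale: 20
participants × 120 probes for recovery, 2 chains × 300 sweeps per fit,
500-replicate calibrations at 200 permutations, and 120 synthetic players
× 180 trials for the staircase equilibrium.  These sizes were chosen as
the smallest at which the respective effects are clearly resolved.

What passing tests do *not* show: the generator draws i.i.d. Gaussian
report noise (no autocorrelated sloppiness, no lapses), its outcome model
is a one-parameter logistic rather than real game physics, abilities are
stationary (no within-session learning of the actual skill), and missing
responses are missing completely at random.  Recovery results here bound
what is achievable under the model's own assumptions; real data can only
be harder.  The component-wise sampler mixes slowly for strongly
correlated posteriors (e.g. rates that share few probes); R̂ warnings at
desk scale are expected and the remedy is more iterations, not a different
estimator.
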