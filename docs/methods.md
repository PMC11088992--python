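# Methods

## The generative model

`attrinf` implements a discretized Bayesian observer for paired
intentional attributions in an iterated Dictator game ("Sharing
Game"). On each of 6 trials per partner (3 partners), a partner either
takes the whole £0.10 stake (unfair, `rew = 0`) or splits it (fair,
`rew = 0.5`); after each outcome the observer reports, on 1–100
scales, how strongly the partner seemed motivated by harmful intent
(HI) and by self-interest (SI).

Beliefs live on a 9 × 9 joint probability grid over discretized
(HI, SI) levels.

**Priors.** Each marginal is a binomial pmf `B(k; 8, p0)` evaluated at
`k = bin − 1`, raised elementwise to `1/uPri` and renormalized. `p0`
locates the prior (`pHI0`, `pSI0`); `uPri > 0` is a temperature:
`uPri = 1` is the plain binomial, `uPri → ∞` flattens to uniform, and
`uPri < 1` sharpens. The joint prior is the outer product of the
marginals.

**Policy likelihood.** The observer's internal model of a partner of
character (HI, SI) acting unfairly is
`π(rew=0; HI, SI) = σ(w0 + wHI·(HI − δ) + wSI·(SI − δ))` with
`δ = (9+1)/2` and `σ` the logistic function. Centring on `δ` makes
`w0` the log-odds of an unfair act for a "neutral" partner. The fair
slice is the exact complement.

**Update, consistency, change point.** After each outcome the grid is
multiplied by the matching likelihood slice and renormalized (Bayes'
rule); then tempered, `p ← (p^{1/uπ} + ξ)/Σ`, with `ξ = 0.02/9² ≈
2.47e−4` fixed (not fitted). Large `uπ` means the partner's behaviour
is not taken as indicative of character (beliefs are pulled toward
uniform); `uπ = 1` leaves the posterior untouched apart from `ξ`. When
a new partner is introduced the starting belief is the convex blend
`(1−η)·prior + η·last posterior`: `η` is the carry-over (learning from
recent encounters) weight.

**Response model.** Ratings map to bins by equal-width intervals
(`ceil(rating·9/100)`); the report log-likelihood of a trial is the
log joint mass of the indexed cell, floored at 1e−12, evaluated on the
post-update, post-consistency grid (ratings are made after observing
each outcome). Simulated agents sample a cell from the joint grid and
report its bin centres; the deterministic prediction used for
generative-performance checks is the belief-weighted mean rating.
The joint cell (rather than the product of marginals) is used for both
directions because the model's state is inherently joint; this is the
simplest internally consistent contract.

**Variants.** M1 frees all nine parameters; M2 ties `wHI = wSI` (one
likelihood weight); M3 ties `uPri_HI = uPri_SI` (one prior
uncertainty, eight free parameters). M3 is the winning variant for
this task and is the default throughout.

## Hierarchical estimation

Parameters are estimated in an unconstrained native space (logistic
transforms for `pHI0`, `pSI0`, `η`; log transforms for `uPri`, `uπ`;
identity for the weights) under Gaussian group priors initialized at
mean 0, sd 6.5. Per subject and candidate model, a multi-start
L-BFGS-B search (default 10 starts, bounds ±20) maximizes the log
posterior; the model evidence is the Laplace approximation at the
mode, with the Hessian from central finite differences (step 1e−4,
regularized to positive definite by jitter, then eigenvalue clipping).

The group level is an empirical-Bayes EM: subject responsibilities are
proportional to model frequency × exp(evidence); group means and
variances are responsibility-weighted moments of the subject modes,
with each subject's Laplace posterior variance added to the spread
term. Model-comparison evidences are the ones computed on the first
sweep, where every candidate is evaluated under the stated broad
prior: there the Laplace integral carries the usual Occam penalty for
extra parameters. Evidences under later, empirically adapted priors
lose that penalty — the adapted prior absorbs each model's
flexibility, which would systematically favour the most flexible
nesting variant — so they serve parameter estimation only. Two
numerical guards matter in practice: per-subject posterior variances
and group variances are both capped at the initial 6.5² prior (flat
likelihood directions otherwise inflate `inv(H)`); the cap is static
because capping at the *current* prior variance would let a
low-responsibility model's group variance only ever shrink, a ratchet
that collapses its prior onto the variance floor. Model
frequencies follow a Dirichlet count update (prior count 1 per
model); exceedance probabilities are Monte-Carlo estimates from the
Dirichlet posterior (10⁵ draws), and the protected variant mixes the
estimate 50:50 with the equal-frequency null. Convergence is declared
when the frequency-weighted maximum group-mean shift falls below 1e−3
(cap 50 iterations); a model that explains almost no subjects may
keep drifting without affecting the fit, which is why shifts are
frequency-weighted. After the first sweep each subject is re-fitted
from its previous mode plus a few fresh starts; pure warm-starting
was observed to strand subjects in stale local optima as the group
prior tightens. Conditions are fitted independently because the same
subjects appear in every condition.

## The synthetic cohort

The generator emulates the study design: 28 subjects × 3 within-
subject conditions (placebo-, haloperidol- and l-DOPA-like) × 3
partners × 6 trials, partner order randomized per subject, partner
policies "always take half", "50:50 chance" (independent Bernoulli
draws by default; a balanced 3/3 shuffle is available) and "always
take all". The design is a crossover: each subject receives one
native-space parameter draw, and non-reference conditions add the
preset's mean shift plus a condition-specific jitter at 0.4 of the
between-subject spread, so individual differences persist across
conditions as they do in a real within-subject cohort.

Preset locations and spreads are the package's own design, since the
study's fitted values are not printed. They were chosen, before the
acceptance suite was frozen, by a profile-likelihood analysis to sit
in the *identifiable plausible region* of the model: binomial priors
at roughly `uPri ≈ exp(−0.6)` (moderately sharp), consistency near
`uπ ≈ 1`, likelihood weights near 0.8–0.9 so partner behaviour
visibly moves beliefs, an unfair-averse intercept `w0 ≈ −1`, and a
broad spread on `η`. In flat corners of the parameter space (near-
uniform priors, heavy tempering) the equations still invert exactly
but single subjects carry almost no information about several
parameters, and no estimator can recover them from 18 trials. The
haloperidol-like preset shifts `wHI` by +0.10, `η` by +0.65 native
(≈ +0.15 in η units) and `w0` by +0.6 toward zero — the directions
and approximate magnitudes of the drug contrasts reported for this
task; the l-DOPA-like preset equals placebo.

What the generator does *not* emulate: continuous rating scales
(reports are bin centres, so nine distinct values), anchoring or
autocorrelation in slider use, within-session drift, and any real
between-subject correlation structure beyond the single crossover
term. Passing recovery tests therefore show that the pipeline inverts
its own generative process at realistic size and noise — not that the
original study's numbers are reproduced from its data.

## Recovery study

The recovery study is two-stage, mirroring the original procedure in
which synthetic participants are built "one for each parameter set
approximated from the data": stage 1 generates a reference cohort
from the spec and fits it per condition; stage 2 simulates a replica
cohort from exactly those fitted individual-level parameter sets
(same partners and outcomes) and re-estimates them identically.
Parameter recovery is the native-space Pearson correlation between
stage-1 parameter sets and their stage-2 re-estimates, pooled over
all 84 subject-condition pairs; the acceptance benchmark is r ≥ 0.71
for every free parameter. Generative recovery compares the fitted
model's expected attribution series with the fitted-to ratings within
each Dictator policy and dimension (benchmark r ≥ 0.62). Correlating
two independently *sampled* report series would instead be bounded by
single-draw reliability, which is not what the generative-performance
figure measures.

## Downstream statistics

* **Paired contrasts.** The paired differences are modelled as
  Gaussian under the Jeffreys reference prior; the posterior of the
  mean is the analytic shifted-scaled Student-t (median and central
  95% interval are exact), and the posterior of Cohen's d is
  summarized from 20,000 conjugate Monte-Carlo draws. The interval is
  equal-tailed; for these unimodal posteriors it is numerically close
  to the highest-density interval.
* **Precision.** Inverse variance (ddof = 1) of each 18-trial rating
  series per subject × condition × dimension, with a within-policy
  variant; zero-variance series are flagged and excluded, never
  reported as infinite. The precision regression uses wHI linearly,
  w0 linearly and quadratically, their interaction, and policy terms
  when records are within-policy; regressors are centred and scaled,
  and the quadratic-w0 model's AIC is reported against the linear-w0
  variant.
* **Coupling.** Per condition and global trial index, the
  across-subject partial correlation between HI and SI ratings with
  Dictator-policy indicators partialled out (rank-transformed first
  for the default Spearman flavour; Pearson available — both wordings
  appear in the source literature, so both are exposed). The decay
  statistic is the Pearson correlation of the 18 per-trial
  coefficients with trial index; condition contrasts reuse the paired
  Bayesian contrast on per-trial coefficients.
* **Factor analysis.** Columns standardized; iterated principal-axis
  factoring (communalities initialized at squared multiple
  correlations, pseudo-inverse throughout so duplicated columns
  degrade gracefully); promax (κ = 4) oblique rotation; factor count
  defaults to the Kaiser criterion and is otherwise caller-chosen;
  scores by the regression method; each factor sign-oriented so its
  dominant loading is positive. A dedicated `factor_analyzer`-style
  dependency is not used; the implementation is validated against a
  synthetic two-latent-factor oracle and column-order invariance.
* **Discrimination.** For 1..K-factor solutions, repeated stratified
  k-fold (10 × 3 by default, folds shrunk when a class is small)
  cross-validation of an unpenalized logistic classifier on factor
  scores; full-data AIC per solution; ROC/AUC and Youden-point
  sensitivity/specificity for the best solution.

## Problem sizes and determinism

Default problem sizes are those of the emulated study (28 subjects, 3
conditions, 18 trials). The model-identification check runs a
16-subject single-condition cohort against all three variants, and the
directional fingerprint checks use larger simulated cohorts (40–100
subjects) because they are pure-simulation sign checks whose precision
is limited only by cohort size. All randomness flows through seeded
`numpy` generators with stage-namespaced substreams; identical
configuration and seed reproduce byte-identical artifacts. The hot
likelihood kernel is numba-compiled with a pure-numpy fallback that
produces identical results.

## Known limitations

* The hierarchical scheme is a Laplace/empirical-Bayes approximation
  to full variational random-effects inference; evidence values are
  approximate and responsibilities can be overconfident for small
  cohorts.
* `η` and `uPri` are weakly identified per subject (two partner
  boundaries, 18 binned reports); their recovery depends on the
  hierarchical prior and on cohort spread more than other parameters.
* The coupling contrast between haloperidol- and placebo-like presets
  is real but small at n = 28 (the study-scale effect reported from
  real data is larger than what the preset mean-shifts alone induce);
  sign checks therefore use larger simulated cohorts.
* Exceedance probabilities use a fixed 0.5 null weight for the
  protected variant rather than an estimated Bayes omnibus risk.
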