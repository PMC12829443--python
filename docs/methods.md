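# Methods

## The task and the data

The package models US-expectancy ratings from a remotely delivered
differential fear-conditioning paradigm.  Two visual cues are presented in
pseudorandom interleaving: a threat cue (CS+) reinforced with an aversive
noise (US) on 75% of acquisition trials (9 of 12), and a safety cue (CS-)
never reinforced.  Acquisition comprises 12 trials per cue, extinction 18
per cue with no reinforcement.  At every trial the participant rates, on a
discrete 1-9 scale and before any US is delivered, how certain they are
that the noise will follow.  Alongside the task, participants complete the
GAD-7 anxiety and PHQ-8 depression questionnaires and a post-experiment
compliance questionnaire (headphone removal, volume, app restarts, US
unpleasantness, contingency awareness).

The `schedule` module generates this trial structure.  Pseudorandomisation
is implemented as uniform rejection sampling: cue orders are resampled until
no more than `max_cue_run` (default 2) consecutive trials share a cue, and
the 9 reinforced CS+ trials are chosen uniformly subject to no more than 2
consecutive unreinforced CS+ trials.  Inter-trial intervals are drawn
uniformly from {1, 2, 3} s and carry no role in the model; they are recorded
for format fidelity.  Whether the original schedules varied across
participants is unknown; the generator defaults to one shared schedule per
cohort, with per-seed variation available.

## The generative model family

Each cue carries an associative value V in [0, 1], initialised at 0.5 (the
scale midpoint) and updated by the Rescorla-Wagner delta rule

    V_{t+1} = V_t + (US_t - V_t) * LR,

with US in {0, 1} and learning rate LR in [0, 1].  Ratings are generated by
an ordinal beta-link: V is the mean of a beta distribution with fixed
precision phi = 10, reparameterised to shapes alpha = V*phi, beta =
phi - V*phi; the beta kernel is evaluated on nine equally spaced grid points
over [0, 1] and normalised into a probability vector P; finally theta =
softmax(P * lapse) gives the categorical rating probabilities.  The lapse
acts as an inverse temperature on the ordinal probabilities: small values
flatten responding toward uniform, large values concentrate it on the mode
of P.

Two numerical guards keep the likelihood finite everywhere.  The grid
endpoints 0 and 1 are clipped to [1e-6, 1 - 1e-6], because the kernel
Q^(alpha-1) diverges at Q = 0 whenever alpha < 1 (possible since alpha =
10V).  V itself is clipped to the same band before the shape
reparameterisation, since V in {0, 1} would put a beta shape exactly at
zero.  For alpha, beta > 1 the perturbation is of order 1e-24 and
numerically invisible.

The family crosses seven learning-rate structures — from a single shared
rate (structure 1) up to five rates split by cue, phase, and US delivery
(structure 7) — with four fitting variants: (a) fixed 0.5 start values,
(b) free per-cue start values, (c) a free "jump" added to the CS- value at
the acquisition-extinction boundary (clamped at 1), capturing threat
generalisation at the phase change, and (d) both.  This yields 28 models,
labelled 1a-7d.  For the outcome-contingent structures (5-7), the
non-aversive rates govern every trial on which no US is delivered:
unreinforced CS+ acquisition trials, all extinction CS+ trials, and
(structure 5) all CS- trials — the only reading under which the presence of
the US alone moderates the rate.  Variant b fits two start values, one per
cue, matching how the original results tabulate separate CS+ and CS-
initial values; a single shared start value is the main plausible
alternative reading and would be a one-line change.

Ratings are elicited before the outcome, so the likelihood of a rating uses
the pre-update value of the presented cue; the update is applied afterwards.
Trials with a missing rating contribute neither a likelihood term nor a
value update — the update occurs at the next rated trial.  The alternative
convention (update on missing trials when a US occurred) is available via
`update_on_missing=True`, default off.

## Hierarchical Bayesian estimation

Subject-level parameters are tied together by population laws with gamma
hyperpriors:

    LR_shape1, LR_shape2         ~ Gamma(0.5, 1)      (shape, rate)
    LR_subject                   ~ Beta(LR_shape1 + 1, LR_shape2 + 1)
    Lapse_shape, Lapse_inv_scale ~ Gamma(5, 1)
    Lapse_subject                ~ Gamma(Lapse_shape, Lapse_inv_scale)

The +1 on the beta shapes keeps the population law from inverting
(U-shaped densities).  Start values and the jump reuse the learning-rate
scheme; their hyperpriors are not separately documented in the source
analysis, and the symmetric Gamma(0.5, 1)+1 construction is adopted for all
[0, 1]-bounded parameters.

Sampling is adaptive Metropolis-within-Gibbs, implemented in numba.  Every
scalar parameter is updated componentwise with Gaussian random-walk
proposals on an unconstrained scale (logit for [0, 1] parameters, log for
positive ones) with the corresponding Jacobian corrections.  Proposal step
sizes adapt per component during warm-up (Robbins-Monro toward 0.44
acceptance) and are frozen for the sampling phase.  Subject-level updates
cost one pass over that subject's 60 trials; group-level conditionals are
O(1) via cached sufficient statistics (sums of log-transformed subject
parameters), which allows many cheap group-level sweeps per iteration.  One
retained draw corresponds to 6 subject-level and 60 group-level componentwise
sweeps by default — a design choice analogous to the many leapfrog steps a
gradient-based sampler takes per retained draw — so the published iteration
counts (4 chains, 500 warm-up, 500 sampling iterations) deliver comparable
information per draw.  Divergences have no meaning for a random-walk
sampler and are reported as 0.  The sampler's joint target equals the sum
of the model's pointwise log-likelihoods plus all prior log-densities; this
identity is verified against an independent scipy evaluation in the test
suite (1e-8 tolerance).

Convergence is summarised by split-chain rank-normalised R-hat (arviz),
with R-hat <= 1.01 considered acceptable, alongside effective sample sizes.
Point estimates are posterior medians with equal-tailed 95% credible
intervals (the 50% highest-density interval is reserved for the predictive
check band, where an HDI is the conventional choice).  Constant draws
across chains (zero between- and within-chain variance) report R-hat = 1 by
convention.  With the default settings, group-level R-hat stays at or below
1.01 for the base model and for the five-learning-rate model on synthetic
cohorts of 20-30 subjects; larger models or datasets may need more retained
draws, mirroring the original analysis's re-run of its selected model at
2000 sampling iterations.

Parameter recovery follows the simulate-fit-check recipe: data are
simulated from fixed, predefined hyperparameters; recovery of a parameter
is successful when its posterior 95% CI contains the truth (closed
intervals).  The reference simulation values are Beta(2, 2) learning rates
(hyper-shapes 1, 1) and lapse ~ Gamma(5, 1), i.e. a mean lapse of 5 —
decisive responding under which learning rates are identifiable from 60
trials, consistent with the guidance that lapse values around five balance
flexibility against precision.  Note that fixing the hyperparameters at
their hyperprior means instead (shapes 0.5; lapse pair 5, 5) implies a mean
lapse of 1 and near-uniform ratings; this flat-likelihood setting is used
where it is explicitly called for (the convergence benchmark), but is too
uninformative for recovery-quality checks.

## Model fit and selection

Pointwise log-likelihoods over all non-missing subject x trial datapoints
feed PSIS-LOO and WAIC (via arviz), with the relative MCMC efficiency of
the log-likelihood draws supplied explicitly.  LOOIC = -2 ELPD.  A
pseudo-r2 relates the posterior-mean total log-likelihood L to the chance
log-likelihood C = T log(1/9): pseudo-r2 = 1 - L/C (which point estimate
enters L is not pinned down by the source analysis; the posterior-mean
pointwise log-likelihood is used).  Fit decompositions by phase and cue
restrict the pointwise matrix to the relevant trials.  Selection keeps the
ELPD-maximising model; a competitor whose paired ELPD difference is within
five times the standard error of that difference (the standard paired
construction) is recorded as tied, and the globally best model is retained
among ties.

## Synthetic cohorts

Because the participant data are not deposited, the `synth` module
generates complete study datasets with the dependence structure the
analysis assumes.  A one-factor Gaussian copula couples everything: a
latent distress factor drives the GAD-7 latent directly, the PHQ-8 latent
at a calibrated loading, and selected learning-rate latents at calibrated
(negative) loadings.  Questionnaire totals are zero-inflated
negative-binomial margins truncated at the scale maxima (21 / 24), matched
to the pooled sample's mean of about 6 and SD of about 5 on both scales,
with extra zero mass (pi0 = 0.10 / 0.08); item-level simulation is not
attempted since every downstream statistic uses totals.  Learning-rate
margins are the Beta(shape1+1, shape2+1) population laws, reached through
the normal CDF / beta quantile transform so that coupled and independent
draws share identical marginals.

Discretisation attenuates rank correlations, so latent loadings are
calibrated numerically: a common-random-number Monte Carlo estimate of
Spearman's rho as a function of the latent correlation is inverted by
bisection (120,000 samples, fixed internal seed, cached per target).
Defaults follow the study: GAD-7/PHQ-8 rank correlation 0.71, and the two
anxiety-linked rates (safety learning, threat extinction) coupled at -0.21
and -0.22.  Missingness is missing-completely-at-random at 2% (the source
reports no mechanism; MCAR is the neutral choice).  Compliance metadata are
sampled with per-criterion rates chosen so the medium filter retains about
62% of subjects and the strict filter about 60% of those, approximating the
study's attrition.  What the generator does **not** emulate: early-trial
counterfactual/fictive updating against the model's direction, demographic
structure, attrition mechanisms correlated with anxiety, and any
misspecification between the generating and fitted model families — so
passing recovery tests demonstrate internal consistency of the pipeline,
not robustness to the deviations real participants produce.

## Descriptive measures and associations

The conventional benchmarks are per-subject whole-phase mean ratings per
cue and end-phase CS discrimination (final CS+ minus final CS- rating per
phase; a missing final trial falls back to the last rated trial for that
cue, and a cue with no rated trials in a phase yields a missing measure).
Paired CS+/CS- comparisons use the Wilcoxon signed-rank test (exact null
for n <= 25 without ties or zeros, tie-corrected normal approximation
otherwise; all-zero differences are flagged as degenerate rather than
tested).

Associations use Spearman's rho with 10,000 percentile-bootstrap resamples
over subjects (count and method are this package's choice; the source
states neither) and t-approximation p-values, with an exact permutation
option for small fixtures.  No multiple-testing correction is applied,
matching the source analysis's unadjusted reporting.  Trait-specific
effects use OLS residualised scores (each scale regressed on the other,
with intercept).  The shared-variance score is the per-subject mean of the
two standardised scale totals: the literal "mean of the standardised
residuals" is degenerate as a subject-level score (OLS residuals average
zero and the two residual vectors exclude precisely the shared component),
so the shared component is summarised by the standardised totals instead.

Competing dependent correlations — a learning rate and its matching
whole-phase mean, both against GAD-7 — are compared with Steiger's (1980)
Z in the shared-variable form, computed on absolute correlation values
because the sign of the learning-rate/responding relationship is contingent
on the cue (a high CS+ rate raises that cue's whole-phase mean; a high CS-
rate lowers it — verified by simulation in the test suite).  The reported
interval on the Steiger T is a subject-resampling bootstrap percentile CI;
the original construction is not documented.

## Problem sizes and defaults

Simulation-backed checks run at the scales the pipeline targets for desk
use: convergence and recovery on 20-30 subject cohorts at 4 chains and
500/500 iterations; model-recovery selection on 5 replicate cohorts with 2
chains at 250/250; copula calibration checks at 2,000-5,000 subjects.
Bootstrap counts defaults to 10,000 in the library and is reduced in tests.

## Known limitations

- The sampler is random-walk based; very large cohorts or models beyond the
  28-member family would benefit from gradient-based MCMC.
- The copula calibration targets one shared anxiety factor; it cannot
  represent, e.g., learning rates correlated with PHQ-8 over and above
  GAD-7.
- Prior predictive mass concentrates at moderate lapse values; extreme
  per-subject lapses (> ~30) are effectively outside the hyperprior and
  recovery there is poor by construction.
- The free precision of the beta link is fixed at phi = 10 throughout;
  continuous-rating variants and counterfactual/reversal extensions are out
  of scope.
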