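# Methods

## The behavioural model

Choices between a 50/50 gamble and a sure amount are described by
three-parameter prospect theory.  Monetary amounts x (yuan) are valued
by a two-branch power function

    u(x) = x^alpha            x >= 0
    u(x) = -lambda (-x)^alpha x < 0

with risk attitude `alpha` (curvature: < 1 risk averse, 1 neutral,
> 1 seeking) and loss aversion `lambda` (a multiplier on the disutility
of losses; > 1 means losses loom larger than gains).  A fair gamble is
valued as the mean of its two outcome utilities, and the probability of
choosing the gamble is a softmax in the utility difference,

    P(gamble) = 1 / (1 + exp(-tau (u_gamble - u_sure))),

where `tau >= 0` is choice consistency (inverse temperature): 0 is
random choice, large values approach deterministic maximisation.  A
dual-risk variant allows separate exponents `alpha+` / `alpha-` for the
gain and loss domains; restricted to `alpha+ = alpha-` it reproduces the
single-exponent model exactly.  A further restriction with `lambda = 1`
(no loss aversion) is included as a mis-specified comparator for
model-recovery checks.

Catch trials (engagement checks with a dominated option) and missed
responses are excluded from every likelihood, leaving 224 of the 230
task trials; including dominated-choice trials would bias `tau`.

## Task construction

The task comprises 40 gain trials (sure 1-15 yuan vs {0, g} with
g/sure spanning 1.5-3.4; two anchor pairs pin the ratio endpoints at
exactly 1.5 and 3.4, the other 38 pairs are drawn on a seeded grid and
re-drawn on constraint violation), 40 loss trials (the element-wise sign
flip of the gain set), 144 mixed trials (the full 12 x 12 factorial of
gains {8, 10, ..., 30} with losses {-5, ..., -27} against a sure zero,
so gain and loss magnitudes are exactly orthogonal), and 6 catch trials.
Order is a seeded permutation; inter-trial intervals are uniform on
[4, 8] s (the simplest distribution consistent with a 6 s mean and that
range); onsets accumulate a 5 s response window plus a 1 s highlight.
The 230 trials are labelled into two equal sessions of 115 but timed on
one continuous clock.  The exact published gamble pairs are not
reproducible from text, so the gain set is a constrained fixture, not a
scientific claim.

## Hierarchical estimation

Subject-level parameters are modelled as draws from group-level normal
distributions restricted to positive values, implemented as
zero-truncated Normal(mu, sigma^2) with the truncation normaliser
included in the density.  Hyperpriors are mu ~ Normal(0, 1) and
sigma ~ half-Cauchy(0, 5) for every parameter (the same hyperpriors for
alpha, lambda and tau).  Sampling is on an unconstrained scale (log for
subject parameters and group sds) with Jacobian terms.

The sampler is a vectorised adaptive Metropolis-within-Gibbs scheme:

* per-coordinate random-walk updates of each subject-level parameter,
  proposed for all subjects simultaneously (step sizes adapted per
  coordinate toward 0.44 acceptance during warmup only);
* two joint subject-level updates per iteration using a per-subject
  proposal covariance estimated from the warmup history (the covariance
  buffer is reset a third of the way through warmup to drop the initial
  transient) — alpha and lambda trade off along a ridge within subject,
  and coordinate moves alone crawl along it;
* joint (mu, log sigma) random-walk updates per group parameter, three
  sweeps per iteration (these carry no likelihood term and are cheap);
* likelihood caching: power terms |x|^alpha are recomputed only when an
  exponent changes; lambda updates re-weight the loss branch and tau
  updates only rescale the logistic argument.

Defaults are four chains, 12000 warmup iterations and 6000 retained
draws per chain (24000 retained in total), keeping every 4th
post-warmup iteration.  The thinning is a property of the random-walk
kernel: it needs a few iterations per effectively independent draw, and
storing every iteration would leave visible autocorrelation in the
retained sample.  Non-finite proposal states (overflowed utilities at
extreme exponents) evaluate to -inf and are rejected.  Convergence is
summarised by the split-chain Gelman-Rubin R-hat with the conventional
1.01 threshold; all-constant chains return 1 by convention.

Point estimates are posterior means on the constrained scale.  Per
subject, maximum-likelihood estimation (multi-start L-BFGS-B on the log
scale, bounds alpha in [0.05, 5], lambda in [0.05, 20], tau in
[0.001, 50]) is provided as the non-hierarchical comparator; degenerate
data (e.g. an all-sure chooser) return the boundary solution flagged
`at_bound` rather than an error.

## Model comparison

DIC = Dbar + pD with Dbar the posterior-mean deviance and
pD = Dbar - D(theta_bar); Dbar is averaged over at most 4000
stride-thinned draws.  The plug-in theta_bar is the posterior mean on
the log (sampling) scale, i.e. the geometric mean of the constrained
parameters: alpha, lambda and tau trade off multiplicatively, and the
arithmetic mean of a curved posterior ridge can land in a region of
poor fit, producing pathological negative pD (observed at -53 for one
subject of a dual-risk fit before the switch).  Per-subject DIC
contributions use that subject's likelihood and draws.

Random-effects model selection approximates each subject's log model
evidence as -DIC/2 (a documented, swappable bridge), then runs the
variational Dirichlet scheme: responsibilities proportional to
exp(log evidence + digamma(alpha_k) - digamma(sum alpha)), Dirichlet
concentrations alpha_k = 1 + sum of responsibilities, iterated to 1e-8.
Exceedance probabilities are exact via the Beta distribution for two
models (Monte Carlo with 1e6 seeded draws otherwise).  The Bayesian
omnibus risk compares the variational free energy of the fitted model
with the null hypothesis of frequencies fixed at 1/K,
BOR = 1 / (1 + exp(F1 - F0)), and the protected exceedance probability
is PXP_k = EP_k (1 - BOR) + BOR / K.

## Trait statistics

Greed is the 7-item Dispositional Greed Scale total (7-35).
Impulsivity is the 30-item BIS-11 total; the subscale assignment
(cognitive / motor / non-planning) and the reverse-scored items live in
a packaged JSON map, not in code, and a no-reversal variant of the map
is exported for raw-sum scoring.  Risky-choice percentages are gamble
choices over answered non-catch trials, per condition; an unanswered
condition yields a missing value, never 0.

Correlations are Pearson; "covariate of no interest" control is a
partial correlation (both variables residualised on the covariates,
degrees of freedom n - k - 2).  Robust regression is IRLS with Tukey's
bisquare (tuning constant 4.685, 95% Gaussian efficiency) and MAD
scale, via statsmodels.  One-sample t-tests are two-sided; zero-variance
input is an error for every statistic (including the t-test at its null
mean, where 0/0 is undefined).

## Mediation

Three OLS regressions with shared covariates in every equation (the
PROCESS convention) give paths a, b, c, c'; the indirect effect is a*b
and c = c' + a*b holds to machine precision.  Confidence intervals are
bias-corrected (BC, not accelerated — no jackknife) percentile
bootstrap over subjects: 5000 resamples by default,
z0 = Phi^-1(fraction of bootstrap estimates below the point estimate),
interval endpoints at Phi(2 z0 +/- z_{alpha/2}) quantiles.  Resampling
is by whole subject rows; degenerate resamples (a predictor collapsing
to a constant) are skipped and counted.  Classification: *full* when
the a*b interval excludes zero and the c' interval does not, *partial*
when both exclude zero, *none* otherwise.  At n = 25 with a strong
mediator-outcome path the BC interval is known to be slightly liberal
(empirical type-I around 5-10%); it approaches the nominal 5% by n = 50.

## ROI GLM

Events at option revelation are sticks modulated by three mean-centred
parametric regressors — potential gain, loss magnitude (coded positive,
expected negative-going beta) and sure value — plus a decision-onset
nuisance stick and an intercept.  Modulators are mean-centred but not
orthogonalised (the factorial mixed design makes gain and loss columns
nearly orthogonal by construction).  Columns are convolved with the
canonical double-gamma HRF (response gamma shape 6, undershoot shape
16, 1:6 amplitude ratio, 32 s support, peak-normalised) on a microtime
grid of 16 bins per TR and sampled at scan times.  Identical onsets
collapse with summed modulators.  Data and regressors are high-pass
filtered by projecting out an orthonormal discrete-cosine basis with
periods above 128 s (constant included); estimation is plain OLS with
no autocorrelation model — the desk-scale target is beta recovery, not
single-run inference.  Neural loss aversion is -beta_loss - beta_gain:
positive when deactivation per yuan of potential loss is steeper than
activation per yuan of potential gain.

## The synthetic cohort generator

The generator is the package's stand-in for the study cohort: 25
subjects, subject-level (alpha, lambda, tau) from zero-truncated
normals with group means (1.033, 1.561, 1.0) and sds 0.4.  The group
means are the published behavioural calibration; the sds and the tau
location are fixture choices (between-subject spreads are not
published).  On top of the parameters:

* GPT = 22 - 9 ln(lambda) + Normal(0, 3.5), rounded, clipped to 7-35.
  The coupling is set so that the default cohort is a *full-mediation*
  cohort with adequate power at n = 25 (true-parameter correlation
  about -0.55); after questionnaire rounding and estimation error the
  observable correlation lands in the -0.4 to -0.5 band characteristic
  of this literature.  Greed is deliberately not coupled to alpha.
* IPT = 44 + 0.8 GPT + Normal(0, 7), rounded, clipped to 30-150,
  targeting the moderate positive greed-impulsivity correlation
  (about 0.45-0.5).
* NLA = 0.3 + 0.9 ln(lambda) + Normal(0, 0.45); beta_gain ~
  Normal(0.4, 0.15) and beta_loss = -(NLA + beta_gain), so the neural
  loss-aversion identity holds exactly at the generating level.

Choices are Bernoulli draws from the softmax per trial (catch trials
deterministically take the dominant option); ROI BOLD is the GLM design
times the generating betas plus white noise.  All subjects share one
task order (real subjects each saw their own permutation; sharing the
order keeps the data rectangular and does not change the likelihood).

What the generator does **not** emulate — hence what green tests do not
establish about real data: reaction times and their relation to
difficulty, item-level questionnaire responses, session/break effects,
non-stationary scanner noise, physiological and motion confounds,
spatial ROI definition, and any model misspecification of real choice
behaviour (real subjects need not follow prospect theory).  Alternative
couplings (including exact-zero nulls) are one constructor call away;
a `from_target_r` helper converts a target correlation into a coupling
and raises if the implied correlation exceeds 1.

## Problem sizes and numerical choices

The test suite runs the full default sampler once on the default
25-subject cohort and reuses that fit across convergence, recovery and
shrinkage checks; model-recovery uses 5 small cohorts (6 subjects) at
reduced iteration counts; mediation calibration uses 200 null and 50
coupled replicate cohorts with 1000 bootstrap draws each; GLM
unbiasedness uses 200 noise realisations of a fixed design.  These
sizes are the package's own choices balancing Monte-Carlo error against
runtime.  The logistic argument is capped at |500| before
exponentiation; choice probabilities are clipped into the open unit
interval; every random quantity flows through an explicit seed
(numpy SeedSequence spawning for chains and subjects).

## Known limitations

* The random-walk sampler needs thinning to match the effective sample
  size a gradient-based sampler would reach per stored draw; very small
  or degenerate datasets (a subject with no variability in choice) rely
  on the hierarchical prior for identification.
* The -DIC/2 evidence bridge is a convention, not a derived quantity;
  BMS conclusions should be read qualitatively (the indistinguishable
  single- vs dual-risk comparison reproduces as a pattern, not as exact
  PXP/BOR values).
* The BC bootstrap's small-sample liberality is inherited from the
  method, not corrected away.
* Whether the original study's modulators were centred per session, or
  its loss modulator coded signed rather than as magnitude, is not
  derivable from text; both conventions are exposed as options and the
  package default (per-task centring, magnitude coding) is stated here.
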