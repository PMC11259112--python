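# Methods

## The problem

Visual working-memory capacity is commonly summarised as the number *k* of
discrete units that attention can keep active at once. Two task families
give famously different answers: compound-stimulus report tasks (CSVI),
where participants report every trained feature they detect in a single
stimulus, yield adult means near seven; change-detection array tasks (VAT),
where participants judge whether one square in a briefly shown colour array
changed, yield means near four. `wmcap` implements the estimation machinery
for both tasks so that the two kinds of estimates can be computed, compared
and stress-tested on simulated cohorts.

## Occupancy model of compound-stimulus report

A stimulus at level *n* contains *n* relevant features ("boxes"). The
participant allocates *r* indistinguishable units of attention ("balls"),
and every uniform weak composition of *r* into *n* parts is equally likely;
the number of correct feature reports is the number of occupied boxes.
This is the Bose-Einstein occupancy distribution

    p(x) = C(n, n-x) C(r-1, x-1) / C(n+r-1, r),  1 <= x <= min(n, r),

with mean `n*r/(n+r-1)`. Binomial coefficients are evaluated in log space
(`lgamma`), exact to well beyond the n+r ~ 90 this application needs. The
sampler draws a uniform (n-1)-subset of n+r-1 star-and-bar slots; dropping
balls into boxes sequentially and independently would give multinomial, not
uniform-composition, occupancy and is deliberately avoided. An exhaustive
enumeration oracle (all compositions, guard C(n+r-1, r) <= 1e6) backs every
pmf value in the tests.

The number of balls depends on capacity *k* and the presentation regime:
long presentation is assumed to allow attending repeatedly until a feeling
of saturation after *k* attending acts, giving r = k^2; brief presentations
allow a fixed number a in {1, 2, 3} of acts, giving r = a*k.

### Capacity estimation

Per participant, the per-level histograms of number-correct are scored by
the log likelihood sum_l sum_x counts[l][x] * log p(x | n=l, r(k)), treating
trials as i.i.d. within level and levels as independent, and *k* is chosen
by exhaustive search over the integers 1..9 (nine trainable features sets
the ceiling). Outcomes impossible under the model (x = 0, or x beyond
min(n, r)) occur in real data through lapses; they receive a floor
probability of 1e-6 so the profile stays finite, and ties break toward the
smaller (more conservative) capacity. Simulation at the published design
(8 trials per level 2-8, two attending acts) recovers generating capacities
with |mean bias| below half a unit; at 200 trials/level recovery is
essentially exact (>= 95% per k in 3..9).

### Goodness of fit and the published table

`pipeline.table1_expected` rebuilds the published expected-mean columns for
k = 7 analytically. Two printed cells are knowingly not reproduced: the
level-3 cell of the two-act condition (printed 2.69; closed form
42/16 = 2.625, a likely typo) and the level-8 row, where three of four
printed cells disagree with the plain occupancy mean (the rule used for
that row is not recoverable); the module computes the plain mean and flags
the row. Ratio correlations between observed and expected short/long
columns are computed from the printed, 2-d.p. values — that is what a
reader can verify — and reproduce 0.89 (two-act), 0.98 (one-act) and the
joint 0.94; the three-act coefficient comes out at 0.79 from the printed
inputs rather than the published 0.84, which we attribute to rounding of
the unpublished full-precision ratios.

`csvi.compare_models` contrasts the occupancy model against a binomial
alternative per level with Pearson chi-square tests, merging cells with
expected count < 5 inward from both tails; the binomial uses the per-level
MLE p-hat = (total correct)/(level x trials) and loses one further degree
of freedom for it.

## Change-detection model

Cowan's formula k = N (p(H) + p(CR) - 1) is provided per set size; negative
values (false alarms exceeding hits) are returned with a warning rather
than clamped, because that pathology is informative. The three-parameter
model adds an attending probability *z* (lapses imply pure guessing) and a
guessing bias *g* (probability of answering "change" when uninformed).
With m = min(k, N)/N (continuous k interpreted linearly),

    p(hit) = z (m + (1-m) g) + (1-z) g
    p(FA)  = z (1-m) g + (1-z) g

and hit/correct-rejection counts are binomial across set sizes. For z = 1,
g = 1/2 and k <= N, Cowan's formula applied to these probabilities returns
k identically — the consistency check in the tests.

### Hierarchical sampler

Participant parameters are sampled on transformed scales — log k, logit z,
logit g — as draws from population normals. Hyperpriors are weakly
informative: population means N(log 4, 1) for log k, N(logit 0.9, 1.5^2)
for logit z, N(0, 1.5^2) for logit g; population variances inverse-gamma
(2, 0.5). The sampler is Metropolis-within-Gibbs: elementwise Gaussian
random-walk proposals for each participant block (the z block gets two
sweeps per iteration because near-ceiling accuracies identify it weakly and
it otherwise mixes slowest), conjugate normal / inverse-gamma Gibbs updates
for the population means and variances. Initialisation is data-driven
(pooled Cowan estimates for k, accuracy at the smallest set size for z,
false-alarm rates for g), with up to 10 re-initialisations if the starting
likelihood is non-finite.

Proposal scales adapt during burn-in only, by Robbins-Monro steps on the
log scale toward a target acceptance of 0.70 (the published analyses report
rates of .65-.72); the configured epsilon window bounds the learning rate,
defaulting to [0.035, 0.05]. Defaults are 10,000 iterations with 1,000
burn-in. With 24 participants and four set sizes a fit takes a few seconds.

`fix_z` freezes every participant's z (the control analysis for designs
with no set size below capacity, where z is weakly identified and its bias
propagates into k); the z block and its hyperparameters are then skipped.
Fixing z above the generating value pushes capacity estimates down, the
direction the control analysis is designed to reveal.

### Convergence diagnostics

The Geweke diagnostic compares the means of the first 10% and last 50% of
a chain, with standard errors from spectral densities at frequency zero
estimated by Yule-Walker autoregression (order by AIC, up to min(20,
n/10)); |z| < 1.96 is the conventional pass, a constant chain returns 0.
Segment-local spectral estimates are biased low on strongly autocorrelated
draws, which inflates |z|, so the fit summary evaluates the diagnostic on
chains thinned to ~1,000 draws. Calibration is verified by simulation
(i.i.d. and AR(1) chains). Note the usual multiplicity caveat: with six
hyperparameter chains tested at the 5% level, a perfectly stationary
sampler still fails at least one test in roughly a quarter of runs, so a
single isolated |z| slightly above 1.96 is not evidence of non-convergence.

## Synthetic cohorts

Generators emulate only what the estimators consume: trial outcomes.
CSVI capacities are integer draws from a rounded truncated normal on
[1, 9] (default mean 6.5, s.d. 1.5, the adult population figures);
per-trial correct counts come from the occupancy sampler. VAT parameters
are continuous truncated normals (k >= 1; z, g in [0, 1]); change trials
occur with probability .5 and responses follow the model's hit/false-alarm
probabilities. Presets carry the five study designs: compound-stimulus
experiments with 20 participants and 8 trials per level 2-8 (long
saturation condition plus a brief condition with 2, 1 or 3 acts), and array
experiments with 80 trials per set size (50 adults at sizes 6/8/10/12 with
short-condition population k ~ 5.6, z ~ 0.81, g ~ 0.40; 24 adolescents at
sizes 3/6/8/10 with k ~ 4.4, z ~ 0.94, g ~ 0.48).

What the generators do **not** emulate: training and practice phases,
masks and timing, feature-salience differences, response order, colour
repetition in arrays, and the chunking/recoding strategies that inflate
long-presentation array estimates. Passing recovery tests therefore shows
that the estimators are correct *under the stated models*, not that the
models capture every feature of real data.

## Numerical and design choices

- Probability clamps: occupancy likelihood floor 1e-6; change-detection
  response probabilities clamped to [1e-9, 1 - 1e-9].
- Integer grid ties break toward smaller k (conservative attribution).
- Display rounding is half-up to 2 d.p.; internal computation never rounds.
  Reproduction checks compare at the printed precision (+/- 0.005).
- Correlation confidence intervals use the Fisher transform; |r| = 1 is
  flagged as degenerate, not widened. Partial correlations residualise on
  the covariate.
- Paired comparisons support shifted nulls (testing a difference of 0, 1 or
  2 units); zero variance of differences raises rather than returning an
  unstable statistic.
- Problem sizes in the test suite: recovery checks run 100 replicates per
  generating capacity at 200 and at 8 trials per level; the hierarchical
  fit is exercised at the full 10,000 iterations on the 24-participant
  adolescent design, and the fixed-z direction check over 10 seeds at
  3,000 iterations with 20 participants.

## Known limitations

- The hierarchical sampler matches the published three-parameter model but
  not the original estimation software; priors and proposal mechanics are
  this package's own documented choices, so posterior point estimates agree
  qualitatively, not digit-for-digit.
- Bayes-factor analyses of the source study (Cauchy-prior t tests, Bayesian
  ANOVAs) are out of scope; frequentist t and r cover the reproducible
  quantities.
- Continuous-report array variants, hierarchical feature/object
  representations, and partial-resource allocation models are not
  implemented.
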