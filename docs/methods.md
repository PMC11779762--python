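# Methods

## Measurement model

Each drawn function is treated as a realization of a zero-mean Gaussian
process over the normalized x-axis with the squared exponential kernel
`k(x_i, x_j) = sigma_s^2 exp(-(x_i - x_j)^2 / (2 lambda^2)) + sigma_n^2 delta_ij`.
The three hyperparameters carry the psychological interpretation: the length
scale `lambda` (axis units) is the distance over which presented points
influence the drawn curve — small values produce data-tracking responses,
large values smooth global-trend responses; the signal variance `sigma_s^2`
(squared axis units) scales how strongly the data pull the curve away from
the zero prior mean; the noise variance `sigma_n^2` absorbs deviations the
drawing does not commit to. Hyperparameters are point-estimated by
maximizing the log marginal likelihood, whose `-1/2 log|K|` term penalizes
complexity, so the estimate trades fit against smoothness. We deliberately
fit the *drawn responses*, not the stimuli: the GP is a measurement model of
the drawing, not a cognitive model of the drawer.

Numerics: optimization is over the three log-hyperparameters (positivity by
construction, scale-free steps) with L-BFGS-B inside box bounds
`log lambda ∈ [log 1e-3, log 1e3]`, `log variances ∈ [log 1e-6, log 1e3]`,
from two data-driven starts plus 10 uniform random restarts (seeded). The
first start targets the smooth basin (`lambda` ≈ a fifth of the x-span,
`sigma_s^2` ≈ var(y), `sigma_n^2` ≈ 5% of var(y)); the second targets the
interpolation basin (`lambda` ≈ half the point spacing with near-floor
noise), which is narrow — from about 1.5× the spacing the optimizer rolls
out of it onto the flat pure-noise surface — and which uniform restarts
alone often miss on data-tracking responses whose true length scale sits
near the grid resolution. Ties within 1e-6 in log marginal likelihood
break toward the larger length scale, i.e. the simpler function. The training covariance is
factorized by Cholesky with geometric jitter escalation capped at
`1e-4 * sigma_s^2`; a hard floor of 1e-8 on the noise variance keeps near
noiseless drawings well conditioned. Gradients are the standard trace-form
derivatives with respect to the log-hyperparameters. Fits that fail every
restart's convergence test are returned flagged, never dropped —
mirroring the retention of imperfect drawings upstream.

On genuine data-tracking drawings the likelihood surface is bimodal: a tiny
length scale with floor noise variance (interpolate every grid point) and a
moderate length scale with large noise variance (treat the wiggle as noise)
are both real optima. Multi-restart selects the better of the two per
function, but fitted parameters for a homogeneous tracking style can
legitimately form more than one cloud in parameter space; downstream
clustering reflects that.

## Trace processing

Digitized traces are affinely normalized so the axis limits map to [-1, 1],
repaired for x-backtracking (walking in drawing order, a point is kept only
if its x exceeds every kept x by more than `x_tolerance` = 1e-6 axis units;
first pass wins, so at duplicate x the earliest y is kept), and resampled by
linear interpolation onto 40 evenly spaced grid points spanning [-1, 1].
Grid points outside a short trace's span take the nearest endpoint's y;
such records carry an `extrapolated` flag so incomplete drawings can be
filtered or weighted downstream. Linear interpolation is the simplest
scheme consistent with densely digitized traces; nothing downstream is
sensitive to the choice at realistic trace densities.

## Clustering

Per problem, participants' log-hyperparameter 3-vectors are clustered with
a Dirichlet-process Gaussian mixture: CRP prior (`P(join G) = n_G /
(n - 1 + alpha)`, `P(new) = alpha / (n - 1 + alpha)`) over partitions and a
normal–inverse-Wishart base measure, sampled by collapsed Gibbs. The
per-group posterior predictive is a Student-t by conjugacy; we approximate
it by the Gaussian matching its first two moments (mean `mu_n`, covariance
`Lambda_n (kappa_n + 1) / (kappa_n (nu_n - d - 1))`), which requires
`nu_n > d + 1` and is cheap to cache per cluster.

Defaults: `alpha` = 1.0; empirical-Bayes base measure with `mu_0` = the
problem's data mean, `kappa_0` = 1, `nu_0` = 5, `Lambda_0` = the data
covariance times `nu_0 - 4` plus a 1e-6 ridge (so degenerate data still
yield a proper prior); 1,000 sweeps with 500 burn-in. The reported
*representative partition* is the post-burn-in sample with the highest
joint score — CRP partition probability (EPPF) times the sequential
predictive likelihood of the data — with cluster labels canonicalized by
decreasing size. Cluster summaries report geometric means and
multiplicative SDs (exp of log-scale moments; a singleton has
multiplicative SD 1). Counting uses all clusters by default; a
`min_size` filter (e.g. 11) is available for display parity with plots
that suppress small clusters.

Initialization is the one genuinely consequential sampler choice. From an
all-in-one-group start, single-site Gibbs essentially never nucleates a new
cluster under the wide empirical-Bayes base measure: a freshly opened
group's predictive is dragged toward the global mean and stays broad, so
every item prefers the incumbent merged cluster (direct computation of the
conditionals puts the join-a-new-singleton move several nats below
staying). We therefore start from all singletons — the agglomerative
direction, which single-site Gibbs handles well — leaving the stationary
distribution unchanged; the merged start remains available via
`init="together"`. With this start the sampler recovers a 3-component
mixture (separation 15 within-SDs, n = 60) with median ARI 1.0 and the
correct count in ~95% of chains.

## Classification

Expert labels (linear / quadratic / cubic / data-tracking / unclassifiable)
are prepared by merging cubic into data-tracking — the two occupy the same
region of parameter space — and dropping unclassifiable rows. The boundary
separates linear from the rest with an L2-regularized squared-hinge linear
classifier trained deterministically in the primal; the regularization
weight is applied against the mean loss (C = 1/n), making the fitted rule
invariant to duplicating every row, and the intercept is left effectively
unregularized so apparent accuracy never falls below the majority rate.
Accuracy is apparent (training-set) accuracy. Scores are
`w · x + b` with the non-negative side the data-tracking/quadratic region;
an exact zero breaks toward data-tracking. Linear drawings live at large
length scale and small noise variance, so on the
(log length scale, log noise variance) plane the data-tracking side weights
log length scale negatively and log noise variance positively.

## Statistics

- **Condition means**: cell means and standard errors of each
  log-hyperparameter over the 12 generator × n-points × scale cells; empty
  cells are reported as missing, not raised.
- **Cluster-count ANOVA**: the 24 per-problem counts are treated as a
  balanced 3×2×2 fixed-effects design with 2 replicates per cell (counts
  enter as plain numbers despite discreteness). Degenerate all-equal input
  returns F = 0, p = 1 with a `zero_variance` flag so batch pipelines
  survive pathological simulations.
- **Parameter ANOVA**: three-way repeated measures with participant as the
  random blocking factor; replicates within a cell are averaged per
  participant, incomplete participants are dropped listwise, and each
  within-subject effect is tested against its own effect × participant
  interaction MS (classical repeated-measures error terms).
- **Intercorrelations**: Pearson r with two-sided p over the three
  log-parameter pairs, pooled over all records.
- **Consistency**: for every pair of problems, the across-participant
  Pearson correlation of a log-parameter; the result is the mean pairwise r
  with a one-sample t-test against zero, df = (number of computed pairs)
  − 1 (276 pairs for 24 problems). Raw correlations are averaged (no
  Fisher-z by default); pairs with fewer than 3 shared participants or a
  zero-variance side are skipped and counted.

## Synthetic data

The generator emulates the study conditions. Stimuli: x-locations are
uniform draws over the drawing range (one shared draw per replicate pair,
so small- and large-scale members have identical relative positions); y is
the generating polynomial plus additive Gaussian stimulus noise, truncated
to the plotting frame; small-scale clouds are the large-scale clouds shrunk
about the origin by sqrt(0.4) per axis, reading "fills 40% of the area" as
area. Default polynomial coefficients span the axis range; the default
stimulus noise SD is 0.15 axis units — a visibly noisy but coherent
scatter, chosen once as a realistic value since no per-problem value is
reported.

Simulated drawers sample a path from the GP posterior conditioned on the
stimulus under a latent style profile — smooth: `(lambda, sigma_s^2,
sigma_n^2)` = (2, 1, 0.1); tracking: (0.05, 1, 1e-6) — jittered per
participant by SD 0.15 in log space for individual variation, evaluated on
a dense x-grid, plus Gaussian motor jitter (SD 0.01 axis units). With
probability `backtrack_prob` (0 by default; enabled in trace-repair tests)
one short reversed-x segment is injected. The simulation captures the
local-vs-global distinction, seeded determinism, and the data features the
pipeline must survive (backtracking, missing functions). It does not
attempt psychophysically realistic motor control, pen pressure, stroke
order, or the correlated drift of real hand movement — so passing tests
demonstrate pipeline correctness and sensitivity under known ground truth,
not measurement validity for human drawings.

## Problem sizes

The test battery uses the sizes that make each check informative while
keeping the suite quick: 20 random instances for the closed-form GP
oracles; 100 synthetic 40-point functions per true length scale (0.1, 1.0)
for recovery; 20 chains of 1,000 sweeps for the 3-component mixture
battery; 50 drawers per style per problem on a 4-problem battery for the
length-scale pattern; reduced sweep counts (a few hundred) for smoke tests
whose full-size versions run in the acceptance layer.

## Known limitations

- The Gaussian moment-matching of the Student-t predictive thins the tails;
  with very small groups this slightly favors opening new clusters for
  outliers relative to the exact predictive.
- Single-site collapsed Gibbs, even from the singleton start, can retain a
  sticky merged cluster on rare chains; the representative-partition
  extraction mitigates but does not eliminate this (≈5% of chains on the
  3-blob battery report 2 or 4 components).
- Apparent (training-set) classifier accuracy is reported by design; it
  overstates generalization.
- The repeated-measures ANOVA assumes sphericity; no correction is applied.
- Reported reference quantities (cluster counts, the 2-D decision boundary)
  are inputs transcribed from the original study, not recomputations from
  raw drawings, which are not distributed with this package.
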