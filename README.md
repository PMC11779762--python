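# funcest

Measurement modelling of hand-drawn function estimates.

In the *function estimation* task, observers are shown scatterplots of noisy
data — varying in generating polynomial (linear / quadratic / cubic), number
of points (6 / 24), and presentation scale (small / large) — and draw the
function they believe generated the data. Some people draw smooth,
polynomial-like functions following the global trend; others draw functions
that track every local fluctuation. `funcest` provides a tested pipeline for
quantifying and clustering these individual differences, for researchers in
graphical perception and quantitative cognition.

## The model

Each processed drawn function (40 evenly spaced points on the normalized
[-1, 1] axes) is summarized by a zero-mean Gaussian process with the squared
exponential kernel

```
k(x_i, x_j) = sigma_s^2 * exp(-(x_i - x_j)^2 / (2 lambda^2)) + sigma_n^2 * delta_ij
```

whose three hyperparameters — length scale `lambda`, signal variance
`sigma_s^2`, noise variance `sigma_n^2` — are estimated by maximizing the
log marginal likelihood

```
log p(y | X, theta) = -1/2 y' K^-1 y - 1/2 log|K| - n/2 log(2 pi)
```

Small length scales describe data-tracking drawings, large length scales
smooth global-trend drawings; the `-1/2 log|K|` term penalizes complexity so
the fit trades data fidelity against smoothness. Per problem, participants'
log-hyperparameter vectors are clustered with a Dirichlet-process Gaussian
mixture (collapsed Gibbs, normal–inverse-Wishart base measure, CRP prior
`P(join G) ∝ n_G`, `P(new) ∝ alpha`); function types are separated with a
linear classifier in log-hyperparameter space; condition effects are tested
with balanced factorial and repeated-measures ANOVAs.

A synthetic-data module generates the full 3×2×2×2 stimulus design and
simulates drawers with known latent styles, so every stage is testable
without human drawings.

## Worked example

Simulate one smooth and one tracking drawer responding to the same quadratic
scatterplot, and fit the measurement model to each:

```python
from funcest import (DesignCell, DrawerProfile, GPHyperParams, FitConfig,
                     make_stimulus, simulate_drawer, fit_hyperparams,
                     run_cluster_count_anova)
from funcest.stimuli import default_coefficients
from funcest.traces import process_trace

cell = DesignCell("quadratic", 24, "large", 1)
stim = make_stimulus(cell, default_coefficients("quadratic"), 0.15, seed=7)

for name, theta in [("smooth", GPHyperParams(2.0, 1.0, 0.1)),
                    ("tracking", GPHyperParams(0.05, 1.0, 1e-6))]:
    trace = simulate_drawer(stim, DrawerProfile(theta), n_raw_points=200, seed=1)
    rec = fit_hyperparams(process_trace(trace), FitConfig(seed=0))
    t = rec.theta
    print(f"{name:9s} lambda={t.length_scale:8.4f}  sigma_s^2={t.signal_var:8.4f}  "
          f"sigma_n^2={t.noise_var:10.3e}  lml={rec.lml:8.2f}")
```

```
smooth    lambda=  2.2905  sigma_s^2=  2.2450  sigma_n^2= 3.471e-05  lml=  128.66
tracking  lambda=  0.0439  sigma_s^2=  0.7387  sigma_n^2= 1.000e-06  lml=  -43.24
```

The smooth drawer's fitted length scale (2.29) dwarfs the tracking drawer's
(0.04): the fitted hyperparameters recover the latent style.

The package ships the per-problem cluster counts reported for the original
24-problem study of 177 observers; the 3×2×2 cluster-count ANOVA on them:

```python
print(run_cluster_count_anova().table.round(3).to_string())
```

```
                              SS  df      MS      F      p
generator                 10.750   2   5.375  2.745  0.104
n_points                   0.375   1   0.375  0.191  0.669
scale                     12.042   1  12.042  6.149  0.029
generator:n_points         1.750   2   0.875  0.447  0.650
generator:scale            4.083   2   2.042  1.043  0.382
n_points:scale            12.042   1  12.042  6.149  0.029
generator:n_points:scale   2.083   2   1.042  0.532  0.601
Residual                  23.500  12   1.958    NaN    NaN
```

Only the scale main effect and the points × scale interaction are
significant, F(1,12) = 6.15, p = 0.029 (identical F-ratios because the
counts are discrete): larger presentation scales elicit more qualitatively
distinct response styles, and the difference grows with more data points.

A full synthetic study (stimuli → drawers → trace processing → GP fits →
clustering → classification → statistics) runs end to end via the CLI:

```
funcest run-all --seed 1 --out results/study
funcest cluster-anova
```

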