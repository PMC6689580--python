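# vaquitrend

Bayesian geostatistical trend analysis and abundance projection for passive
acoustic monitoring of the vaquita (*Phocoena sinus*), the critically
endangered porpoise of the northern Gulf of California — and for any
monitoring programme with the same design: a fixed grid of echolocation
click loggers sampled each season, with uneven effort and missing stations.

The package is aimed at quantitative ecologists and marine-mammal
monitoring programmes who need defensible trend estimates from click-count
data, and at anyone auditing or extending that analysis.

## The model

Let `W_ti` be the mean number of clicks per sampled day at site *i* in year
*t*, averaged over `n_ti` days inside a fixed 62-day core window (Julian
day 170–231). The log response `Y_ti = log(W_ti + 1)` is modelled as

```
Y_ti | μ_t, Z_ti  ~  Normal(μ_t + Z_ti,  σ²ε / n_ti)
Z_t               ~  MVN(0, σ²z R(ρ)),    R_ij = exp(−3 h_ij / ρ)
```

with `h_ij` the inter-site distance in km. Years with sparse effort borrow
strength through the shared spatial field. The derived yearly activity
index is `B_t = (1/S) Σ_i (exp(μ_t + Z_ti) − 1)`, and the annual change is
`λ_{t,t+1} = B_{t+1} / B_t` (λ < 1 means decline; `(1 − λ)·100` is the
percentage decline).

Fitting is Metropolis-within-Gibbs MCMC: `(μ_t, Z_t)` are drawn jointly
from their Gaussian conditionals, the variances from conjugate
inverse-gamma updates, and `log ρ` by adaptive random-walk Metropolis.
Geweke, Heidelberger–Welch and per-observation Bayesian p-value
diagnostics are built in.

An independent survey abundance estimate (for the vaquita: autumn 2015,
arithmetic mean 66 animals, sd 33) is represented as a moment-matched
lognormal and projected forward by multiplying each draw through the joint
posterior λ draws. Verified minimum-known-alive counts (≥ 7 animals in
2017, ≥ 6 in 2018) then truncate the trajectory set from below — a
rejection-sampling posterior update that also retrospectively raises the
starting-year estimate.

## Worked example

`examples/02_fit_trend_model.py` simulates a study-like season (46 sites,
2011–2018, steep decline, sparse early effort), fits the model with a
reduced 2000-draw run, and prints:

```
                        period  lambda_mean  cri_low  cri_high  prob_declining_pct  prob_declining_gt20_pct
                     2011-2012         0.59     0.53      0.67               100.0                    100.0
                     2012-2013         1.13     0.97      1.29                 4.6                      0.0
                     ...
                     2017-2018         0.63     0.57      0.72               100.0                     99.9
geometric mean per-year change         0.65     0.64      0.66               100.0                    100.0

realized true ratios for comparison: [0.6, 1.23, 0.55, 0.53, 0.44, 0.9, 0.64]
```

Each row summarizes the posterior of λ for one year pair: the mean change
ratio, its 95% credible interval, and the posterior probabilities (in %)
that activity declined at all (λ < 1) and faster than 20%/yr (λ < 0.8).
The fitted means track the generator's realized ratios closely.
`examples/04_project_abundance.py` continues to the abundance projection
and minimum-count update, and `examples/05_full_pipeline.py` runs the whole
chain with serialized outputs. The same stages are available from a thin
CLI (`vaquitrend prepare|simulate|fit|diagnose|trend|project|run-all`).

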