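# groupsync

Multivariate synchrony metrics for coordination-dynamics research.

When several people (or several channels of one person) interact — a team in
a meeting, a family in conversation, limbs of a dancer, physiological
signals of a group — their behavior tends to coordinate in time.  Most
synchrony tooling is dyadic; `groupsync` quantifies coordination across the
whole group at once.  It is aimed at researchers in social, cognitive, and
movement science who have multivariate time series (posture traces, motion
energy, respiration, ...) and want group-level synchrony scores, chance
baselines, and significance tests.

## What it computes

For a recording `X` with variables `x_1..x_N` sampled uniformly in time:

- **Symbolic entropy** — each variable is discretized into terciles
  (low/medium/high); the joint state at time t is one of 3^N symbols, and
  the score is the Shannon entropy (nats) of the empirical symbol
  distribution.  Perfect synchrony gives ln 3 ≈ 1.1; N independent channels
  approach N·ln 3 (≈ 5.5 for five).
- **mdRQA** — multidimensional recurrence quantification: threshold the
  Euclidean distance between joint states at a radius ε to get a binary
  recurrence matrix, then summarize its diagonal structure: %REC (recurrence
  rate), %DET (share of recurrent points on diagonal lines ≥ `min_line`),
  ADL (average diagonal line length), maxL (longest line).
- **Team coherence** — Welch magnitude-squared coherence
  `|S_xy|² / (S_xx·S_yy)` per pair and frequency, averaged over frequencies
  and over all pairs.
- **Sum-normalized CSD** — `Σ_f |S_xy(f)|² / Σ_f S_xx(f)·S_yy(f)` per pair,
  averaged over pairs.  Unlike coherence it weights frequencies by
  amplitude, making it more robust to broadband noise; it lies in [0, 1] by
  Cauchy–Schwarz.
- **Cluster-phase rho** — from instantaneous phases θ_k(t) (Hilbert
  transform): the cluster phase q(t) is the circular mean across variables,
  each variable's relative phase φ_k(t) = θ_k(t) − q(t) is centered on its
  own circular mean offset, and ρ(t) is the resultant length of those
  centered relative phases; the overall score is the time mean.
- **Kuramoto weak-null test** — for a *sample* of recordings, the
  time-average of the squared order parameter r(t)² is compared against its
  chance expectation 1/N with a one-sample t test (one-sided), allowing
  autocorrelation within variables under the null.
- **Surrogate baselines** — segment shuffling (within a recording) and
  variable swapping (across recordings), both preserving every channel's
  marginal distribution.
- **Windowing** — any metric evaluated over sliding windows, with max/min
  reducers for time-varying analyses.
- **Simulators** — AR(2) channels with optional common-mode noise (a null
  with adjustable spurious synchrony) and a stochastic Kuramoto model with
  known coupling strength K, plus drivers that sweep noise SD and K to
  check metric robustness and validity.

## Worked example

```python
import numpy as np
from groupsync import (sample_kuramoto_collection, metric_battery, tune_radius,
                       swap_variables, kuramoto_weak_null, cohens_d)
import pandas as pd

rng = np.random.default_rng(0)
coll, phases = sample_kuramoto_collection(20, K=1.5, n_osc=5, length=1000, rng=rng)
radius = tune_radius(coll[0].values, target_rec=5.0, tolerance=0.5)  # 1.165
obs = pd.DataFrame([metric_battery(s, radius, include_dyadic=True) for s in coll])
sur = pd.DataFrame([metric_battery(s, radius, include_dyadic=True)
                    for s in swap_variables(coll, rng)])
print(obs.mean().round(3))
print(kuramoto_weak_null(phases))
```

Output (abridged):

```
rec_pct             5.527      # surrogate mean: 2.350
rho                 0.648      # surrogate mean: 0.436
coherence           0.194      # surrogate mean: 0.172
symbolic_entropy    4.432      # surrogate mean: 4.998
sncsd               0.701      # surrogate mean: 0.174
dyadic_corr         0.226      # surrogate mean: 0.002
weak null: p = 3.4e-05, t(19) = 5.1
```

At coupling K = 1.5 every synchrony metric sits clearly on the synchrony
side of its variable-swap baseline (entropy *below* its baseline, since
lower entropy means more regular joint states), and the weak-null test
rejects chance-level synchrony across the 20 recordings (Cohen's d for rho
vs its baseline is 2.07 here).

A CLI mirrors the library:

```sh
groupsync simulate kuramoto --k 1.5 --length 1000 --seed 3 --output ts.csv
groupsync compute --metric rho --input ts.csv
groupsync window --metric entropy --window 300 --step 300 --input ts.csv
groupsync experiment coupling-sweep --reps 100 --seed 1 --out sweep.csv
```

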