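# Methods

This note documents the models and estimators implemented in `groupsync`,
the defaults and why they were chosen, what the synthetic generators do and
do not emulate, and the package's known limitations.

## Data model

All series are real matrices of shape `(n_variables, n_timesteps)`;
variables on axis 0, time on axis 1, uniform sampling.  Readers accept
row- or column-oriented CSVs but everything downstream assumes this one
orientation, asserted at module boundaries.  Missing or non-finite values
are rejected at read time; outlier handling and filtering are considered
preprocessing and live outside the package.  A `SampleCollection` groups
recordings that share a variable count; time lengths may differ except
where an operation (variable swapping) requires equal lengths.

All randomness flows through an explicit `numpy.random.Generator`; no
function touches global random state, so a fixed seed reproduces every
stochastic result bit for bit.

## Phase extraction

Instantaneous phase comes from the analytic signal: each channel is
mean-centered (stabilizing the angle computation for offset signals), the
Hilbert transform forms the analytic signal, and the phase is its complex
argument wrapped to (−π, π].  The discrete Hilbert transform distorts a few
samples at each end; no automatic trimming is applied, and comparisons
against closed forms should ignore boundaries.  Wavelet-based extraction is
a possible extension point but is not implemented; the Hilbert route is the
default practice for the metrics here.

Phase-based inference assumes each variable's phase is roughly uniformly
distributed over the cycle.  `phase_uniformity_check` reports a per-variable
Kolmogorov–Smirnov distance from Uniform(−π, π] with an advisory flag at
distance > 0.1 (a deliberate, never-blocking diagnostic: signals with long
still periods pile phase near one value and can grossly overstate
weak-null significance).

## Metrics

**Symbolic entropy.** Terciles are nearest-rank empirical quantiles
(boundary values go to the lower level), making the discretization
deterministic and invariant under strictly monotone transforms.  The joint
symbol is the base-3 encoding across variables; entropy is Shannon entropy
of the empirical symbol distribution in nats (so the five-variable bounds
are ln 3 ≈ 1.1 and 5·ln 3 ≈ 5.5); the log base is configurable.  With T
samples the empirical entropy of a high-entropy source is biased low when
3^N is not ≪ T — windowed entropy on short windows should be compared only
against equally sized windows.

**mdRQA.** Each variable is standardized to mean 0, variance 1 (population
SD) before distances unless `normalize=False`.  Time-delay embedding
(m, τ) concatenates all variables at lags 0, τ, …, (m−1)τ; the default is
no embedding (m=1), which is standard for multidimensional RQA since the
joint state is already multivariate.  The recurrence rule is Euclidean
distance ≤ radius.  All four summaries exclude the main diagonal: %REC is
recurrent off-diagonal cells over n²−n; %DET is the share of those cells on
diagonal runs of length ≥ `min_line` (default 2, the common convention);
ADL is the mean qualifying run length; maxL is the longest off-main
diagonal run of any length.  Runs are counted on both triangles.  A
zero-recurrence matrix yields det = adl = maxl = 0.  `tune_radius` bisects
the radius into a target recurrence band (practitioners typically aim for
1–5%; the sweep drivers target 5% ± 0.5) — it proposes, and never silently
applies, a radius.

**Spectral metrics.** Welch estimates use a Hann taper, 50% segment
overlap, and constant detrending, with segment length 256 by default (75
is the sensible choice for ~300-step windows).  The DC bin is excluded from
both aggregations — channels are mean-centered in several pipelines, which
makes DC coherence degenerate; this is configurable.  Pairs are unordered
and counted once.  Team coherence averages magnitude-squared coherence
over frequencies then pairs, so every frequency bin has equal weight; with
few Welch segments the per-bin estimate carries an upward bias of order
1/n_segments even for independent signals, which is why surrogate
baselines matter for this metric.  The sum-normalized CSD instead sums
|S_xy|² across frequencies and normalizes once by Σ S_xx·S_yy, weighting
frequencies by amplitude; termwise Cauchy–Schwarz on the segment-averaged
spectra bounds it in [0, 1].  Both metrics are invariant under per-channel
positive rescaling.

**Cluster-phase rho.** The implementation follows the standard cluster-
phase construction: cluster phase = circular mean of phases across
variables; relative phases are centered on each variable's own circular
mean offset; rho(t) is the resultant length of the centered relative
phases, and the overall score is its time mean.  This absorbs constant
pairwise offsets, so a rigidly rotating ensemble scores 1.0.  Variants of
the procedure exist in the literature (e.g. different weightings); this
exact sequence is pinned by a step-by-step transcription oracle in the
test suite.

**Weak-null test.** The chance model permits autocorrelation within
variables but assumes independence between them, under which the
time-averaged squared order parameter has expectation 1/N.  Each
recording contributes one statistic, mean_t r(t)²; a one-sample t test
compares the sample of statistics to 1/N with dof = M−1.  The implemented
statistic/expectation pair is a reconstruction of the cited construction
(the original source gives the premise and interface; the exact variance
handling is not restated here) — treat borderline p values with care.  The
alternative is one-sided ("greater") by default because the test exists to
detect above-chance synchrony; two-sided is available.  The uniformity
diagnostic runs automatically and its advisory flag is attached to the
result.

**Mean dyadic correlation.** Lag-0 Pearson correlation averaged over all
unordered pairs; the dyadic reference against which the multivariate
metrics are compared in the validity studies.

## Surrogates

Segment shuffling partitions each channel into consecutive segments of a
chosen length (a trailing partial segment is kept as its own shufflable
unit) and permutes them independently per channel.  It preserves marginals
but breaks continuity at cut points, and empirically moves several metrics
even for independent channels; it is therefore not the default baseline.

Variable swapping pools all channels of an equal-length sample and regroups
them into new recordings, leaving each channel untouched internally.  By
default no surrogate recording receives two channels from the same original
recording (preventing genuine within-recording synchrony from leaking into
the baseline); this requires n_variables ≤ n_recordings and is implemented
as column-wise random bipartite matchings — each "slot" column is a random
permutation of recordings constrained to keep rows distinct, built greedily
with restarts.  The unconstrained variant (a single uniform permutation of
all pooled channels) is available via `forbid_same_member=False`.

## Windowing

`apply_windowed` slices contiguous windows (trailing remainder dropped) and
applies any per-recording metric independently; tercile boundaries,
normalization, and spectral estimates are recomputed inside each window, so
each window is a standalone recording.  Reducers `max` and `min` summarize
across windows (minimum is the natural reducer for entropy, maximum for the
other metrics).  Sample-level procedures (the weak-null test) cannot be
windowed through this interface.

## Synthetic generators

**AR(2).** X_t = c + φ₁X_{t−1} + φ₂X_{t−2} + ε_t with ε_t ~ N(0, ε²),
initialized at zero.  Defaults φ₁=0.8, φ₂=−0.2, c=0, ε=1 give a stationary
channel with smooth low-frequency autocorrelation; nonstationary
coefficient pairs trigger a warning.  Independent channels from this
process are the package's null: temporal structure, no cross-channel
coordination.  `add_correlated_noise` adds one shared N(0, s²) draw per
time step to every (standardized) channel, inducing pairwise correlation
s²/(s²+1) — spurious synchrony with a known dial.  This emulates shared
measurement artifacts that hit all channels simultaneously at every step;
real confounds are often intermittent and band-limited, so robustness here
does not guarantee robustness to real-world noise.

**Stochastic Kuramoto.** Euler integration of
θ̇_i = ω_i + K·r·sin(ψ − θ_i) plus per-step noise α·N(0, √d_t), with r and
ψ the modulus and argument of the ensemble mean unit vector.  The
observable is sin(θ) — the minimal oscillator output consistent with
Hilbert-phase recovery — and the true phases are returned alongside so
metrics can bypass extraction error.  Collections draw each recording's
natural frequencies from an exponential distribution (mean `omega_scale`)
and uniform initial phases; distinct frequency sets per recording keep
variable-swap baselines honest.  Defaults: d_t = 0.05 s, α = 0.3,
omega_scale = π rad/s, giving mean phase increments of ~0.16 rad/step —
oscillation periods of tens of samples, partial (not saturated)
synchronization across K ∈ [0, 2], and a noise floor comparable to weak
coupling.  The model assumes equal, constant, all-to-all coupling among
genuinely periodic units; empirical signals rarely satisfy any of these,
so the validity results bound what the metrics can do under ideal
conditions rather than predict field performance.

## Validation drivers and problem sizes

`noise_sweep` sweeps common-mode noise SD 0.0–1.0 in steps of 0.1 over
recordings of five standardized AR(2) channels × 1000 steps, computing all
metrics on the data and on variable-swap surrogates, and reporting Cohen's
d (pooled SD, n−1 weighting) and percent change over the baseline per
metric.  `coupling_sweep` sweeps K 0.0–2.0 in steps of 0.2 over
five-oscillator Kuramoto recordings × 1000 steps and reports, in addition,
each metric's Pearson correlation with K across the grid (criterion
validity) and the pooled per-recording inter-metric correlation matrix
(convergent validity).  The mdRQA radius is tuned once at the first (null)
grid point to ~5% recurrence and frozen across the grid so %REC is
comparable between conditions.

The package's own validation runs use 100 recordings per grid point (the
drivers default to 500), which keeps the full acceptance run under a
minute while leaving per-K means precise enough for the validity
correlations; all sizes are plain arguments.

Two caveats the sweeps make visible rather than hide: with the default AR
coefficients, frequency-averaged coherence rises to ~0.5 (not 1.0) at noise
SD 1.0, because the AR channels keep private low-frequency power where
their spectrum peaks; and in the pooled convergent-validity matrix the
coherence–%REC correlation is attenuated (~0.46) by per-recording estimator
noise in coherence and the strong right skew of %REC at high K.  Both
values are computed, reported, and tested as measured.

## Known limitations

- No imputation, filtering, or artifact handling; inputs must be clean.
- Hilbert phase is meaningful only for narrowband-ish signals; no
  band-decomposition or wavelet ridge extraction is provided.
- Vertical-line RQA measures (laminarity, trapping time), cross-RQA, and
  automated embedding selection are out of scope.
- Phase-randomization (FFT/IAAFT) surrogates are not implemented; the two
  included methods cover the common use cases.
- The weak-null statistic is a documented reconstruction (see above), and
  the uniformity requirement is checked but not enforced.
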