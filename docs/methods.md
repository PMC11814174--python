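# Methods

`popsep` analyses trial-aligned extracellular spike data from two-category
visual experiments (cat vs dog images shown to fixating macaques, recorded
in inferior temporal areas TEO and TE).  It asks how much category
information a neuronal population carries, and how that information evolves
within a trial and across category training.  Because such recordings are
rarely deposited, the package ships a generative stand-in whose structure
matches what the analyses assume, so every stage can be validated by
parameter recovery.

## Conventions

Times are in milliseconds relative to stimulus onset (0 = onset).  All
analysis windows are half-open `[t, t + Δt)`, so a spike on a shared edge of
two abutting windows is counted exactly once.  Rates are in spikes/s
(window counts divided by the window width in seconds).  Loaded datasets
default to a `[-300, 400]` ms peri-onset epoch (covering the 200–300 ms
pre-onset fixation and a 350–400 ms presentation); synthetic datasets use
`[-300, 500]` ms so that 100-ms windows starting as late as 350–400 ms — the
late group of the window-start contrast — remain inside the epoch.  Stimulus
offset dynamics are not modelled; the evoked rate is held through the epoch.

## Generative model

Neuron `n` on any presentation of image `i` fires as an inhomogeneous
Poisson process with rate

```
λ_ni(t) = max(0, b_n + 1[t ≥ L_n] · (g_n + s_n · c_i · p_n(t) + ε_ni))
```

- `b_n` — baseline rate, Normal(`baseline_rate_mean`, `baseline_rate_sd`),
  truncated at 0 (defaults 4 ± 1.5 spikes/s, in the 2–5 spikes/s range of
  the recorded populations);
- `L_n` — response latency, Normal(`latency_mean`, `latency_sd`) ms
  (defaults 65 ± 15 ms; reported population means span ≈38–107 ms);
- `g_n` — visual response gain, Normal(`response_gain_mean`,
  `response_gain_sd`) (defaults 8 ± 3 spikes/s), applied to every image;
- `s_n` — category selectivity: 0 with probability
  `1 − selective_fraction`, otherwise `± category_contrast · training_gain`
  with random sign.  `c_i` is +½ for dog and −½ for cat images, so the
  between-category rate difference of a selective neuron is
  `|s_n| · p_n(t)`;
- `p_n(t)` — temporal profile of the category signal: `step` (1 from
  latency onward — a temporally flat, TEO-like code) or `ramp` (rising
  linearly from 0 at `L_n` to 1 at `ramp_end`, default 255 ms — a TE-like
  code whose separation builds within the trial; 255 ms is where TE
  decoding peaked in the recorded data);
- `training_gain` — multiplier on the contrast modelling the post-training
  enhancement in TE.  No quantitative effect size is published; 1.5 is the
  demonstration default and tests sweep it;
- `ε_ni` — Normal(0, `image_idiosyncrasy_sd`) offset drawn once per
  (neuron, image) and shared by that image's trials, so images within a
  category are similar but not identical.  Without it, a per-image
  classifier would face a trivially separable problem.

Spikes are sampled by thinning: per (neuron, trial), `Poisson(λ_max · T)`
candidate times are drawn uniformly over the epoch and kept with
probability `λ(t)/λ_max`, where `λ_max` is the exact ceiling of the
piecewise-linear rate.  Poisson spiking without refractoriness is
sufficient because every analysis consumes only windowed counts, and it
keeps the analytic oracle closed-form.  Truncation of `λ` at 0 is ignored
by the oracle; validation configs keep baselines ≳3 SD above the
modulation so truncation is negligible.

Reproducibility: the population parameters come from one named RNG stream
and each (neuron, trial) has its own stream, all spawned from
`SeedSequence(seed, spawn_key=…)` — spike trains are bit-identical across
runs and independent of iteration order.

### Analytic window separation

For a window `[a, b)` the expected population-scale Mahalanobis distance is

```
D_pop = sqrt( Σ_n δ_n² / σ_n² )
δ_n   = |s_n| · ∫_a^b 1[t ≥ L_n] p_n(t) dt / (b − a)
σ_n²  = λ̄_n / (trials_per_image · Δt_s) + (image_idiosyncrasy_sd · f_n)²
```

with `λ̄_n` the window-mean rate (baseline plus gain times the
post-latency window fraction `f_n`) and `Δt_s` the width in seconds: the
within-class variance of a per-image trial-averaged rate is its Poisson
sampling variance plus the idiosyncratic rate variance.  The empirical
pipeline computes D from the *unnormalised* within-class scatter `S_W`
(see below); to compare an estimate against `D_pop`, the package's
recovery protocol applies the standard inverse-Wishart debiasing

```
D_pop² ≈ D̂_scatter² · (n − 2 − N − 1) − N · (1/n₁ + 1/n₂)
```

(`n` images total, `N` neurons), which corrects both the scatter scale,
the inversion bias and the chance-level floor of the estimated mean
difference.

## Responsiveness

A neuron is visually responsive if its rate changes significantly for at
least one image: per (neuron, image), a two-sided paired t-test compares
per-trial rates in a baseline window (default `[-200, 0)` ms) against the
stimulus window (default `[0, 350)` ms — the minimum presentation
duration); the test operates on rates rather than counts so unequal window
widths are handled (with equal widths the p-value is identical).  Benjamini–
Hochberg FDR correction is applied across the image tests; the default
family is the 520 tests within one neuron (keeping each neuron's
classification self-contained), with a `global` switch pooling all
neuron × image tests.  All-zero per-trial differences give p = 1 and an
undefined direction (logged), never an error.  Neurons are classed
`only_dog` / `only_cat` / `both` / `none` by the categories of their
significant images, and pooled summaries report
`100 · Σ(total − none) / Σ(total)`.

Firing-rate functions are trial-pooled Gaussian KDEs (bandwidth fixed at
10 ms); the integral of the rate over a grid covering the spikes recovers
the mean spike count per trial, which is asserted to 1e-3 relative.

Onset latency uses a threshold rule of this package's own devising (the
field has no single standard and the source analyses do not state one):
the earliest t ≥ 0 where the KDE rate exceeds baseline mean + 3 baseline
SD continuously for ≥ 20 ms.  The rule's parameters are attached to every
estimate so downstream consumers can see exactly what produced a number.

## Population vectors and decoding

The population vector of image `i` in window `[t, t+Δt)` holds each
neuron's spike count averaged over that image's trials, divided by `Δt` —
a 520 × N matrix at full stimulus count.  Pseudo-populations concatenate
neuron columns across datasets (monkeys/arrays/sessions), aligned by
shared image identity — the only construction available for
non-simultaneous recordings; provenance records the sources.  Trials are
averaged within a dataset first, then concatenated, so unequal trial
counts (5–19 across monkeys) never weight one source's noise into
another's columns.

Decoding is binary logistic regression `y(Φ) = σ(wᵀΦ)` on population
vectors, fit by minimising cross-entropy via scikit-learn's LBFGS with an
intercept.  The default adds a weak ridge penalty (λ = 1, i.e. C = 1):
with N up to a few hundred features and ~470 training rows per fold,
separable windows make the unpenalised optimum diverge; `reg=None`
restores the plain cross-entropy objective.  Accuracy is stratified
10-fold cross-validation with hard decisions at σ = 0.5 (exact ties to
dog, a measure-zero convention).  The fold assignment is drawn once per
run from the decoder seed and reused at every window, so accuracy curves
are pointwise comparable — the paired across-window tests depend on this.
Sliding grids default to 100-ms windows stepped 1 ms (a 50-ms window is
too brief and 200 ms too smoothing for fixation-epoch dynamics).

## Fisher LDA and Mahalanobis separation

With per-image rows `x` and class means `m₁` (cat), `m₂` (dog):

```
S_W = Σ_k Σ_{n∈C_k} (x_n − m_k)(x_n − m_k)ᵀ      (unnormalised scatter)
S_B = (m₂ − m₁)(m₂ − m₁)ᵀ
J(w) = wᵀS_B w / wᵀS_W w
ŵ ∝ S_W⁻¹ (m₂ − m₁),  normalised so ŵᵀS_W ŵ = 1
D  = sqrt((m₂ − m₁)ᵀ S_W⁻¹ (m₂ − m₁))
```

`J(ŵ) = λ_max(S_W⁻¹S_B) = D²`; the implementation computes each quantity
independently from quadratic forms and asserts the identities to 1e-8
relative whenever a separation result is constructed.  D is reported as
the square root of the quadratic form (the criterion is proportional to
D², which forces the root and the transpose).

`S_W` inversion is a recorded policy because N can approach the
within-class degrees of freedom: `ridge` (default; Tikhonov
ε = 1e-6 · trace(S_W)/N on the diagonal — for ridge the identities are
evaluated in the stabilised metric), `strict` (plain solve, error when the
condition number exceeds 1e12), or `pinv` (truncated pseudo-inverse,
relative tolerance 1e-10).

## Statistical comparisons

- Accuracy curves: paired t over per-window differences, paired by window
  start (the only index two curves share), one- or two-sided.  Identical
  curves return p = 1 with a degenerate flag.
- Separation: Mann–Whitney U between D samples whose window starts fall in
  two disjoint ranges (defaults 0–100 ms vs 250–350 ms, inclusive): exact
  null distribution when the combined sample is ≤ 20 without ties,
  otherwise the normal approximation with tie and continuity correction.
- Responsive proportions: pooled two-proportion z-test, two-sided.

All p-values are raw; no correction is applied across comparisons.

**Caveat — autocorrelated window samples.**  D values from 100-ms windows
stepped 1 ms overlap by 99%; a range of 101 window starts carries roughly
one to two statistically independent values, not 101.  The Mann–Whitney
contrast treats them as independent and is therefore strongly
anticonservative: in simulations with an exactly flat separation time
course, the two-sided early-vs-late test rejects far more often than its
nominal level (the scatter-inversion noise of `S_W`, with CV ≈ √(2/(n−2−N))
on D², gives distant window segments persistently different levels that a
rank test then "detects").  Detecting a genuine ramp this way is reliable;
*certifying flatness* by a non-significant result is not, at desk scale.
`mannwhitney_windows(..., thin=k)` subsamples every k-th window as a
robustness option, and ratio-based summaries (late/early mean D) are the
recommended flatness check.

## Validation protocols and problem sizes

The bundled protocols (`popsep.protocols`, exercised by the acceptance
tests and `scripts/acceptance.py`) run at deliberately reduced scale so a
sweep completes in minutes on one CPU:

- window contrast: 50 neurons, 40 images/category, 10 trials/image,
  20 seeded runs per profile.  TEO-like: step profile, contrast
  1.5 spikes/s (the recorded TEO populations separate categories less than
  TE), latency 40 ± 10 ms (short end of the reported range, so early
  windows lie past response onset).  TE-like: ramp to 255 ms, contrast
  2.5 spikes/s, training gain 1.5;
- chance calibration: 30 neurons, 80 images, labels permuted once,
  401 windows; the pointwise 99% binomial band is ±2.576·√(0.25/80);
- parameter recovery: 10 neurons, 100 images/category, 200 trials/image,
  all neurons selective, idiosyncrasy noise at its default — empirical
  debiased D tracks the analytic value within 15%;
- null error control: 80 neurons, 520 images, 5 trials/image, no visual
  response at all — responsive fraction stays below α + 3·binomial SE.

What passing these protocols shows — and does not show.  The generator
reproduces the *statistical skeleton* the analyses assume: Poisson
variability, per-image idiosyncrasy, latency jitter, flat vs ramping
category signals, a training-gain contrast.  It omits correlated noise
across neurons, firing-rate adaptation, offset responses, eye-movement
artefacts and non-Poisson dispersion, so passing recovery here validates
the pipeline's correctness, not any claim about cortical data.

## Known limitations

- Pseudo-population vectors are trial-averaged per image; single-trial
  decoding is out of scope.
- The Mann–Whitney window contrast inherits the autocorrelation caveat
  above.
- The latency rule is a package convention; estimates should be compared
  only within a fixed rule.
- `expected_window_separation` ignores rate truncation at zero and is
  inaccurate for configurations whose modulation regularly drives λ
  negative.
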