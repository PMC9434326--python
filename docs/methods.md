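# Methods

## Model

The oscillator is the damped-harmonic form
`y(t) = A exp(-γt/2) cos(2πt/τ + φ) + y0`, with `t` in hours post
synchronization (t = 0 at the first sample). `γ` is the amplitude-change
(AC) coefficient: the envelope halves every `2 ln 2 / γ ≈ 1.39/γ` hours.
Amplitude is normalized non-negative (a sign flip is absorbed as a
half-turn of phase) and `φ` is reduced to `[0, 2π)`. The trend library
adds `m·t + b` (linear), `a·e^{kt} + c` (exponential, `|k| ≤ 1`/h to keep
the curve finite over a multi-day course), and oscillator + `m·t`.

AC categories partition `γ`: harmonic for `|γ| ≤ 0.15`/h, damped/forced
up to `±1`/h, repressed/overexpressed beyond. The inner cutoff 0.15/h
corresponds to an envelope change of roughly a third per 24-h cycle —
about the smallest change distinguishable from harmonic at realistic
noise on a two-day course; the outer cutoff 1/h marks envelopes that
collapse or explode within half a day, which read as monotone expression
change rather than rhythm. Both are configurable; boundary values go to
the milder category. Only damped/harmonic/forced are eligible for a
circadian call.

## Conditioning chain

`presence_filter` (default: feature observed in ≥ 70 % of samples,
boundary inclusive) → `impute_missing` (linear interpolation over time
within each replicate series, constant at the edges; feature-mean
fallback when a series has no observations or the feature has fewer than
two) → `zscore_rows` (sample SD, `ddof=1`; constant rows map to zeros) →
`detrend_linear` (per-feature OLS line subtracted) → `smooth` (centered
kernel `(1,2,1)/4` within each replicate series, weights renormalized at
the ends). Each step is idempotent where that is meaningful (z-score,
detrend) and the chain never introduces missing values. Batch-effect
correction is deliberately out of scope; the filter + imputation pair is
the package's substitute for heavier upstream cleaning, and replicates
are never averaged — the fit consumes every sample.

## Fitting and inference

Free-run period bounds default to `[2Δt, span]` (= [4, 48] h for the
reference design): "no period restriction" still needs numeric limits,
and these are the resolvable extremes. The start grid scans periods at
2-h steps; at each candidate period the model with `γ = 0` is linear in
`(A cos, A sin, y0)`, so phase/amplitude/baseline are profiled out by
exact linear least squares rather than enumerated on a phase grid — this
dominates any discrete phase grid at the same cost and keeps the
procedure fully deterministic. The best-screened periods (3 by default)
seed bounded trust-region refinements of all five (six with slope)
parameters; two extra starts at `γ = ±0.4` guard against strong
damping/forcing that the `γ = 0` screen underrates. The lowest-RSS
converged refinement wins; if nothing converges the best screened
evaluation is returned flagged `converged=False`.

Significance is a nested F-test of the fitted trend against the
intercept-only model, `F = ((RSS₀−RSS₁)/(k−1)) / (RSS₁/(n−k))` with `k`
the model's free-parameter count (5 for the oscillator). Counting the
period and phase in `k` partially absorbs the selection effect of
free-running; raw p-values on pure noise are still anti-conservative
(~23 % below 0.05 in the null benchmark), but after Benjamini–Hochberg
adjustment across features the called fraction at q < 0.05 is ~0.1 % —
the postrun period window and the BH step, not the raw p-value, carry the
error control. The circadian call (`postrun_restrict`) keeps oscillatory
fits with period inside the window (inclusive), `q < 0.05` (strict) and a
circadian AC category.

Model selection in the trend library uses BIC
(`n ln(RSS/n) + k ln n`) with RSS floored at `1e-18·n`, so numerically
perfect fits are tied and the parameter penalty decides (a pure
oscillator is reported as ECHO, not ECHO-Linear-with-zero-slope).

## Joint modeling

Two channels of the same feature are stacked into one weighted
least-squares problem sharing `τ` and `φ`, with per-channel amplitude,
AC, baseline (and slope for the linear variants). Sharing the phase as
well as the period encodes that the paired channels express the *same*
underlying rhythm; phase-delay questions remain a downstream comparison
of peak times between separately fitted channels. Channel weights are
inverse residual variances from the independent fits, re-estimated once
from the joint residuals; the shared parameters are anchored on the
higher-weight (cleaner) channel's independent fit. Per-channel p-values
reuse the nested F-test on that channel's residuals under the joint
parameters. A zero-variance channel makes the weighting ill-posed; the
fit falls back to independent fits with a warning.

The six-way labeling: an independently significant oscillation inside
the channel's window is ECHO (or ECHO Linear per the selected model); one
that only reaches significance under the joint fit is ECHO Joint (or
ECHO Linear Joint); otherwise a significant non-oscillatory winner keeps
its name; otherwise the feature is unlabeled. Because the independent
fit minimizes its channel's RSS while the joint fit constrains it, the
joint p-value can never undercut the independent one on *identical*
channels — the Joint labels genuinely require a second, cleaner channel.
The power gain on a noisy channel comes mostly through the period: a
noisy independent free-run fit often locks onto a spurious period
outside the circadian window, while the shared period stays anchored by
the clean channel.

## Synthetic data

The generator emulates the reference design: 25 timepoints (0–48 h,
step 2), 3 replicates, Gaussian noise on the z-scored scale with SD 0.2
(RNA) and 0.8 (protein) — the analysis operates post-z-score, so
generating on that scale keeps signal-to-noise interpretable. Oscillator
parameters: `τ ~ U(20, 28)` h, `A ~ U(0.5, 2)` z-units,
`φ ~ U(0, 2π)`, `y0 = 0`, `γ` uniform over `[-0.3, 0.3]`/h (or a
category's band for class-labeled draws). Paired features share `τ` and
`φ` across channels and re-draw amplitude and AC per channel.
Missingness, when requested, is uniform at random. Everything is
deterministic given the seed.

What the generator does *not* emulate: count-level noise (values are
Gaussian, not negative binomial), batch effects, heteroscedasticity over
time, autocorrelated noise, or non-sinusoidal waveforms. Passing the
recovery and power benchmarks therefore demonstrates correctness of the
estimator and the joint-modeling mechanism under the stated noise model,
not robustness to every artifact of real RNA-seq/TMT-MS data.

## Benchmarks and problem sizes

The standard benchmarks (`circatrend.benchmarks`, also run by
`scripts/acceptance.py`) use 200 oscillators at noise SD 0.3 for
recovery, 1,000 flat features at SD 1 for type-I control, 200 paired
features (SD 0.2/0.8) for joint-modeling power, and one noiseless curve
per library model for exactness — sizes chosen to give stable rates in a
few minutes on one core. Recovery and power benchmarks fit the generated
series directly: the generator already produces data on the z-scored,
trend-free scale the fit expects, and applying the real-data conditioning
chain to extreme forced envelopes (which z-scoring compresses and
detrending distorts) would measure the conditioning, not the estimator.

A note on period precision under these conditions: with damping up to
`γ = 0.3`/h the informative part of the series shrinks to roughly the
first day, and the Fisher information for `τ` drops accordingly — the
Cramér–Rao bound for this design and parameter mix caps *any* unbiased
estimator near 77 % of features within ±1 h of the true period. The
fitted estimator sits at that bound (it attains the global least-squares
optimum on every benchmark feature); AC-category accuracy (~92–96 %) and
detection recall (~99 %) are not similarly limited.

## Numerical choices and edge cases

- Refinement tolerances `xtol = ftol = 1e-12`, ≤ 400 function
  evaluations; AC coefficient bounded to `[-3, 3]`/h.
- Ties in the multi-start pool resolve to the first (deterministic
  screen order) within `1e-12` RSS.
- `peak_time` is the first non-negative cosine peak
  `((−φ) mod 2π)·τ/2π`, guarded against a denormal phase rounding the
  modulus up to a full turn; undefined at zero amplitude.
- Fisher's exact p-values use probability-ordering (two-sided); the
  reported odds ratio is the sample OR with Haldane's +0.5 correction
  when a cell is zero, with the conditional-MLE OR available because
  published ORs may follow either convention.
- File dialect: wide CSV/TSV, sample columns `<timepoint>.<replicate>`
  (split at the last dot, so fractional timepoints parse), missing values
  empty or `NA`; duplicate feature ids are rejected at parse time.
- Circadian-time conversion is `(HPS − offset) mod 24` with the offset
  anchored on a reference rhythm's peak (e.g. Per2).

## Known limitations

Single-component sinusoids only (no ultradian mixtures or cosinor-style
multi-harmonic fits); joint modeling couples exactly two channels; the
F-test's raw p-values are anti-conservative under free-running and
should not be used without the BH + window postrun step; enrichment
denominators are caller-defined (the table constructor is parameterized
rather than hard-coding a background set).
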