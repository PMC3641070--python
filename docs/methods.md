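# Methods

## Signal model and assumptions

The analysis object is the center-of-pressure (COP) *magnitude series*: the
Euclidean displacement between consecutive samples of a 2-D force-plate
trajectory. The magnitude series is non-negative and one sample shorter
than the trajectory; it is analyzed raw — no filtering, decimation or
detrending is applied before the magnitude computation, so the exponents
describe the recorded dynamics, not a preprocessing choice. Fractal
structure is quantified on the integrated, mean-removed series (the
profile), assuming the underlying process is reasonably described by a
power-law relation `F(s) ~ s^alpha` between RMS fluctuation and time scale,
possibly with one change of regime (a crossover).

## Empirical mode decomposition

EMD represents the profile as a sum of intrinsic mode functions (IMFs) plus
a residual trend. Each sifting pass subtracts the mean of two envelopes:
natural cubic splines through the local maxima and minima respectively.
Implementation choices:

- **Extrema.** Strict sign-change extrema; a flat plateau counts once, at
  its midpoint (rounded down). Endpoints are never extrema.
- **Boundaries.** Two extrema at each end are mirrored across the end
  samples before spline fitting. Mirroring is the least-surprising standard
  treatment and bounds envelope swings at the record edges.
- **Stopping (per mode).** Cauchy-type criterion: sifting stops when
  `sum((h_prev - h)^2) / sum(h_prev^2) < 0.2`, with a hard cap of 200
  passes. 0.2 is in the canonical 0.2–0.3 range; the threshold and cap are
  configurable.
- **Stopping (decomposition).** Modes are extracted until the remainder
  has too few extrema to form envelopes (at most 2 local extrema — a
  trend). During decomposition the envelope builder tolerates a single
  minimum or maximum (falling back to linear interpolation through the
  mirrored points) so the remainder is driven down to a true trend; the
  public single-sift operation requires two extrema of each kind.
- **Completeness.** The residual is defined as the arithmetic remainder of
  the input after the extracted IMFs, so IMFs + residual reconstruct the
  input to floating-point rounding on every input. The test suite asserts
  a 1e-8-of-range bound.

EMD here is fully deterministic: no ensemble averaging, no noise
injection.

## Intrinsic scales and the fluctuation function

Within each IMF, the distance in samples between neighboring local minima
is one intrinsic scale — a single mono-component oscillation. The residual
trend contributes no scales. For a scale `s`, the per-scale series keeps
each IMF's samples on the half-open index ranges `[m_k, m_{k+1})` whose
length is `s` and zeros everything else, then sums across IMFs; the
half-open convention makes the segments of one IMF partition the span
between its first and last minima, so no sample is double-counted within an
IMF.

Two readings of the RMS normalization are implemented:

- `retained` (default): `F(s) = sqrt(sum Y_s^2 / n_retained)` — the RMS
  amplitude of the oscillations actually present at scale `s`.
- `full`: `F(s) = sqrt(sum Y_s^2 / N)` — divide by the whole record
  length, zeros included.

The `full` reading couples `F(s)` to the *occupancy* of scale `s` (how many
samples happen to carry it), not only to its amplitude. On monofractal
fractional Gaussian noise, where theory demands a single straight line in
log-log space, the occupancy factor varies systematically with `s` and the
`full` reading manufactures a pronounced spurious crossover, while the
`retained` reading reproduces the conventional-DFA exponent. `retained` is
therefore the default; `full` remains a config/CLI option for comparison.

## Scale binning and the crossover fit

Every distinct integer scale gives a curve point in principle, but large
scales typically occur in a single segment each, so their `F` values
scatter widely and a breakpoint fit latches onto that noise. The pipeline
defaults therefore:

- restrict scales to `[4, N/8]` samples — segments of 2–3 samples cannot
  represent an oscillation (same floor as DFA's minimum window), and scales
  beyond N/8 rest on a handful of segments;
- pool scales into log-spaced bins, 5 per decade, computing `F` on the
  pooled reconstruction and reporting the count-weighted geometric-mean
  scale per bin ("log" binning; "none" = exact integer scales and "merge" =
  pool adjacent scales until each bin retains 100 samples are also
  available);
- require each fitted regime to span at least 5 curve points (≈ one decade
  of scales at the default binning).

The crossover fit scans every admissible breakpoint of the sorted
(log10 s, log10 F) points, fits two independent ordinary-least-squares
lines (no continuity constraint — the regimes are two separate linear
regions), and keeps the breakpoint with minimal total SSE, ties going to
the smaller index. The crossover scale is the geometric mean of the scales
adjacent to the breakpoint. With fewer than twice the minimum points the
result falls back to a single global slope and says so (`single_slope`);
a slope difference under 0.05 sets `no_distinct_regimes`. A global
single-line slope (`alpha_global`) is always reported alongside.

These defaults were calibrated on synthetic ground truth before being
frozen: on monofractal fGn (H = 0.3, 0.5, 0.7, 0.9; n = 2^14; 10 seeds) the
mean |alpha_Short − alpha_Long| stays below 0.15 and the global slope
tracks conventional DFA within 0.04, while on two-regime composites
(crossover 64 samples, n = 2^15) the crossover is recovered within a factor
of 2 in ≥ 9/10 seeds and both slopes within 0.12 of truth.

**Resolution tradeoff.** Requiring decade-wide regimes means the default
configuration cannot place a crossover below roughly 30 samples. Quiet-
stance COP magnitude series at 1000 Hz are reported to cross over around
10 ms (10 samples); resolving that regime requires `binning="none"` (or a
finer `bins_per_decade`) with `min_points_per_segment=3`, at the cost of
more variance in the fitted slopes. Both knobs are exposed in the config,
the CLI and the result bundle.

## Conventional DFA baseline

Textbook DFA-1: integrate the mean-removed series; for each of 20
log-spaced window sizes in `[4, N/4]`, partition the profile into
non-overlapping windows from the start *and* from the end (so trailing
samples are used), subtract a least-squares line per window, and pool the
residuals into `F(n)`; `alpha` is the OLS log-log slope over all window
sizes. Detrending order and the window grid are arguments. Windows smaller
than `order + 2` points are rejected.

## Synthetic generators

All generators are pure functions of (parameters, seed).

- **fGn** — circulant embedding of the exact autocovariance
  `gamma(k) = 0.5(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H})`; one FFT gives the
  embedding eigenvalues, a complex-Gaussian synthesis gives a series with
  exactly this covariance (unit variance). If the embedding fails positive
  semi-definiteness (extreme H at small n) the generator falls back to
  random-phase spectral synthesis with a logged warning. Chosen over
  approximate schemes because the closed-form autocovariance makes the
  generator itself testable (lag-1 autocorrelation of H = 0.7 fGn is
  `2^{2H−1} − 1 ≈ 0.320`).
- **Composite** — random-phase Fourier synthesis with power-law amplitude
  `f^{−beta/2}`, `beta = 2*alpha − 1`, using `alpha_fast` above the splice
  frequency `1/crossover_scale` and `alpha_slow` below, amplitude-matched
  at the splice so the spectrum has no step (a step would create a spurious
  plateau in `F(s)`). The crossover must lie in `[8, n/8]`.
- **COP-like trials** — x and y are independent integrals of composite
  noises, scaled to a radial RMS displacement of 3 mm about the mean, plus
  one slow sinusoidal drift cycle (1 mm, quadrature phase between axes).
  Defaults emulate the target protocol: 20 s at 1000 Hz, increments with
  `alpha_fast = 1.0` (pink-like short scales), `alpha_slow = 0.5`
  (white-like long scales), crossover 64 samples. Ground-truth parameters
  travel in the trajectory metadata.

What the COP simulator does *not* emulate: biomechanics (no inverted
pendulum or intermittent control), sensor quantization, or the nonlinear
coupling between amplitude and correlation found in real sway. Passing
tests on it demonstrate plumbing and orderings (e.g. cohorts generated
with faster short-scale exponents score higher alpha_Short), not clinical
validity; absolute exponent recovery is asserted on the 1-D generators
where theory is exact.

- **Spectral exponent** — Hann-windowed, mean-removed periodogram; the 3
  lowest and highest positive-frequency bins are excluded; log-power is
  averaged within 30 log-spaced frequency bands before the OLS slope.
  Band-averaging is used because raw periodogram ordinates crowd the
  high-frequency end of the log axis and would dominate an unweighted fit;
  averaging log-power inside bands shifts the intercept (the χ² log-bias
  is frequency-independent) but not the slope.

## Degenerate inputs and numerical conventions

- Trajectories must have ≥ 2 finite samples; the magnitude series of a
  constant trajectory is all zeros; a collinear COP cloud yields ellipse
  area 0 with a `RuntimeWarning` instead of an exception, so batch runs
  survive flat trials.
- Trial duration is `(n − 1)/fs` (elapsed time between first and last
  samples), so speed equals path length over elapsed time exactly.
- The 95% ellipse uses the unbiased (n − 1) covariance and the 0.95
  chi-square quantile with 2 dof (`≈ 5.9915`).
- EMD-DFA requires ≥ 512 samples; EMD requires ≥ 16. A scale whose mask
  retains no samples, or whose `F` is zero, is dropped from the curve with
  a logged warning, never silently.
- Scales pooled across IMFs: when different IMFs contain segments of the
  same integer length, they are reconstructed together at that scale.
- JSON result bundles use sorted keys and shortest-round-trip floats, so
  write → read → write is byte-identical; reruns with identical config and
  seed reproduce artifacts exactly.

## Problem sizes used in validation

The test suite and the acceptance script use n = 2^14 for exponent
recovery and consistency checks (10 seeds per condition), n = 2^15 for
crossover recovery on composites, n = 20000 (the 20 s × 1000 Hz protocol
length) for EMD completeness and the simulated COP trial, and 10^5 points
for the Gaussian ellipse check.

## Known limitations

- The default crossover-fit configuration trades resolution for
  robustness; crossovers below ~30 samples need non-default settings (see
  above).
- alpha_Short is mildly biased low (~0.05–0.1) at the shortest scales
  because 4–10-sample oscillations are coarsely discretized.
- Two-regime fits on records shorter than ~2^12 samples frequently fall
  back to a single slope: there are too few usable scale bins to support
  two decade-wide regimes.
- The spectral cross-check `beta = 2*alpha − 1` holds for the stationary
  noise regime (0 < alpha < 1 roughly); strongly nonstationary inputs
  (alpha near 1.5+) show the expected finite-size deviations.
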