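# Methods

## Model and assumptions

The package targets series with as few as four non-negative observations on
strictly consecutive integer periods. The GM(1,1) grey model assumes that
the *accumulated* series x⁽¹⁾ is well approximated by the solution of a
first-order linear ODE, i.e. that the raw series is approximately a
geometric (exponential-trend) sequence plus irregularity that accumulation
smooths out. No distributional assumptions are made; nothing is stochastic
in the fitting path.

The contribution implemented here is the background-value weighting.
Writing the discrete grey equation x⁽⁰⁾(k) + a·z⁽¹⁾(k) = b for k = 2..n,
the background value is

    z⁽¹⁾(k) = x⁽¹⁾(k−1) + MF_k · x⁽⁰⁾(k),   MF_k ∈ [0, 1],

with MF_k the triangular mega-trend-diffusion membership of observation k.
MF_k = 0.5 for all k recovers the conventional midpoint model exactly
(verified as a test invariant). The intuition: an observation close to the
sample's central location is "typical" of the trend and may weight the
newest datum heavily; outlying observations are discounted toward the older
accumulated level.

## The MTD profile

For a window with minimum e̲, maximum ē, CL = (ē+e̲)/2:

- N⁺/N⁻ count observations strictly above/below CL; ties at CL belong to
  neither flank (and receive membership 1).
- SU = N⁺/(N⁺+N⁻), SL = N⁻/(N⁺+N⁻).
- s² is the unbiased sample variance (denominator n−1).
- Upper bound: UB = CL + SU·sqrt(−2·s²/N⁺·ln 10⁻²⁰); lower bound:
  LB = CL − SL·sqrt(−2·s²/N⁻·ln 10⁻²⁰). The expansion constant ln 10⁻²⁰
  ≈ −46.05 is fixed (exposed as `EXPANSION_COEFFICIENT`, never silently
  changed); it corresponds to diffusing each flank to the 10⁻²⁰ density
  level of a normal kernel, ≈ ±6.8 flank-standard-deviations.
- Adjusted bounds clamp outward so the interval always covers the data:
  UB_adj = max(UB, ē), LB_adj = min(LB, e̲).

Two genuinely open design points were settled as follows:

1. **Lower-bound skew coefficient.** Transcriptions of the MTD recipe
   circulate with either SU or SL multiplying the lower radical. This
   package uses SL — the mirror image of the upper flank — as the default,
   which is also the only reading that reproduces the case study's
   published coefficients (a = 0.03483, b = 24.71380) bit-for-bit at the
   printed precision. The SU variant remains available via
   `lb_skew="su"` / `--lb-skew su` for comparison.
2. **Clamp direction.** Both bounds clamp *outward* (interval must cover
   the data); a lower bound clamped inward would contradict the purpose of
   avoiding insufficient expansion and fails to reproduce the published
   fit.

Degenerate windows raise explicit errors rather than fabricating a
profile: constant series (no variance, empty flanks), one-sided samples
(a flank with zero count would divide by zero inside the radical), and
zero-width membership flanks.

## Fitting and forecasting

The n−1 discrete equations are stacked as Y = B·[a, b]ᵀ with rows
[−z⁽¹⁾(k), 1] and solved by QR-based least squares (`numpy.linalg.lstsq`).
The literal normal-equations solution (BᵀB)⁻¹BᵀY is retained in the test
suite as an independent extended-precision oracle; the two agree to 1e−8
relative error on well-conditioned inputs. Guard rails: at least 4
observations per fit (grey-theory convention; configurable upward only),
singular design → error, |a| < 1e−12 → explicit near-zero-development
error rather than a silent linear-limit fallback (the time response
divides by a). No intermediate rounding anywhere; presentation layers
round to 5 decimals (coefficients), 3 (values), 2 (MAPE percent).

The time response x̂⁽¹⁾(k+1) = (x⁽⁰⁾(1) − b/a)e^(−ak) + b/a uses the
initial condition x̂⁽¹⁾(1) = x⁽⁰⁾(1); raw forecasts are its first
differences, so consecutive forecasts have the exact ratio e^(−a).
Negative forecasts are mathematically possible for extreme inputs and are
returned as-is with a warning, never clamped.

## Rolling procedures

- `backtest(series, window)`: for each period after the first `window`,
  fit on the preceding `window` *actual* values and predict one step.
  Membership values are recomputed for every window — they depend on the
  window's min/max/variance and are never reused. MAPE (stored as a
  fraction, displayed as percent) is graded on the Lewis scale with
  half-open boundaries [10, 20), [20, 50) at the printed cut points.
- `rolling_forecast(series, window, horizon)`: starts from the `window`
  most recent actuals; each step appends its forecast and drops the oldest
  value, so windows are forecast-augmented from step 2 onward (flagged in
  the result's provenance). Useful for medium-term trend reading; errors
  compound with horizon since later fits consume earlier forecasts.

These are deliberately two distinct operations: backtesting measures
out-of-sample skill on real data only, the rolling forecast extrapolates
beyond it.

## Synthetic generator

`generate(SyntheticSpec)` produces series whose accumulated values follow
the grey time response exactly for chosen (a*, b*, x₁), each value after
the first optionally multiplied by (1 + ε), ε ~ N(0, noise_sd²) under an
explicit seed. Multiplicative noise keeps small-noise series positive and
matches the relative-error metric (MAPE) used throughout; generation
raises if noise drives a value negative. Defaults in tests use a* = 0.05,
b* = 25, x₁ = 24, n = 8 — magnitudes comparable to the bundled emission
series, with a decay rate in the range the method is designed for.

What passing tests show: the pipeline recovers its own dynamics (zero
noise → â within 5% of a*, and *exactly* when fitted with the constant
weight (a + e^(−a) − 1)/(a(1 − e^(−a))) that makes the discrete equation
consistent for exponential data), and degrades gracefully with noise. What
they do not show: real emission series are not exponential-plus-
multiplicative-noise; structural breaks, policy shocks and measurement
revisions are outside the generator's scope and the model's assumptions.

## Problem sizes and determinism

All case-study computations are desk-scale (n = 9, windows of 4) and run in
milliseconds; property suites use samples of length ≤ 30 with derandomised
hypothesis settings. Everything in the fit/backtest/forecast path is
deterministic; randomness exists only in the synthetic generator, always
behind an explicit seed.

## Known limitations

- Single-variable GM(1,1) only: no multivariate GM(1,N), grey Verhulst,
  interval grey numbers, or heuristic background optimisation.
- No prediction intervals; point forecasts only.
- MAPE is undefined when an actual value is zero; series touching zero can
  be modelled but not MAPE-scored.
- The membership weighting assumes the window's extremes are meaningful
  trend anchors; a single gross outlier distorts CL and both bounds.
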