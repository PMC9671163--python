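# Methods

## Envelope extraction

A waveform `x[t]` sampled at rate `fs` (expected 44.1 kHz, 16-bit PCM; other
PCM depths and float WAVs are accepted, with integer data scaled by
`2^(bits−1)`) is converted to an amplitude envelope in three linear stages:

1. **Rectification** — elementwise absolute value.
2. **Zero-phase low-pass filtering** — a 3rd-order Butterworth IIR filter
   applied forward then backward (`scipy.signal.filtfilt`), giving an
   effective 6th-order magnitude response and exactly zero phase shift. The
   default cutoff is `fs/4`, half the Nyquist frequency (11.025 kHz at
   44.1 kHz). This cutoff barely smooths a rectified broadband signal; it is
   kept as the pipeline's definition rather than "corrected" to a conventional
   envelope cutoff of a few tens of Hz, because the subsequent 125-ms block
   average is what actually determines the envelope bandwidth. Edge handling
   uses `filtfilt`'s odd-reflection padding (3× the filter length, well beyond
   3× the filter order).
3. **Block averaging** — the arithmetic mean over consecutive,
   non-overlapping 125-ms windows (~8 Hz output). A trailing partial window is
   dropped rather than padded, so the output length is
   `floor(duration / 0.125)`; padding would bias the final mean toward
   whatever the pad value was.

All three stages are linear (up to the rectification nonlinearity at the
input), so doubling the input amplitude doubles every envelope point; tests
assert this, along with nonnegativity and the zero-phase property.

Multichannel WAVs are rejected by default; a `downmix` policy averages
channels before scaling. No peak normalization is applied: the Pearson-based
similarity measures and the variance-ratio GC are both invariant to positive
rescaling, so normalization would be a no-op downstream.

## Granger causality

For aligned envelopes `X` (recording) and `Y` (performance), both demeaned per
trial, two nested models of `Y` are fitted by per-equation OLS at lag order
`p`:

* reduced: `Y_t` on `Y_{t−1..t−p}`;
* full: the `Y`-equation of the bivariate VAR(p) (`Y_t` on `Y_{t−1..t−p}` and
  `X_{t−1..t−p}`).

Both use the same sample (`t = p .. N−1`) and the maximum-likelihood residual
variance divisor `n_effective = N − p`. Because the regressor sets are nested
on the same sample, `RSS_full ≤ RSS_reduced`, so

```
F_{X→Y} = ln(σ²_reduced / σ²_full) ≥ 0
```

holds exactly, not just asymptotically. `F` is in nats and is invariant to
adding constants to, or positively rescaling, either series. Under the
one-lag coupling model `Y_t = c·X_{t−1} + e_t` with white unit-variance `X`
and `e`, `F → ln(1 + c²)`; the test suite verifies this within 5% at
N = 20000 for c ∈ {0.5, 1, 2}. On independent series `F` has a small-sample
bias of order `p/N`, decreasing in `N` (also tested).

Degenerate inputs — affinely identical series (sample correlation 1 within
1e−10) or a rank-deficient design — return `F = 0` with a `degenerate` flag
instead of raising: two identical time series carry no incremental predictive
information about each other.

**Order selection.** Per trial, `p` minimises
`AIC(p) = ln det(Σ̂_p) + 2·p·n²/n_effective` over `p ∈ {1..p_max}` for an
n-variate fit, with ties broken toward smaller `p`. The default `p_max` is 20
(2.5 s of history at 8 Hz), comfortably above the 6–9 lags typically selected
for performance envelopes. Per participant and piece, the **maximum** of the
per-trial orders is then used for all trials, so within-participant GC values
are comparable across trials.

**Stationarity.** Each bivariate fit is checked via the companion-matrix
spectral radius (stationary iff < 1 − 1e−6). A failure warns and annotates
the estimate rather than aborting, so that pathological synthetic inputs do
not kill a batch run; the radius is written to the output tables.

Residual variances deliberately use the ML divisor rather than a
degrees-of-freedom correction in both models: a per-model correction would
break the exact `F ≥ 0` guarantee, and at trial lengths of ~720 points the
difference is negligible.

## Cross-correlation

At lag `ℓ ∈ [−L, +L]` (default L = 10 points = 1.25 s), the Pearson
correlation pairs `recording[t]` with `performance[t + ℓ]`: positive `ℓ` means
the recording precedes the performance. Each lag's coefficient is computed on
the overlap region using that region's own means and SDs — no zero-padding —
avoiding artificial attenuation at the window edges. The similarity score is
the maximum signed coefficient (an `absolute` switch maximises |r| instead;
for nonnegative, positively correlated envelopes the two rarely differ), the
synchrony score is the lag-0 coefficient, and exact ties at the maximum break
toward the smallest |ℓ|, then toward positive ℓ. By construction the
similarity score can never fall below the synchrony score.

## Trend inference

Per-trial measures form a long table (participant × trial × measure). Three
analyses:

**Paired direction test.** A one-sample t test on the participant × trial
paired differences `GC(rec→perf) − GC(perf→rec)`, df = n_pairs − 1 (63 for an
8 × 8 design), two-sided.

**Random-intercept mixed model.** `value = β₀ + β·trial + b_participant + ε`
with `b ~ N(0, σ_b²)`, `ε ~ N(0, σ_e²)`, trial numeric 1..J (uncentered).
Fitting is maximum likelihood — not REML — because the full model (with the
trial slope) is compared against the intercept-only reduced model by a
likelihood-ratio test, which is only valid for ML fits. The implementation
profiles the likelihood over the variance ratio λ = σ_b²/σ_e², using the
closed-form inverse `(I + λJ)⁻¹ = I − λ/(1 + n_g λ)·J` per participant block,
reducing each fit to a 1-D bounded optimisation (λ = 0 is checked explicitly
so the boundary solution is exact). The fit agrees with `statsmodels` MixedLM
(ML) to ~1e−4 in log-likelihood on the 8 × 8 design and is fast enough for
the thousand-replicate calibration checks. The LRT statistic
`2(ll_full − ll_reduced)` is referred to χ²(1). ML variance-component
estimates are biased downward by roughly a factor (P−1)/P with P participants;
this is inherent to the ML choice and visible in the parameter-recovery
numbers for σ_b².

**Semi-partial R².** Reported as the proportional reduction in ML residual
variance from the reduced to the full model, `1 − σ²_full/σ²_reduced`,
clipped to [0, 1]. This estimator is exactly 0 when the fitted slope is 0 and
approaches 1 when the trial trend absorbs all within-participant variance.
(Published analyses of this design name the statistic but not its estimator;
several inequivalent definitions exist, so the choice here is pinned by those
two limit properties.)

**Linear trend contrast.** Trial re-enters as an ordered factor; the order-1
orthogonal-polynomial contrast (weights ∝ [−7, −5, … , +7] for 8 levels) is
applied to the trial means and its 1-df sum of squares is tested against the
within-participant residual `SS_total − SS_participant` with
`df = N − P = P(J−1)` — F(1, 56) for 8 × 8, the df convention standard for
this design. That error term still contains the non-linear trial variation,
so the test is conservative when higher-order trends are present.

All tests are two-sided and invariant to adding constants; t and F are
invariant to positive rescaling.

## Synthetic study generator

The generator stands in for undeposited recordings; it produces 8-Hz envelope
pairs directly (an audio-rendering mode synthesizes sine-tone WAV audio from
the same score to integration-test the waveform pipeline).

A **score** is a random sequence of note events (inter-onset intervals of ½,
1 or 2 beats at ~100 bpm, occasional fermata-like stretches), rendered with
linear-attack/exponential-decay shapes, a smooth random tempo warp and a slow
sinusoidal dynamics curve, plus weak multiplicative texture — enough
structure that the recording's envelope is strongly autocorrelated but not
periodic. A 90-s piece gives 720 envelope points.

A **performance** on trial `j` is

```
P_t = w_int(j)·R(t − d_t) + w_react(j)·Σ_{k=1..K} c_k·R_{t−k} + noise,
```

floored at zero (a softplus floor is available behind a flag). `R` is the
fixed recording envelope, identical across trials and participants. The
reactive kernel `c_k` decays exponentially over K = 6 lags (0.75 s),
normalised to sum 1, placing the true lag structure inside the order range
AIC selection recovers. The delay field `d_t ≥ 0` is smooth seeded noise with
scale τ(j): the performer trails the recording, which is what makes optimal
lags nonnegative. Default schedules: `w_react(j)` linear 0.6 → 0.15,
`w_int = 1 − w_react`, τ(j) linear 0.25 s → 0.05 s, noise SD 5% of the
recording's SD. Participants differ by seeded log-normal factors (SD 0.15 on
the log scale) on coupling, delay and noise.

These magnitudes encode the qualitative learning signature — directed flow
from recording to performance that declines over trials, synchrony that
rises, optimal lags that stay nonnegative — not any particular dataset's
values. Two caveats about realism: the internal-model term reads out the true
recording envelope (with timing error only), so it carries *timing*
information the reactive pathway would in reality partly share; and the
generator models neither pitch structure nor amplitude memory errors. Passing
tests therefore show the pipeline recovers a known coupling structure of this
form, not that real performances follow it.

## Problem sizes and numerical choices

The simulation suites use 100 seeds for directional-asymmetry and
learning-trend checks, 1000 replicates for LRT type-I-error calibration and
500 for parameter recovery, with 8 × 8 × 90-s studies throughout — the full
design scale, chosen so one suite run completes in a couple of minutes.
Envelope tie-breaks, degenerate-input behaviour and boundary handling are
described above; all randomness flows through `numpy.random.default_rng`
seeded from a single study or CLI seed, and the analysis path itself is
deterministic (rerun reproducibility is asserted bytewise on the CSV
outputs).

## Limitations

* Pairwise time-domain GC only: no conditional/multivariate, spectral or
  state-space variants, and no per-trial significance tests of individual GC
  values.
* The envelope discards pitch, timbre and articulation; two performances can
  be "similar" here while differing musically.
* The mixed model fits a single linear trial slope with a random intercept;
  random slopes, REML inference and Satterthwaite/Kenward–Roger df are out of
  scope.
* The generator's coupling schedules are stylised; effect sizes from real
  corpora should not be read off the synthetic defaults.
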