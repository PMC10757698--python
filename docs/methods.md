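# Methods

This note documents the models, defaults, and numerical choices behind
`eodassay`, and what the synthetic-data generator does and does not emulate.

## Dominant-frequency tracking

The EOD is tracked window by window from FFT power spectra. Window `k`'s
dominant frequency `f_d,k` is the highest spectral peak inside the adaptive
search band `[0.9, 1.1] × f_d,k−1`, seeded by `f_d,0`, the Welch-spectrum
peak of the baseline phase inside a plausible band (default 500–1200 Hz, and
required to stand ≥ 50× above the in-band median power so noise-only input
raises an error). By construction the track can never jump to a harmonic or
follow a step faster than a factor 1.1 per window; windows without a usable
in-band peak (e.g., the few-second transfer gaps) carry the previous
estimate forward and are flagged rather than aborting the track.

Defaults and rationale:

* **Window 50 ms, step 25 ms.** ~20 Hz raw resolution at 40 kHz; short
  enough that slow frequency drifts are quasi-stationary per window.
* **Hann taper, zero-padding ×4, quadratic interpolation on log power.**
  Sub-bin peak localization (≪ 1 Hz on stationary tones) without longer
  windows; sidelobe suppression near the strong fundamental.
* **Per-window band-pass `[0.4, 1.4] × f_d,k`** realized as a zero-phase
  forward–backward 4th-order Butterworth, preserving transient timing.

The median-frequency series takes one median of the track per 1-min window,
windows placed every 30 s, so a record of integer duration `D` minutes
yields `2(D−1)+1` values (59 for 30 min). All frequencies can be normalized
to 26 °C with a Q10 of 1.56; the coefficient of variation uses the sample
(n−1) standard deviation.

## Chirp detection

Type-2 chirps are ~10–50 ms sech-shaped frequency excursions,
`ΔF · Φ(ξ; α)` with `Φ(ξ; α) = 2e^{αξ}/(1+e^{2αξ}) = sech(αξ)`, peak rises
below 150 Hz (strict; 200–350 Hz rises are type-1 and excluded). An FFT
window comparable to the event duration smears such an excursion — the
windowed spectral peak barely moves for a 10-ms event — so the detector
derives its millisecond-scale frequency trace from the analytic (Hilbert)
phase of the signal band-passed to `[0.4, 1.4] ×` carrier: instantaneous
frequency at the full sampling rate, smoothed over 2 ms, decimated to
0.5-ms steps, computed segment-wise (10 s + 0.5 s pads) to bound memory and
edge effects. This band simultaneously retains anesthesia-induced drops
(≥ 0.55 × baseline) and chirp excursions (≤ baseline + 150 Hz) for
fundamentals in the species' range.

Detection: the local baseline is a running median (0.25-s block medians,
median-smoothed over ±1 s — robust to the chirps themselves); candidates
are runs where the excursion exceeds 20 Hz (well below the smallest modeled
type-2 rise of 30 Hz, well above phase-noise jitter) for ≥ 2 ms. Each
candidate's `ΔF` is its peak excursion; `α` is fitted by bounded 1-D
minimization on `log α` (50–5000 s⁻¹, grid-initialized) of the residual sum
of squares of the `ΔF`-normalized excursion against `Φ`, in a window of
half-width `5/α` (≥ 99% of the shape's mass, iterated once). Events are
accepted as type-2 when `ΔF < 150 Hz` and the fit explains ≥ 0.8 of the
variance — the fraction that separates sech bumps from steps and noise in
synthetic calibration. On synthetic recordings at the default noise level
this yields ≥ 95% sensitivity with ≤ 5% false discoveries
(`tests/test_acceptance.py`).

## Recovery model and amplitude analysis

Median frequencies are normalized by the median of the 30-min baseline
medians, with t = 0 at the fish's return to the home tank. The recovery
model `F(t) = a + ((c−a)t + d·t²)/(b+t)` satisfies `F(0) = a` exactly and
behaves as `c + d·t` for `t ≫ b`. Fits use least squares on pooled
post-treatment points (per-concentration pooling across fish; per-fish
fitting is available), initialized at `a₀ = min(y)`, `c₀ = 1`, `d₀ = 0`
with a multi-start over `b₀ ∈ {1, 0.5, 2, 5}` min. On short scaled runs the
plateau parameters `b, c, d` are weakly identified (the data end long
before the asymptote); `a` and the fitted curve itself remain stable.

The amplitude envelope is the per-window (1 s) peak-to-peak signal range.
Collapse episodes are runs where the envelope stays below 30% of the
baseline envelope median for ≥ 10 s — the published account gives no
numeric threshold ("markedly lower levels"), so the fraction is a
configurable calibration against the generator's 10% collapse floor.

## Statistics

* **Exact sign test.** Ties dropped, `p = min(1, 2·P(Bin(n, ½) ≤ min(n₊,
  n₋)))`. The minimal-n design rule `⌈1 − log₂(α)⌉` gives 8 at α = 0.01:
  the smallest cohort whose all-concordant outcome is significant.
* **Split-plot mixed model.** `Y_ijk = δ0 + δ1·c_i + β_j(i) + δ2·t_k +
  δ12·c_i·t_k + ε_ijk` with concentration as a numeric covariate (µL/L,
  0 = control), random fish-within-treatment intercepts, `t_k = k/2` min.
  Estimated by REML for reported fits and ML for nested comparisons
  (statsmodels `MixedLM`). Zero-residual (noiseless) input degenerates the
  likelihood and falls back to the closed-form least-squares solution with
  both variance components zero, flagged singular.
* **Joint concentration test.** Likelihood-ratio test of
  `δ1 = 0 ∧ δ12 = 0` between ML fits, referred to χ²₂. When the random
  intercept sits exactly at its zero boundary statsmodels cannot invert the
  profile Hessian; both likelihoods are then taken from the σβ = 0 limit of
  the model (ordinary least squares), keeping the comparison symmetric.
  Monte-Carlo calibration at the window size used by the recovery-time
  scan (1000 null simulations) puts the type-I rate at nominal 0.01 inside
  [0.004, 0.02].
* **Recovery time.** For `q = 0 … 345` the model is refitted on
  `k ∈ {q+1, …, q+15}` and the joint test computed; the r-th tested
  window's p-value is Bonferroni-multiplied by `r` (the windows examined so
  far — the sequential reading of the published procedure; a fixed
  correction by the total window count is available behind a flag).
  `t_r` is the start time `(q+1)/2` min of the first non-rejected window,
  so identical groups recover at `t_r = 0.5` min. Non-convergent windows
  are skipped with a warning and do not enter the correction count.

## Synthetic-data generator

The generator reproduces the study design: 8 fish with baseline frequencies
drawn once from 650–1000 Hz and reused across conditions, conditions
{0, 30, 45, 60} µL/L in randomized order per fish (randomized complete
block), 30-min baseline / 5-min immersion / 180-min post phases.

* **Baseline jitter** is a mean-reverting Ornstein–Uhlenbeck process,
  parameterized by stationary sd (default 3.0 Hz) and correlation time
  (default 20 s). These values were calibrated once, by simulation across
  the f0 range, so that the cv of the 59 baseline medians falls inside the
  0.12–0.59% band reported for real fish for essentially every seed
  (observed span 0.13–0.47% over 1000 draws); they were then frozen.
* **Dose response.** During immersion the frequency declines along a
  smooth cosine ramp (after a 1-min latency, matching the observed 1–2 min
  onset), reaching exactly `a·f0` at the end of the phase; the post phase
  follows `f0·F(t)` with the published per-concentration recovery
  parameters, so generated and analyzed trajectories share one model.
  Controls stay flat apart from jitter.
* **Chirps** are Poisson-timed additive `ΔF·Φ` excursions (with
  multiplicative amplitude dips), truncated where `Φ < 0.01`
  (|ξ| ≈ 5.3/α); overlapping draws are re-drawn. Default rates: 0.05/min
  throughout, boosted for the 30 min after return by +3.25/+4.57/+5.33
  events/min at 30/45/60 µL/L — the published median per-fish increases
  divided by the 30-min window. `ΔF ∈ [30, 150] Hz`; `α ∈ [200, 1500] s⁻¹`
  (~10–50 ms events) is a modeling choice, since the source method's range
  is not restated in the assay description.
* **Waveform.** `A(t) · Σ_h w_h sin(2π h θ(t)) + N(0, 0.05)` with
  `θ = ∫f dτ` accumulated exactly across synthesis chunks; default 3
  harmonics with weights (1, 0.3, 0.1) to exercise the tracker's band
  logic, 40 kHz sampling (the acquisition rate is not stated in the study;
  40 kHz is ≥ 4× the highest modeled harmonic), rejected if the rate
  falls below 4× the highest harmonic of the peak instantaneous frequency.
* **Amplitude.** Multiplicative lognormal-OU movement jitter (attenuated
  during anesthesia, when the fish stops moving); at 60 µL/L half of the
  trials (Bernoulli) collapse to a 10% floor starting 3.5 min after onset
  (30-s sigmoidal fall) and recover linearly over 6 min after return.
  The two transfer amplitude surges are available but off by default.

Everything derives from `numpy` `SeedSequence` spawning, so identical
(config, seed) regenerate bit-identical datasets; waveforms are rendered
on demand from per-trial seeds to keep datasets compact.

**What the generator does not emulate:** multiple fish per electrode pair,
electrode motion beyond multiplicative jitter, non-stationary noise floors,
type-1 chirps, gradual frequency rises or discharge interruptions, and any
pharmacological mechanism. Passing tests therefore demonstrate that the
computation recovers the structure this generator produces — dose-dependent
drops with known recovery shapes, sech chirps in Gaussian noise — not that
it is robust to every artifact of real recordings.

## Problem sizes used in tests

The test suite runs the full design at reduced scale as its own choice of
economical defaults: minutes-long phases, single-harmonic carriers at
6–20 kHz where the band logic is not under test, 5-seed Monte-Carlo
envelopes for the recovery-time scan, and 1000 window-sized simulations for
null calibration. The acceptance script uses the full default configuration
(40 kHz, 3 harmonics, 30-min baselines, 8 fish).

## Known limitations

* The windowed-FFT track reports a carried-forward value during no-peak
  windows; long silent gaps therefore flatten rather than break the track.
* The sequential-Bonferroni reading of the recovery-time correction is one
  of two defensible interpretations of the published wording; the other
  (fixed total-count correction) is available via `correction="fixed"`.
* `b`, `c`, `d` of the recovery model are only identified when the data
  span several multiples of `b` and approach the plateau.
* The joint test's χ²₂ reference is asymptotic; at the window sizes used
  here its measured type-I rate is ~1.4% at nominal 1%, within the
  documented calibration band but slightly liberal.
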