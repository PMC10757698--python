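"""Detection, shape fitting, and classification of type-2 chirps.

Chirps are millisecond-scale transient rises of the EOD frequency
(accompanied by an amplitude dip).  Normalized by its peak rise, a chirp's
frequency excursion follows the single-parameter shape

    Phi(xi; alpha) = 2 e^{alpha xi} / (1 + e^{2 alpha xi}) = sech(alpha xi)

where xi is time from the peak and alpha (1/s) sets the event width.
Type-2 chirps are defined by peak frequency rises below 150 Hz; larger
events (type-1 chirps rise by 200-350 Hz) are excluded.

Because chirps last only ~10-50 ms, the detector does not rely on the slow
windowed-FFT track.  It derives a millisecond-scale instantaneous-frequency
trace from the analytic (Hilbert) phase of the signal band-passed to
[0.4, 1.4] x carrier — the same band the tracker uses — then finds
excursions above a running-median local baseline, fits Phi to each
candidate, and classifies the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.optimize import minimize_scalar
from scipy.signal import butter, hilbert, sosfiltfilt


def phi(xi, alpha):
    """Normalized chirp shape Phi(xi; alpha) = 2 e^{a xi} / (1 + e^{2 a xi}).

    Identical to sech(alpha*xi); evaluated in an overflow-free form so large
    |alpha*xi| underflows smoothly to 0.  Phi(0) = 1 and Phi is even in xi.
    """
    z = np.abs(np.asarray(alpha, dtype=float) * np.asarray(xi, dtype=float))
    out = 2.0 * np.exp(-z) / (1.0 + np.exp(-2.0 * z))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ChirpDetectConfig:
    """Tunables of the chirp detector.

    ``onset_threshold_hz`` (20 Hz) sits well below the smallest modeled
    type-2 rise (30 Hz) and well above tracker/phase jitter; candidates must
    stay above it for ``min_duration_s``.  The fit window half-width is
    ``fit_halfwidth_factor``/alpha, covering >= 99% of the shape's mass.
    """

    band_factors: tuple[float, float] = (0.4, 1.4)
    trace_step_s: float = 0.0005
    smooth_s: float = 0.002
    baseline_block_s: float = 0.25
    baseline_span_s: float = 2.0
    onset_threshold_hz: float = 20.0
    min_duration_s: float = 0.002
    fit_halfwidth_factor: float = 5.0
    alpha_bounds: tuple[float, float] = (50.0, 5000.0)
    goodness_threshold: float = 0.8
    type2_max_rise_hz: float = 150.0
    segment_s: float = 10.0
    segment_pad_s: float = 0.5


@dataclass(frozen=True)
class ChirpEvent:
    """A fitted frequency excursion."""

    peak_time_s: float
    delta_f_hz: float
    alpha_per_s: float
    goodness: float
    cls: str  # "type2" | "excluded"


@dataclass(frozen=True)
class FrequencyTrace:
    """Millisecond-scale instantaneous-frequency trace."""

    times_s: np.ndarray
    freqs_hz: np.ndarray
    step_s: float


def frequency_trace(samples, rate_hz: float, carrier_hz: float,
                    config: ChirpDetectConfig | None = None) -> FrequencyTrace:
    """Instantaneous frequency from the analytic phase of the band-passed EOD.

    The signal is band-passed to ``band_factors x carrier_hz`` (which retains
    both anesthesia-induced drops and chirp excursions for fundamentals in
    the species' range), Hilbert-transformed segment by segment with
    overlapping pads to suppress edge effects, differentiated in phase,
    lightly smoothed, and decimated to ``trace_step_s``.
    """
    if config is None:
        config = ChirpDetectConfig()
    x = np.asarray(samples, dtype=float)
    if not carrier_hz > 0:
        raise ValueError("carrier frequency must be positive")
    lo = config.band_factors[0] * carrier_hz
    hi = min(config.band_factors[1] * carrier_hz, 0.99 * rate_hz / 2)
    if not 0 < lo < hi:
        raise ValueError("invalid analysis band")
    sos = butter(4, [lo, hi], btype="bandpass", fs=rate_hz, output="sos")

    seg = max(int(config.segment_s * rate_hz), 1)
    pad = int(config.segment_pad_s * rate_hz)
    dec = max(int(round(config.trace_step_s * rate_hz)), 1)
    smooth = max(int(round(config.smooth_s * rate_hz)), 1)

    pieces_t, pieces_f = [], []
    for start in range(0, x.size, seg):
        stop = min(start + seg, x.size)
        a = max(start - pad, 0)
        b = min(stop + pad, x.size)
        if b - a < 16:
            break
        filt = sosfiltfilt(sos, x[a:b])
        phase = np.unwrap(np.angle(hilbert(filt)))
        inst = np.gradient(phase) * rate_hz / (2 * np.pi)
        inst = uniform_filter1d(inst, size=smooth)
        i0, i1 = start - a, start - a + (stop - start)
        idx = np.arange(i0, i1, dec)
        pieces_t.append((a + idx) / rate_hz)
        pieces_f.append(inst[idx])
    times = np.concatenate(pieces_t)
    freqs = np.concatenate(pieces_f)
    return FrequencyTrace(times_s=times, freqs_hz=freqs, step_s=dec / rate_hz)


def local_baseline(trace: FrequencyTrace, config: ChirpDetectConfig | None = None) -> np.ndarray:
    """Running-median local baseline of the trace.

    Block medians over ``baseline_block_s`` blocks, then a running median of
    blocks over ``baseline_span_s``, interpolated back to the trace grid.
    Block medians are robust to the short chirps themselves, so no explicit
    exclusion of candidate support is needed.
    """
    if config is None:
        config = ChirpDetectConfig()
    block = max(int(round(config.baseline_block_s / trace.step_s)), 1)
    n_blocks = max(trace.freqs_hz.size // block, 1)
    usable = trace.freqs_hz[: n_blocks * block].reshape(n_blocks, block)
    block_meds = np.median(usable, axis=1)
    block_times = trace.times_s[: n_blocks * block].reshape(n_blocks, block).mean(axis=1)
    half = max(int(round(config.baseline_span_s / (2 * config.baseline_block_s))), 1)
    smoothed = np.array([
        np.median(block_meds[max(i - half, 0): i + half + 1])
        for i in range(n_blocks)
    ])
    return np.interp(trace.times_s, block_times, smoothed)


@dataclass(frozen=True)
class Candidate:
    peak_index: int
    peak_time_s: float
    peak_excess_hz: float


def detect_candidates(trace: FrequencyTrace, baseline_hz,
                      config: ChirpDetectConfig | None = None) -> list[Candidate]:
    """Contiguous excursions above the local baseline.

    A candidate is a run where ``trace - baseline`` exceeds the onset
    threshold for at least ``min_duration_s``; its peak is the run's maximum.
    """
    if config is None:
        config = ChirpDetectConfig()
    excess = trace.freqs_hz - np.asarray(baseline_hz, dtype=float)
    above = excess > config.onset_threshold_hz
    edges = np.flatnonzero(np.diff(np.concatenate(([False], above, [False]))))
    min_len = max(int(round(config.min_duration_s / trace.step_s)), 2)
    candidates = []
    for start, stop in edges.reshape(-1, 2):
        if stop - start < min_len:
            continue
        i = start + int(np.argmax(excess[start:stop]))
        candidates.append(Candidate(peak_index=i,
                                    peak_time_s=float(trace.times_s[i]),
                                    peak_excess_hz=float(excess[i])))
    return candidates


def fit_chirp(trace: FrequencyTrace, baseline_hz, candidate: Candidate,
              config: ChirpDetectConfig | None = None) -> ChirpEvent:
    """Fit the normalized shape Phi(xi; alpha) to one candidate excursion.

    delta_f is the peak excursion above the local baseline; alpha is found by
    bounded 1-D minimization on log(alpha) of the residual sum of squares of
    the delta_f-normalized excursion against Phi, initialized by a coarse
    grid.  The fit window half-width is ``fit_halfwidth_factor / alpha``,
    iterated once from the grid estimate.  Goodness is the fraction of
    variance explained; degenerate candidates come back flagged as excluded
    with goodness NaN.
    """
    if config is None:
        config = ChirpDetectConfig()
    excess = trace.freqs_hz - np.asarray(baseline_hz, dtype=float)
    delta_f = excess[candidate.peak_index]
    if not delta_f > 0:
        return ChirpEvent(candidate.peak_time_s, float(delta_f), np.nan, np.nan, "excluded")
    lo_a, hi_a = config.alpha_bounds

    def window(alpha: float) -> tuple[np.ndarray, np.ndarray]:
        half = config.fit_halfwidth_factor / alpha
        n = max(int(round(half / trace.step_s)), 2)
        a = max(candidate.peak_index - n, 0)
        b = min(candidate.peak_index + n + 1, trace.freqs_hz.size)
        xi = trace.times_s[a:b] - candidate.peak_time_s
        return xi, excess[a:b] / delta_f

    def sse(log_alpha: float, xi: np.ndarray, y: np.ndarray) -> float:
        return float(np.sum((y - phi(xi, np.exp(log_alpha))) ** 2))

    grid = np.linspace(np.log(lo_a), np.log(hi_a), 25)
    xi0, y0 = window(float(np.exp(grid[len(grid) // 2])))
    alpha0 = float(np.exp(grid[np.argmin([sse(g, xi0, y0) for g in grid])]))
    xi, y = window(alpha0)
    if xi.size < 5:
        return ChirpEvent(candidate.peak_time_s, float(delta_f), np.nan, np.nan, "excluded")
    res = minimize_scalar(sse, bounds=(np.log(lo_a), np.log(hi_a)),
                          args=(xi, y), method="bounded")
    if not res.success:
        return ChirpEvent(candidate.peak_time_s, float(delta_f), np.nan, np.nan, "excluded")
    alpha = float(np.exp(res.x))
    ss_res = sse(res.x, xi, y)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    goodness = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    cls = classify_chirp(float(delta_f), goodness, config)
    return ChirpEvent(candidate.peak_time_s, float(delta_f), alpha, goodness, cls)


def classify_chirp(delta_f_hz: float, goodness: float,
                   config: ChirpDetectConfig | None = None) -> str:
    """type2 iff the peak rise is strictly below 150 Hz and the fit is good."""
    if config is None:
        config = ChirpDetectConfig()
    ok = (delta_f_hz < config.type2_max_rise_hz
          and np.isfinite(goodness)
          and goodness >= config.goodness_threshold)
    return "type2" if ok else "excluded"


def detect_chirps(samples, rate_hz: float, carrier_hz: float,
                  config: ChirpDetectConfig | None = None,
                  start_s: float = 0.0) -> list[ChirpEvent]:
    """Full chirp pipeline: trace -> candidates -> shape fits -> classes.

    ``start_s`` offsets all event times (recording start on the experiment
    clock), making detection translation-equivariant.
    """
    if config is None:
        config = ChirpDetectConfig()
    trace = frequency_trace(samples, rate_hz, carrier_hz, config)
    base = local_baseline(trace, config)
    events = []
    for cand in detect_candidates(trace, base, config):
        ev = fit_chirp(trace, base, cand, config)
        events.append(ChirpEvent(ev.peak_time_s + start_s, ev.delta_f_hz,
                                 ev.alpha_per_s, ev.goodness, ev.cls))
    return events


@dataclass(frozen=True)
class ChirpRateSummary:
    """Type-2 chirp counts and per-minute rates per labeled interval."""

    counts: dict[str, int]
    rates_per_min: dict[str, float]
    intervals_s: dict[str, tuple[float, float]]


def chirp_rate_summary(events: list[ChirpEvent],
                       treatment_onset_s: float, return_s: float,
                       duration_s: float,
                       pre_window_s: float = 1800.0,
                       post_window_s: float = 1800.0) -> ChirpRateSummary:
    """Count type-2 chirps in the pre/treatment/post/remainder intervals.

    ``pre`` is the ``pre_window_s`` immediately before treatment onset and
    ``post`` the ``post_window_s`` immediately after the fish's return —
    the two windows compared by the chirp-rate statistics.
    """
    if treatment_onset_s - pre_window_s < -1e-9:
        raise ValueError("pre window starts before the recording")
    if return_s + post_window_s > duration_s + 1e-9:
        raise ValueError("post window extends beyond the recording")
    intervals = {
        "pre": (treatment_onset_s - pre_window_s, treatment_onset_s),
        "treatment": (treatment_onset_s, return_s),
        "post": (return_s, return_s + post_window_s),
        "remainder": (return_s + post_window_s, duration_s),
    }
    counts, rates = {}, {}
    times = np.array([e.peak_time_s for e in events if e.cls == "type2"])
    for name, (lo, hi) in intervals.items():
        n = int(np.sum((times >= lo) & (times < hi))) if times.size else 0
        counts[name] = n
        rates[name] = n / ((hi - lo) / 60.0) if hi > lo else 0.0
    return ChirpRateSummary(counts=counts, rates_per_min=rates, intervals_s=intervals)
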