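"""Window-by-window dominant-frequency tracking of an EOD recording.

The electric organ discharge of *Apteronotus leptorhynchus* is a
quasi-sinusoidal carrier at ~650-1000 Hz whose frequency moves slowly
(baseline jitter, anesthesia-induced drops) apart from millisecond-scale
chirps.  The tracker estimates the dominant frequency f_d,k of successive
short windows from the FFT power spectrum, restricting the spectral peak
search of window k to [0.9, 1.1] x f_d,k-1 — the previous window's estimate —
so the track cannot jump to harmonics or interference.  Each window can then
be band-pass filtered to [0.4, 1.4] x f_d,k for downstream chirp analysis.

On top of the raw track the module derives the 30-s-cadence median-frequency
series (1-min windows), Q10 temperature adjustment to a 26 degC reference,
and the coefficient of variation used to report baseline stability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import next_fast_len, rfft, rfftfreq
from scipy.signal import butter, sosfiltfilt, welch


class NoPeakError(ValueError):
    """No usable spectral peak inside the requested band."""


@dataclass(frozen=True)
class TrackConfig:
    """Configuration of the adaptive dominant-frequency tracker.

    The 50 ms window / 25 ms step defaults give ~20 Hz raw spectral
    resolution, refined well below 1 Hz by zero-padding (factor 4) and
    quadratic peak interpolation on a Hann-tapered spectrum.
    """

    window_s: float = 0.05
    step_s: float = 0.025
    search_band: tuple[float, float] = (0.9, 1.1)
    filter_band: tuple[float, float] = (0.4, 1.4)
    interpolate: bool = True
    pad_factor: int = 4
    baseline_band_hz: tuple[float, float] = (500.0, 1200.0)

    def __post_init__(self) -> None:
        if not 0 < self.step_s <= self.window_s:
            raise ValueError("require 0 < step <= window")
        for name in ("search_band", "filter_band"):
            lo, hi = getattr(self, name)
            if not 0 < lo < hi:
                raise ValueError(f"{name} factors must satisfy 0 < low < high")
        if self.pad_factor < 1:
            raise ValueError("pad_factor must be >= 1")


@dataclass(frozen=True)
class FrequencyTrack:
    """Dominant-frequency estimates f_d,k at window centers.

    ``flags`` marks windows where no in-band peak was found and the previous
    estimate was carried forward.
    """

    times_s: np.ndarray
    freqs_hz: np.ndarray
    flags: np.ndarray
    f_d0: float
    duration_s: float
    config: TrackConfig = field(default_factory=TrackConfig)

    def check_band_invariant(self) -> bool:
        """Every f_d,k must lie inside search_band x f_d,k-1."""
        lo, hi = self.config.search_band
        prev = np.concatenate(([self.f_d0], self.freqs_hz[:-1]))
        eps = 1e-9
        return bool(np.all((self.freqs_hz >= lo * prev - eps)
                           & (self.freqs_hz <= hi * prev + eps)))


def _quadratic_peak(power: np.ndarray, idx: int, freqs: np.ndarray) -> float:
    """Sub-bin peak location by parabolic interpolation on log power."""
    if idx <= 0 or idx >= power.size - 1:
        return float(freqs[idx])
    y0, y1, y2 = np.log(power[idx - 1 : idx + 2] + 1e-300)
    denom = y0 - 2 * y1 + y2
    if denom >= 0:
        return float(freqs[idx])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    return float(freqs[idx] + delta * (freqs[1] - freqs[0]))


def _peak_in_band(power: np.ndarray, freqs: np.ndarray,
                  band_hz: tuple[float, float], interpolate: bool) -> float:
    lo, hi = band_hz
    sel = np.flatnonzero((freqs >= lo) & (freqs <= hi))
    if sel.size < 3:
        raise NoPeakError(f"band [{lo:.1f}, {hi:.1f}] Hz too narrow for spectrum")
    i = sel[np.argmax(power[sel])]
    # require a genuine local maximum of the full spectrum
    if i <= 0 or i >= power.size - 1 or power[i] < power[i - 1] or power[i] < power[i + 1]:
        interior = sel[(sel > 0) & (sel < power.size - 1)]
        is_max = (power[interior] >= power[interior - 1]) & (power[interior] >= power[interior + 1])
        interior = interior[is_max]
        if interior.size == 0:
            raise NoPeakError(f"no local spectral maximum in [{lo:.1f}, {hi:.1f}] Hz")
        i = interior[np.argmax(power[interior])]
    f = _quadratic_peak(power, int(i), freqs) if interpolate else float(freqs[i])
    return float(np.clip(f, lo, hi))


def dominant_frequency(samples, rate_hz: float, band_hz: tuple[float, float],
                       pad_factor: int = 4, interpolate: bool = True) -> float:
    """Frequency of the highest spectral peak of ``samples`` inside ``band_hz``.

    The window is Hann-tapered and zero-padded (``pad_factor``) before the
    FFT; the peak is refined by quadratic interpolation on log power.
    Raises :class:`NoPeakError` when the band holds no local maximum.
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty window")
    if band_hz[1] > rate_hz / 2:
        raise ValueError("band extends beyond Nyquist")
    n = next_fast_len(int(x.size * pad_factor))
    spec = rfft(x * np.hanning(x.size), n=n)
    power = np.abs(spec) ** 2
    freqs = rfftfreq(n, 1.0 / rate_hz)
    return _peak_in_band(power, freqs, band_hz, interpolate)


def baseline_dominant_frequency(samples, rate_hz: float,
                                band_hz: tuple[float, float] = (500.0, 1200.0),
                                min_peak_snr: float = 50.0) -> float:
    """Initial dominant frequency f_d,0 from the baseline recording.

    Uses a Welch spectrum of the baseline segment and requires the in-band
    peak to stand at least ``min_peak_snr`` times above the in-band median
    power, so near-silent or noise-only baselines raise :class:`NoPeakError`.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 16:
        raise NoPeakError("baseline segment too short")
    nperseg = min(int(2**14), x.size)
    freqs, power = welch(x, fs=rate_hz, nperseg=nperseg)
    sel = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    if not np.any(sel):
        raise NoPeakError("baseline search band empty")
    med = np.median(power[sel])
    if med <= 0 or power[sel].max() < min_peak_snr * med:
        raise NoPeakError("no dominant spectral peak above the noise floor")
    return _peak_in_band(power, freqs, band_hz, interpolate=True)


def track_frequency(samples, rate_hz: float, f_d0: float,
                    config: TrackConfig | None = None,
                    chunk_windows: int = 4096) -> FrequencyTrack:
    """Adaptive dominant-frequency track of a full recording.

    For each window k the spectral peak is searched inside
    ``search_band x f_d,k-1``; windows without a usable peak carry the
    previous estimate forward and are flagged.  Spectra are computed in
    batches of ``chunk_windows`` windows; the band-restricted peak pick is
    sequential because the band depends on the previous estimate.
    """
    if config is None:
        config = TrackConfig()
    if not f_d0 > 0:
        raise ValueError("f_d0 must be positive")
    x = np.asarray(samples, dtype=np.float64)
    w = int(round(config.window_s * rate_hz))
    step = int(round(config.step_s * rate_hz))
    if x.size < w:
        raise ValueError("recording shorter than one analysis window")
    n_win = 1 + (x.size - w) // step
    nfft = next_fast_len(w * config.pad_factor)
    freqs = rfftfreq(nfft, 1.0 / rate_hz)
    taper = np.hanning(w)

    out = np.empty(n_win)
    flags = np.zeros(n_win, dtype=bool)
    prev = float(f_d0)
    lo_f, hi_f = config.search_band
    for start in range(0, n_win, chunk_windows):
        stop = min(start + chunk_windows, n_win)
        idx = np.arange(start, stop)[:, None] * step + np.arange(w)[None, :]
        frames = x[idx] * taper
        power = np.abs(rfft(frames, n=nfft, axis=1)) ** 2
        for j, k in enumerate(range(start, stop)):
            try:
                prev = _peak_in_band(power[j], freqs, (lo_f * prev, hi_f * prev),
                                     config.interpolate)
            except NoPeakError:
                flags[k] = True  # carry previous estimate forward
            out[k] = prev
    times = (np.arange(n_win) * step + w / 2) / rate_hz
    return FrequencyTrack(times_s=times, freqs_hz=out, flags=flags,
                          f_d0=float(f_d0), duration_s=x.size / rate_hz,
                          config=config)


def bandpass_window(samples, rate_hz: float, f_center_hz: float,
                    band_factors: tuple[float, float] = (0.4, 1.4),
                    order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass to ``band_factors x f_center_hz``.

    Forward-backward filtering preserves the timing of transient events
    (chirps) inside the window.
    """
    lo = band_factors[0] * f_center_hz
    hi = min(band_factors[1] * f_center_hz, 0.99 * rate_hz / 2)
    if not 0 < lo < hi:
        raise ValueError("invalid band")
    sos = butter(order, [lo, hi], btype="bandpass", fs=rate_hz, output="sos")
    return sosfiltfilt(sos, np.asarray(samples, dtype=float))


@dataclass(frozen=True)
class MedianSeries:
    """Median frequency per 1-min window, sampled every 30 s.

    A record of integer duration D minutes yields 2*(D-1)+1 values.  Sample
    times are window centers on the recording clock.
    """

    times_s: np.ndarray
    medians_hz: np.ndarray
    interval_s: float
    window_s: float


def median_frequency_series(track: FrequencyTrack, interval_s: float = 30.0,
                            window_s: float = 60.0) -> MedianSeries:
    """Sampled median-frequency series derived from a track.

    One median of the track values inside each ``window_s`` window, windows
    placed every ``interval_s`` from the start of the recording.
    """
    duration = track.duration_s
    if duration < window_s - 1e-9:
        raise ValueError("track shorter than one median window")
    n_vals = int(np.floor((duration - window_s) / interval_s + 1e-9)) + 1
    times = np.empty(n_vals)
    medians = np.empty(n_vals)
    for i in range(n_vals):
        t0 = i * interval_s
        sel = (track.times_s >= t0) & (track.times_s < t0 + window_s)
        if not np.any(sel):
            raise ValueError(f"median window at {t0:.1f}s holds no track samples")
        times[i] = t0 + window_s / 2
        medians[i] = np.median(track.freqs_hz[sel])
    return MedianSeries(times_s=times, medians_hz=medians,
                        interval_s=interval_s, window_s=window_s)


def adjust_temperature(freq_hz, temp_c, ref_c: float = 26.0, q10: float = 1.56,
                       valid_range_c: tuple[float, float] = (20.0, 35.0)):
    """Normalize EOD frequency to a reference temperature with a Q10 law.

    f_ref = f * Q10 ** ((ref_c - temp_c) / 10).  Temperatures outside the
    physiological ``valid_range_c`` are rejected.
    """
    temp = np.asarray(temp_c, dtype=float)
    if np.any(temp < valid_range_c[0]) or np.any(temp > valid_range_c[1]):
        raise ValueError(f"temperature outside physiological range {valid_range_c}")
    out = np.asarray(freq_hz, dtype=float) * q10 ** ((ref_c - temp) / 10.0)
    return out if out.ndim else float(out)


def coefficient_of_variation(values) -> float:
    """cv = 100 * sd / mean (percent), sd with the sample (n-1) denominator."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("cv requires at least two values")
    mean = x.mean()
    if mean == 0:
        raise ValueError("cv undefined for zero mean")
    return float(100.0 * x.std(ddof=1) / mean)
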