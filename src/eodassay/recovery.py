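"""Baseline normalization, recovery-curve fitting, and amplitude-envelope analysis.

After a fish is returned from the anesthetic bath, its electric organ
discharge (EOD) frequency climbs back toward baseline.  Normalized to the
pre-treatment baseline median, the trajectory is well described by the
four-parameter rational model

    F(t) = a + ((c - a) * t + d * t**2) / (b + t)

with ``t`` in minutes from the return to the home tank.  ``a`` is the
normalized frequency at t = 0 (F(0) = a exactly), ``b`` sets the recovery
time scale, ``c`` is the near-asymptotic plateau, and ``d`` a slow linear
drift at large ``t``.

The module also computes maximum frequency drops and the peak-to-peak
amplitude envelope, including detection of amplitude-collapse episodes seen
at high anesthetic concentration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit


@dataclass(frozen=True)
class RecoveryModelParams:
    """Parameters of the recovery model F(t) = a + ((c-a)t + d t^2)/(b + t).

    a : dimensionless normalized frequency at t=0
    b : minutes; recovery time scale (must be > 0)
    c : dimensionless plateau level
    d : 1/min; slow late drift
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if not self.b > 0:
            raise ValueError(f"recovery time-scale b must be > 0, got {self.b}")

    def __call__(self, t):
        return evaluate_recovery_model(self, t)


#: Published nonlinear-regression parameters of the eugenol recovery curves,
#: keyed by concentration in µL/L.  Used as the synthetic generator's default
#: dose–response shapes.
REFERENCE_RECOVERY_PARAMS: dict[float, RecoveryModelParams] = {
    30.0: RecoveryModelParams(a=0.7465, b=1.4568, c=1.0089, d=-3.2299e-5),
    45.0: RecoveryModelParams(a=0.6344, b=1.4064, c=1.0084, d=-3.3821e-5),
    60.0: RecoveryModelParams(a=0.5649, b=1.5816, c=1.0131, d=-6.2321e-5),
}


def evaluate_recovery_model(params: RecoveryModelParams, t):
    """Evaluate F(t) = a + ((c-a)t + d t^2)/(b+t) for t >= 0 (minutes)."""
    t = np.asarray(t, dtype=float)
    out = params.a + ((params.c - params.a) * t + params.d * t**2) / (params.b + t)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class NormalizedSeries:
    """Frequency series normalized to the baseline median.

    ``t_min`` is measured in minutes with t = 0 at the return of the fish to
    its home tank; ``values`` are dimensionless (baseline ~ 1).
    """

    t_min: np.ndarray
    values: np.ndarray
    baseline_median_hz: float

    def __post_init__(self) -> None:
        t = np.asarray(self.t_min, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape:
            raise ValueError("t_min and values must have matching shapes")
        if np.any(np.diff(t) <= 0):
            raise ValueError("t_min must be strictly increasing")
        if not self.baseline_median_hz > 0:
            raise ValueError("baseline median must be positive")
        object.__setattr__(self, "t_min", t)
        object.__setattr__(self, "values", v)

    @property
    def post(self) -> "NormalizedSeries":
        """Restrict to t >= 0 (post-treatment points used for model fitting)."""
        keep = self.t_min >= 0
        return NormalizedSeries(self.t_min[keep], self.values[keep],
                                self.baseline_median_hz)


def normalize_frequency(times_s, freqs_hz, baseline_window_s, t_zero_s) -> NormalizedSeries:
    """Normalize a median-frequency series to its baseline median.

    Parameters
    ----------
    times_s, freqs_hz
        Sample times (s, recording clock) and median frequencies (Hz).
    baseline_window_s
        ``(start_s, end_s)`` of the baseline interval; the normalizer is the
        median of the values whose times fall inside it.
    t_zero_s
        Recording time (s) of the fish's return to the home tank; mapped to
        t = 0 min in the output.
    """
    times_s = np.asarray(times_s, dtype=float)
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    lo, hi = baseline_window_s
    in_base = (times_s >= lo) & (times_s < hi)
    if not np.any(in_base):
        raise ValueError("baseline window contains no samples")
    base_median = float(np.median(freqs_hz[in_base]))
    if base_median <= 0:
        raise ValueError("baseline median must be positive")
    return NormalizedSeries(
        t_min=(times_s - t_zero_s) / 60.0,
        values=freqs_hz / base_median,
        baseline_median_hz=base_median,
    )


@dataclass(frozen=True)
class RecoveryFit:
    params: RecoveryModelParams
    rmse: float
    n_points: int
    b0_used: float


def fit_recovery_model(t_min, values, b0_grid=(1.0, 0.5, 2.0, 5.0),
                       max_nfev: int = 20000) -> RecoveryFit:
    """Least-squares fit of the recovery model to pooled normalized points.

    Initialization: a0 = min(values), c0 = 1, d0 = 0, with a multi-start over
    the time-scale guess b0 when a start fails to converge.  Points with
    t < 0 are ignored (the model is defined on the post-treatment axis).
    """
    t = np.asarray(t_min, dtype=float)
    y = np.asarray(values, dtype=float)
    keep = t >= 0
    t, y = t[keep], y[keep]
    if t.size < 8:
        raise ValueError(f"need >= 8 post-treatment points to fit, got {t.size}")

    def model(tt, a, b, c, d):
        return a + ((c - a) * tt + d * tt**2) / (b + tt)

    a0 = float(np.min(y))
    errors = []
    for b0 in b0_grid:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    model, t, y, p0=[a0, b0, 1.0, 0.0],
                    bounds=([-np.inf, 1e-9, -np.inf, -np.inf],
                            [np.inf, np.inf, np.inf, np.inf]),
                    max_nfev=max_nfev,
                )
        except (RuntimeError, ValueError) as exc:  # non-convergence for this start
            errors.append(f"b0={b0}: {exc}")
            continue
        resid = y - model(t, *popt)
        params = RecoveryModelParams(*[float(p) for p in popt])
        return RecoveryFit(params=params, rmse=float(np.sqrt(np.mean(resid**2))),
                           n_points=int(t.size), b0_used=float(b0))
    raise RuntimeError(
        "recovery-model fit failed for all starts: " + "; ".join(errors))


def max_frequency_drop(freqs_hz, baseline_median_hz: float) -> tuple[float, float]:
    """Maximum drop below baseline: (drop in Hz, drop normalized to baseline).

    drop = baseline median - min(series); the normalized drop divides by the
    baseline median.
    """
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    if freqs_hz.size == 0:
        raise ValueError("empty frequency series")
    if not baseline_median_hz > 0:
        raise ValueError("baseline median must be positive")
    drop = float(baseline_median_hz - np.min(freqs_hz))
    return drop, drop / baseline_median_hz


@dataclass(frozen=True)
class AmplitudeEnvelope:
    """Peak-to-peak amplitude per analysis window."""

    times_s: np.ndarray
    p2p: np.ndarray
    window_s: float

    def baseline_median(self, baseline_window_s) -> float:
        lo, hi = baseline_window_s
        sel = (self.times_s >= lo) & (self.times_s < hi)
        if not np.any(sel):
            raise ValueError("baseline window contains no envelope samples")
        return float(np.median(self.p2p[sel]))


def amplitude_envelope(samples, rate_hz: float, window_s: float = 1.0) -> AmplitudeEnvelope:
    """Per-window max - min of the raw signal (the classic p2p envelope)."""
    x = np.asarray(samples)
    w = int(round(window_s * rate_hz))
    if w < 2:
        raise ValueError("envelope window must span several samples")
    n_win = x.size // w
    if n_win == 0:
        raise ValueError("signal shorter than one envelope window")
    frames = x[: n_win * w].reshape(n_win, w)
    p2p = frames.max(axis=1).astype(float) - frames.min(axis=1).astype(float)
    times = (np.arange(n_win) + 0.5) * w / rate_hz
    return AmplitudeEnvelope(times_s=times, p2p=p2p, window_s=w / rate_hz)


@dataclass(frozen=True)
class CollapseEvent:
    onset_s: float
    duration_s: float


def detect_amplitude_collapse(envelope: AmplitudeEnvelope,
                              baseline_median: float,
                              collapse_fraction: float = 0.3,
                              min_duration_s: float = 10.0) -> list[CollapseEvent]:
    """Episodes where the envelope stays below ``collapse_fraction`` of baseline.

    Returns one event per contiguous run lasting at least ``min_duration_s``.
    A fraction of 0 can never be undercut by a non-negative envelope, so it
    degenerates to an empty list.
    """
    if baseline_median < 0:
        raise ValueError("baseline envelope median must be non-negative")
    below = envelope.p2p < collapse_fraction * baseline_median
    events: list[CollapseEvent] = []
    edges = np.flatnonzero(np.diff(np.concatenate(([False], below, [False]))))
    step = envelope.window_s
    for start, stop in edges.reshape(-1, 2):
        duration = (stop - start) * step
        if duration >= min_duration_s:
            onset = envelope.times_s[start] - 0.5 * step
            events.append(CollapseEvent(onset_s=float(onset), duration_s=float(duration)))
    return events
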