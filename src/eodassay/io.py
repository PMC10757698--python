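"""File formats: WAV recordings with JSON sidecars, CSV tracks/events/ground truth."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .chirps import ChirpEvent
from .synthetic import Phases, Recording, RecordingMetadata
from .tracking import FrequencyTrack, MedianSeries


def write_recording(path, recording: Recording) -> None:
    """Write a recording as 32-bit float mono WAV plus a JSON sidecar."""
    path = Path(path)
    wavfile.write(path, int(round(recording.rate_hz)),
                  recording.samples.astype(np.float32))
    meta = recording.metadata
    sidecar = {
        "fish_id": meta.fish_id,
        "concentration_ul_per_l": meta.concentration_ul_per_l,
        "start_s": recording.start_s,
        "rate_hz": recording.rate_hz,
        "phases": {
            "baseline_s": meta.phases.baseline_s,
            "treatment_s": meta.phases.treatment_s,
            "post_s": meta.phases.post_s,
        },
        "temperature_times_s": meta.temperature_times_s.tolist(),
        "temperature_c": meta.temperature_c.tolist(),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_recording(path) -> Recording:
    """Read a WAV + JSON sidecar pair written by :func:`write_recording`."""
    path = Path(path)
    rate, samples = wavfile.read(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    phases = Phases(**sidecar["phases"])
    meta = RecordingMetadata(
        fish_id=sidecar["fish_id"],
        concentration_ul_per_l=float(sidecar["concentration_ul_per_l"]),
        phases=phases,
        temperature_times_s=np.asarray(sidecar["temperature_times_s"], dtype=float),
        temperature_c=np.asarray(sidecar["temperature_c"], dtype=float),
    )
    return Recording(samples=np.asarray(samples, dtype=np.float32),
                     rate_hz=float(sidecar.get("rate_hz", rate)),
                     start_s=float(sidecar.get("start_s", 0.0)), metadata=meta)


def track_to_frame(track: FrequencyTrack) -> pd.DataFrame:
    return pd.DataFrame({"time_s": track.times_s, "freq_hz": track.freqs_hz,
                         "flag": track.flags.astype(int)})


def median_series_to_frame(series: MedianSeries) -> pd.DataFrame:
    return pd.DataFrame({"time_s": series.times_s, "freq_hz": series.medians_hz})


def events_to_frame(events: list[ChirpEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"peak_time_s": e.peak_time_s, "delta_f_hz": e.delta_f_hz,
          "alpha_per_s": e.alpha_per_s, "goodness": e.goodness, "class": e.cls}
         for e in events],
        columns=["peak_time_s", "delta_f_hz", "alpha_per_s", "goodness", "class"])


def ground_truth_chirps_frame(chirps) -> pd.DataFrame:
    return pd.DataFrame(
        [{"time_s": c.time_s, "delta_f_hz": c.delta_f_hz,
          "alpha_per_s": c.alpha_per_s, "amp_dip": c.amp_dip} for c in chirps],
        columns=["time_s", "delta_f_hz", "alpha_per_s", "amp_dip"])


def profile_breakpoints_frame(profile) -> pd.DataFrame:
    return pd.DataFrame({"time_s": profile.times_s, "freq_hz": profile.base_freqs_hz})
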