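import numpy as np
import pytest

from eodassay.synthetic import (GeneratorConfig, Phases, make_amplitude_profile,
                                make_frequency_profile, synthesize_waveform)


def make_tone(freq_hz, duration_s, rate_hz=40000.0, amps=(1.0,), noise_sd=0.0, seed=0):
    """Plain multi-harmonic tone, independent of the generator machinery."""
    rng = np.random.default_rng(seed)
    t = np.arange(int(duration_s * rate_hz)) / rate_hz
    x = sum(a * np.sin(2 * np.pi * (h + 1) * freq_hz * t) for h, a in enumerate(amps))
    if noise_sd:
        x = x + rng.normal(0, noise_sd, t.size)
    return np.asarray(x, dtype=float)


@pytest.fixture(scope="session")
def flat_recording():
    """Noise-free flat 800 Hz synthetic recording (short baseline-only trial)."""
    cfg = GeneratorConfig(phases=Phases(baseline_s=90.0, treatment_s=0.0, post_s=0.0),
                          jitter_sd_hz=0.0, noise_sd=0.0, movement_jitter_sd=0.0)
    prof = make_frequency_profile(cfg, 0.0, np.random.default_rng(0), f0_hz=800.0)
    amp = make_amplitude_profile(cfg, 0.0, np.random.default_rng(1))
    rec = synthesize_waveform(prof, amp, cfg, np.random.default_rng(2))
    return rec


@pytest.fixture
def rng():
    return np.random.default_rng(20230)
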