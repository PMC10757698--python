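"""Generator: frequency profiles, chirp insertion, waveform rendering, experiments."""

import numpy as np
import pytest
from scipy.stats import chisquare, poisson

from eodassay.recovery import REFERENCE_RECOVERY_PARAMS, evaluate_recovery_model
from eodassay.synthetic import (ChirpSpec, GeneratorConfig, Phases,
                                generate_experiment, insert_chirps,
                                make_amplitude_profile, make_frequency_profile,
                                synthesize_waveform)

FULL = Phases()  # 30 min baseline / 5 min treatment / 180 min post


def _quiet_config(**kw):
    defaults = dict(jitter_sd_hz=0.0, noise_sd=0.0, movement_jitter_sd=0.0)
    defaults.update(kw)
    return GeneratorConfig(**defaults)


class TestFrequencyProfile:
    def test_control_with_zero_jitter_is_flat(self):
        cfg = _quiet_config(phases=FULL)
        prof = make_frequency_profile(cfg, 0.0, np.random.default_rng(0), f0_hz=800.0)
        assert prof.times_s[-1] == pytest.approx(215 * 60)
        assert np.all(prof.base_freqs_hz == 800.0)

    def test_post_phase_follows_recovery_model(self):
        cfg = _quiet_config(phases=FULL)
        prof = make_frequency_profile(cfg, 60.0, np.random.default_rng(0), f0_hz=800.0)
        params = REFERENCE_RECOVERY_PARAMS[60.0]
        post = prof.times_s >= FULL.return_s
        t_min = (prof.times_s[post] - FULL.return_s) / 60.0
        expected = 800.0 * evaluate_recovery_model(params, t_min)
        np.testing.assert_allclose(prof.base_freqs_hz[post], expected, rtol=1e-12)

    def test_recovery_value_at_30_min(self):
        # direct arithmetic on the highest-dose parameter set, f0 = 1
        assert evaluate_recovery_model(REFERENCE_RECOVERY_PARAMS[60.0], 30.0) == \
            pytest.approx(0.9889, abs=5e-5)

    def test_treatment_segment_declines_to_a_f0(self):
        cfg = _quiet_config(phases=FULL)
        prof = make_frequency_profile(cfg, 45.0, np.random.default_rng(0), f0_hz=700.0)
        i_return = np.searchsorted(prof.times_s, FULL.return_s)
        a = REFERENCE_RECOVERY_PARAMS[45.0].a
        assert prof.base_freqs_hz[i_return - 1] == pytest.approx(700.0 * a, rel=1e-3)
        # decline is monotone after the latency
        seg = prof.base_freqs_hz[(prof.times_s >= FULL.treatment_onset_s + 60)
                                 & (prof.times_s < FULL.return_s)]
        assert np.all(np.diff(seg) <= 1e-9)

    def test_baseline_stationary_around_f0(self):
        cfg = GeneratorConfig(phases=Phases(1800, 0, 0))
        prof = make_frequency_profile(cfg, 0.0, np.random.default_rng(3), f0_hz=800.0)
        assert abs(prof.base_freqs_hz.mean() - 800.0) < 3 * cfg.jitter_sd_hz
        assert np.all(prof.base_freqs_hz > 0)

    def test_invalid_inputs_rejected(self):
        cfg = _quiet_config()
        with pytest.raises(ValueError):
            make_frequency_profile(cfg, 0.0, np.random.default_rng(0), f0_hz=-5.0)
        with pytest.raises(ValueError):
            Phases(baseline_s=-1.0)
        with pytest.raises(ValueError):
            make_frequency_profile(cfg, 37.5, np.random.default_rng(0), f0_hz=800.0)


class TestInsertChirps:
    def test_zero_rate_leaves_profile_unchanged(self):
        cfg = _quiet_config()
        prof = make_frequency_profile(cfg, 0.0, np.random.default_rng(0), f0_hz=800.0)
        prof2, log = insert_chirps(prof, 0.0, 0.0, cfg, np.random.default_rng(1))
        assert log == []
        np.testing.assert_array_equal(prof2.evaluate(prof.times_s), prof.base_freqs_hz)

    def test_single_chirp_peak_height(self):
        cfg = _quiet_config(phases=Phases(60, 0, 0))
        prof = make_frequency_profile(cfg, 0.0, np.random.default_rng(0), f0_hz=800.0)
        chirp = ChirpSpec(time_s=10.0, delta_f_hz=60.0, alpha_per_s=500.0)
        from dataclasses import replace
        prof = replace(prof, chirps=(chirp,))
        t = np.arange(0, 60, 1e-4)
        f = prof.evaluate(t)
        assert f.max() == pytest.approx(860.0, abs=1e-3)
        assert t[np.argmax(f)] == pytest.approx(10.0, abs=1e-3)

    def test_event_count_near_poisson_expectation(self):
        cfg = _quiet_config(phases=Phases(0, 0, 1800))
        prof = make_frequency_profile(cfg, 0.0, np.random.default_rng(0), f0_hz=800.0)
        _, log = insert_chirps(prof, 0.0, 5.0, cfg, np.random.default_rng(11))
        lam = 150.0
        assert abs(len(log) - lam) < 3 * np.sqrt(lam)

    def test_ground_truth_log_is_complete_and_separated(self):
        cfg = _quiet_config(phases=Phases(0, 0, 600))
        prof = make_frequency_profile(cfg, 0.0, np.random.default_rng(0), f0_hz=800.0)
        prof2, log = insert_chirps(prof, 0.0, 8.0, cfg, np.random.default_rng(5))
        assert tuple(log) == prof2.chirps
        times = np.array([c.time_s for c in log])
        halves = np.array([c.half_support_s for c in log])
        assert np.all(np.diff(times) > (halves[:-1] + halves[1:]))

    def test_count_distribution_matches_poisson_law(self):
        # chi-square goodness of fit of event counts across many seeds
        cfg = _quiet_config(phases=Phases(0, 0, 600))
        prof = make_frequency_profile(cfg, 0.0, np.random.default_rng(0), f0_hz=800.0)
        lam = 2.0 * 10.0  # 2/min over 10 min
        counts = [len(insert_chirps(prof, 0.0, 2.0, cfg, np.random.default_rng(s))[1])
                  for s in range(150)]
        edges = [0, 14, 17, 20, 23, 26, 1000]
        obs = np.histogram(counts, bins=edges)[0]
        probs = np.diff([poisson.cdf(e - 1, lam) for e in edges])
        stat = chisquare(obs, probs / probs.sum() * len(counts))
        assert stat.pvalue > 0.01

    def test_negative_rate_rejected(self):
        cfg = _quiet_config()
        prof = make_frequency_profile(cfg, 0.0, np.random.default_rng(0), f0_hz=800.0)
        with pytest.raises(ValueError):
            insert_chirps(prof, -1.0, 0.0, cfg, np.random.default_rng(0))


class TestWaveform:
    def test_pure_tone_periodogram_peak(self):
        cfg = _quiet_config(phases=Phases(5, 0, 0), harmonics=(1.0,))
        prof = make_frequency_profile(cfg, 0.0, np.random.default_rng(0), f0_hz=700.0)
        amp = make_amplitude_profile(cfg, 0.0, np.random.default_rng(1))
        rec = synthesize_waveform(prof, amp, cfg, np.random.default_rng(2))
        for start in (0, 2):
            x = rec.samples[start * 40000:(start + 1) * 40000]
            spec = np.abs(np.fft.rfft(x))
            peak = np.fft.rfftfreq(x.size, 1 / 40000.0)[np.argmax(spec)]
            assert peak == pytest.approx(700.0, abs=1.0)

    def test_sample_to_sample_difference_bounded(self):
        cfg = _quiet_config(phases=Phases(5, 0, 0), harmonics=(1.0,))
        prof = make_frequency_profile(cfg, 0.0, np.random.default_rng(0), f0_hz=900.0)
        amp = make_amplitude_profile(cfg, 0.0, np.random.default_rng(1))
        rec = synthesize_waveform(prof, amp, cfg, np.random.default_rng(2))
        bound = 2 * np.pi * 900.0 / 40000.0 * 1.0
        assert np.max(np.abs(np.diff(rec.samples))) <= bound * 1.05

    def test_aliasing_rejected(self):
        cfg = _quiet_config(phases=Phases(1, 0, 0), sample_rate_hz=5000.0)
        prof = make_frequency_profile(cfg, 0.0, np.random.default_rng(0), f0_hz=800.0)
        amp = make_amplitude_profile(cfg, 0.0, np.random.default_rng(1))
        with pytest.raises(ValueError, match="sample rate"):
            synthesize_waveform(prof, amp, cfg, np.random.default_rng(2))

    def test_rendering_is_deterministic(self):
        cfg = GeneratorConfig(phases=Phases(10, 0, 0))
        out = []
        for _ in range(2):
            prof = make_frequency_profile(cfg, 0.0, np.random.default_rng(7), f0_hz=750.0)
            amp = make_amplitude_profile(cfg, 0.0, np.random.default_rng(8))
            out.append(synthesize_waveform(prof, amp, cfg, np.random.default_rng(9)))
        np.testing.assert_array_equal(out[0].samples, out[1].samples)


class TestExperiment:
    def test_default_design_has_32_trials(self):
        ds = generate_experiment(GeneratorConfig(), seed=1)
        assert len(ds.trials) == 32
        assert len(ds.fish_ids) == 8
        for fid in ds.fish_ids:
            # f0 drawn once per fish and shared by all four conditions
            f0s = {ds.trials[(fid, c)].f0_hz for c in (0.0, 30.0, 45.0, 60.0)}
            assert len(f0s) == 1
            assert 650.0 <= f0s.pop() <= 1000.0
            assert sorted(ds.treatment_order[fid]) == [0.0, 30.0, 45.0, 60.0]

    def test_single_control_trial(self):
        cfg = GeneratorConfig(n_fish=1, concentrations=(0.0,),
                              phases=Phases(30, 0, 0))
        ds = generate_experiment(cfg, seed=5)
        assert set(ds.trials) == {("fish-1", 0.0)}
        gt = ds.trials[("fish-1", 0.0)]
        # control: no drop beyond jitter, no chirp-rate boost
        assert np.all(np.abs(gt.profile.base_freqs_hz - gt.f0_hz) < 6 * cfg.jitter_sd_hz)

    def test_regeneration_from_seed_is_bit_identical(self):
        cfg = GeneratorConfig(n_fish=2, concentrations=(0.0, 60.0),
                              phases=Phases(20, 5, 20), sample_rate_hz=20000.0)
        a = generate_experiment(cfg, seed=99)
        b = generate_experiment(cfg, seed=99)
        assert a.f0_by_fish == b.f0_by_fish
        assert a.treatment_order == b.treatment_order
        for key in a.trials:
            np.testing.assert_array_equal(a.trials[key].profile.base_freqs_hz,
                                          b.trials[key].profile.base_freqs_hz)
            assert a.trials[key].chirps == b.trials[key].chirps
            np.testing.assert_array_equal(a.realize(*key).samples,
                                          b.realize(*key).samples)

    def test_collapse_only_at_highest_dose(self):
        cfg = GeneratorConfig(phases=Phases(60, 300, 600))
        hits = 0
        for s in range(12):
            amp60 = make_amplitude_profile(cfg, 60.0, np.random.default_rng(s))
            amp30 = make_amplitude_profile(cfg, 30.0, np.random.default_rng(s))
            assert amp30.collapses == ()
            if amp60.collapses:
                hits += 1
                ev = amp60.collapses[0]
                assert ev.onset_s == pytest.approx(60 + 210.0)
                assert amp60.evaluate(np.array([ev.onset_s + 60.0]))[0] < 0.3
        assert 0 < hits < 12  # Bernoulli half-rate, not all-or-none
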