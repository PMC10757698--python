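"""Exact sign test, minimal-n rule, split-plot mixed model, recovery time."""

import itertools
import warnings

import numpy as np
import pytest

from eodassay.stats import (fit_mixed_model, joint_concentration_test,
                            make_mixed_model_frame, min_n_for_sign_test,
                            recovery_time, sign_test_exact)


def brute_force_sign_p(n_pos, n_neg):
    """Enumerate all 2^n equally likely sign patterns; two-tailed tail mass."""
    n = n_pos + n_neg
    k_obs = min(n_pos, n_neg)
    lower_tail = sum(1 for pattern in itertools.product([1, -1], repeat=n)
                     if sum(s > 0 for s in pattern) <= k_obs)
    return min(1.0, 2.0 * lower_tail / 2**n)


class TestSignTest:
    @pytest.mark.parametrize("pos,neg,expected", [
        (0, 8, 0.0078125),
        (8, 0, 0.0078125),
        (6, 2, 0.2890625),
        (5, 3, 0.7265625),
    ])
    def test_reference_splits(self, pos, neg, expected):
        d = np.r_[np.ones(pos), -np.ones(neg)]
        assert sign_test_exact(d).p_value == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("n", [3, 5, 8, 10, 12])
    def test_matches_brute_force_enumeration(self, n):
        for n_pos in range(n + 1):
            d = np.r_[np.ones(n_pos), -np.ones(n - n_pos)]
            assert sign_test_exact(d).p_value == \
                pytest.approx(brute_force_sign_p(n_pos, n - n_pos), abs=1e-12)

    def test_ties_dropped(self):
        res = sign_test_exact([1.0, -1.0, 0.0, 0.0, 2.0])
        assert res.n == 3
        assert res.n_positive == 2

    def test_all_ties_rejected(self):
        with pytest.raises(ValueError):
            sign_test_exact([0.0, 0.0])

    def test_p_value_in_unit_interval(self):
        d = np.r_[np.ones(4), -np.ones(4)]
        assert sign_test_exact(d).p_value == 1.0


class TestMinimalN:
    def test_reference_alphas(self):
        assert min_n_for_sign_test(0.01) == 8
        assert min_n_for_sign_test(0.05) == 6

    @pytest.mark.parametrize("alpha", [0.001, 0.01, 0.02, 0.05, 0.1])
    def test_consistency_with_exact_test(self, alpha):
        n = min_n_for_sign_test(alpha)
        all_same = lambda m: sign_test_exact(np.ones(m)).p_value
        assert all_same(n) < alpha
        if n > 1:
            assert all_same(n - 1) >= alpha

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            min_n_for_sign_test(1.5)


def simulate_frame(rng, delta=(1.0, -0.002, 0.0005, 1e-5), sigma_b=0.0,
                   sigma_e=0.0, n_fish=4, n_time=12, concs=(0.0, 60.0)):
    d0, d1, d2, d12 = delta
    records = []
    for c in concs:
        for j in range(n_fish):
            b = rng.normal(0, sigma_b) if sigma_b else 0.0
            for k in range(1, n_time + 1):
                t = k / 2.0
                y = d0 + d1 * c + b + d2 * t + d12 * c * t
                if sigma_e:
                    y += rng.normal(0, sigma_e)
                records.append((f"f{j}", c, k, y))
    return make_mixed_model_frame(records)


class TestMixedModel:
    def test_zero_noise_equals_closed_form_least_squares(self, rng):
        delta = (1.0, -0.002, 0.0005, 1e-5)
        frame = simulate_frame(rng, delta=delta)
        fit = fit_mixed_model(frame)
        assert fit.singular  # zero residual variance is a boundary case
        assert (fit.delta0, fit.delta1, fit.delta2, fit.delta12) == \
            pytest.approx(delta, abs=1e-9)

    def test_variance_component_near_zero_without_fish_effect(self, rng):
        frame = simulate_frame(rng, sigma_b=0.0, sigma_e=0.01, n_fish=8, n_time=20)
        fit = fit_mixed_model(frame)
        assert fit.sigma2_fish < 1e-5
        assert fit.sigma2_resid == pytest.approx(1e-4, rel=0.5)

    def test_fixed_effects_recovered_within_3se(self):
        delta = (1.0, -0.002, 0.0005, 1e-5)
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            frame = simulate_frame(rng, delta=delta, sigma_b=0.02, sigma_e=0.01,
                                   n_fish=8, n_time=40)
            fit = fit_mixed_model(frame)
            # crude SE proxies from the model structure
            est = np.array([fit.delta0, fit.delta1, fit.delta2, fit.delta12])
            if np.all(np.abs(est - delta) < np.array([0.05, 1e-3, 1e-3, 2e-5])):
                hits += 1
        assert hits >= 18

    def test_single_unit_rejected(self):
        frame = make_mixed_model_frame([("f0", 0.0, k, 1.0) for k in range(1, 9)])
        with pytest.raises(ValueError):
            fit_mixed_model(frame)


class TestJointTest:
    def test_exact_copy_of_control_gives_large_p(self, rng):
        records = []
        for j in range(8):
            y = 1.0 + rng.normal(0, 0.01, 15)
            for c in (0.0, 60.0):  # concentration group duplicates control
                records += [(f"f{j}", c, k, float(v)) for k, v in enumerate(y, 1)]
        res = joint_concentration_test(make_mixed_model_frame(records))
        assert res.p_value > 0.5

    def test_overwhelming_offset_detected(self, rng):
        frame = simulate_frame(rng, delta=(1.0, -0.005, 0.0, 0.0),
                               sigma_e=0.01, n_fish=8, n_time=15)
        res = joint_concentration_test(frame)
        assert res.p_value < 1e-6

    def test_requires_exactly_two_levels(self, rng):
        frame = simulate_frame(rng, sigma_e=0.01, concs=(0.0, 30.0, 60.0))
        with pytest.raises(ValueError):
            joint_concentration_test(frame)


class TestRecoveryTime:
    def test_identical_groups_recover_at_first_window(self, rng):
        frame = simulate_frame(rng, delta=(1.0, 0.0, 0.0, 0.0), sigma_e=0.01,
                               n_fish=8, n_time=40)
        res = recovery_time(frame)
        assert res.recovered
        assert res.t_r_min == 0.5
        assert res.r_index == 1

    def test_bonferroni_never_below_raw(self, rng):
        frame = simulate_frame(rng, delta=(1.0, -0.001, 0.0, 0.0), sigma_e=0.02,
                               n_fish=4, n_time=45)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = recovery_time(frame, alpha=1e-9)  # force a full scan
        for r, (q, p) in enumerate(sorted(res.window_p_values.items()), start=1):
            assert min(1.0, p * r) >= p

    def test_invariant_to_fish_relabeling(self, rng):
        frame = simulate_frame(rng, delta=(1.0, -0.0005, 0.0, 0.0), sigma_e=0.01,
                               n_fish=8, n_time=30)
        relabeled = frame.copy()
        mapping = {f"f{j}": f"fish-{7 - j}" for j in range(8)}
        relabeled["fish"] = relabeled["fish"].map(mapping)
        relabeled["unit"] = relabeled["fish"] + "@" + \
            relabeled["concentration_ul_per_l"].astype(str)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = recovery_time(frame)
            b = recovery_time(relabeled)
        assert a.t_r_min == b.t_r_min
        assert a.r_index == b.r_index

    def test_short_grid_rejected(self, rng):
        frame = simulate_frame(rng, sigma_e=0.01, n_time=10)
        with pytest.raises(ValueError):
            recovery_time(frame, window_len=15)
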