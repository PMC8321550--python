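import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from reachloop import HandTrajectory, RawProbeSnippet, SpikeTrain
from reachloop.signal_prep import (
    align_to_event,
    bin_spikes,
    gaussian_kernel,
    hand_velocity,
    multiunit_depth_profile,
    smooth_rate,
    stim_power_density,
    zscore_to_baseline,
)


class TestBinSpikes:
    def test_no_spikes_all_zero(self):
        counts = bin_spikes(np.empty(0), 0.0, 1.0, 0.01)
        assert counts.shape == (100,) and not counts.any()

    def test_edge_spike_goes_to_right_hand_bin(self):
        counts = bin_spikes(np.array([0.5]), 0.0, 1.0, 0.1)
        assert counts[5] == 1 and counts.sum() == 1

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_counts_sum_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        times = np.sort(rng.uniform(0, 10, rng.integers(0, 200)))
        counts = bin_spikes(times, 2.0, 7.0, 0.013)
        n_bins = counts.size
        brute = np.sum((times >= 2.0) & (times < 2.0 + n_bins * 0.013))
        assert counts.sum() == brute


class TestSmoothRate:
    def test_single_spike_peak_rate(self):
        counts = np.zeros(1001)
        counts[500] = 1
        rate = smooth_rate(counts, 0.001, 0.050)
        assert abs(rate[500] - 1.0 / (0.050 * np.sqrt(2 * np.pi))) < 0.01
        assert abs(rate[500] - 7.979) < 0.01

    def test_zero_counts_zero_rate(self):
        assert not smooth_rate(np.zeros(100), 0.001, 0.05).any()

    def test_matches_dense_convolution_oracle(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(0.05, 2000).astype(float)
        rate = smooth_rate(counts, 0.001, 0.025)
        k = gaussian_kernel(0.025, 0.001)
        half = k.size // 2
        # brute-force convolution
        oracle = np.zeros_like(counts)
        for i in range(counts.size):
            for j, kv in enumerate(k):
                src = i - (j - half)
                if 0 <= src < counts.size:
                    oracle[i] += counts[src] * kv
        np.testing.assert_allclose(rate, oracle / 0.001, atol=1e-10)

    def test_mass_conservation_away_from_edges(self):
        rng = np.random.default_rng(1)
        counts = np.zeros(3000)
        idx = rng.integers(300, 2700, 50)  # >= 4 sigma from edges
        for i in idx:
            counts[i] += 1
        rate = smooth_rate(counts, 0.001, 0.050)
        assert abs(rate.sum() * 0.001 - counts.sum()) / counts.sum() < 1e-3


class TestZScore:
    def test_constant_rate_floored_to_zero(self):
        values = np.full((2, 100, 5), 10.0)
        t = np.linspace(-1, 1, 100)
        z, _, _, floored = zscore_to_baseline(values, t, (-1.0, -0.2))
        assert floored.all()
        np.testing.assert_array_equal(z, 0.0)

    def test_known_mean_and_sd(self):
        t = np.linspace(-1, 1, 200)
        base = t < 0
        rng = np.random.default_rng(0)
        values = np.empty((1, 200, 50))
        values[0, base, :] = rng.normal(10, 2, (base.sum(), 50))
        values[0, ~base, :] = 14.0
        z, mean, sd, floored = zscore_to_baseline(values, t, (-1.0, 0.0))
        assert not floored[0]
        assert abs(mean[0] - 10) < 0.2 and abs(sd[0] - 2) < 0.2
        # z of the post-event samples is close to (14 - 10) / 2 = 2
        assert abs(z[0, ~base, :].mean() - 2.0) < 0.3

    def test_inverse_transform_recovers_rates(self):
        rng = np.random.default_rng(2)
        values = rng.gamma(2.0, 5.0, (3, 50, 8))
        t = np.linspace(-0.5, 0.5, 50)
        z, mean, sd, _ = zscore_to_baseline(values, t, (-0.5, 0.0))
        back = z * sd[:, None, None] + mean[:, None, None]
        np.testing.assert_allclose(back, values, atol=1e-10)

    def test_zero_trials_error(self):
        with pytest.raises(ValueError):
            zscore_to_baseline(np.empty((2, 10, 0)), np.linspace(-1, 0, 10), (-1, 0))


class TestAlignToEvent:
    def test_single_trial_average_is_that_trial(self, small_session):
        session, _ = small_session
        unit = session.units(region="PN")[:1]
        aligned = align_to_event(session, unit, "cue_time", (-0.2, 0.5))
        one = aligned.values[:, :, :1]
        sub = aligned.values[:, :, 0]
        np.testing.assert_array_equal(one[:, :, 0], sub)

    def test_cue_locked_bump_peaks_near_truth(self):
        from reachloop.synthetic import simulate_glm_unit
        from conftest import make_cue_lift_trials
        from reachloop import Session

        trials = make_cue_lift_trials(200, seed=5)
        k_cue = np.zeros(600)
        k_cue[150:250] = 1.5
        train = simulate_glm_unit(k_cue, np.zeros(1), 10.0, trials, seed=6)
        session = Session(session_id="s", animal_id="a", spikes=[train], trials=trials)
        aligned = align_to_event(session, [train], "cue_time", (-0.5, 0.8), sigma_s=0.02)
        avg = aligned.trial_average()[0]
        peak_t = aligned.t[np.argmax(avg)]
        assert 0.1 < peak_t < 0.3

    def test_window_fully_before_cue_is_flat(self):
        from reachloop.synthetic import simulate_glm_unit
        from conftest import make_cue_lift_trials
        from reachloop import Session

        trials = make_cue_lift_trials(300, seed=7)
        k_cue = np.zeros(600)
        k_cue[:300] = 2.0
        train = simulate_glm_unit(k_cue, np.zeros(1), 10.0, trials, seed=8)
        session = Session(session_id="s", animal_id="a", spikes=[train], trials=trials)
        aligned = align_to_event(session, [train], "cue_time", (-0.9, -0.3))
        avg = aligned.trial_average()[0]
        assert np.ptp(avg) < 0.5 * avg.mean()

    def test_missing_event_trials_counted(self, small_session):
        session, _ = small_session
        units = session.units(region="PN")[:1]
        aligned = align_to_event(session, units, "lift_time", (-0.1, 0.1))
        n_lift = np.isfinite(session.trials.lift_time).sum()
        assert aligned.values.shape[2] == n_lift
        assert aligned.n_excluded == len(session.trials) - n_lift


class TestHandVelocity:
    @staticmethod
    def _traj(pos):
        t = np.arange(pos.shape[1]) * 0.002
        return HandTrajectory(t=t, position=pos)

    def test_constant_position_zero_velocity(self):
        vel, valid = hand_velocity(self._traj(np.full((3, 100), 5.0)), sigma_s=None)
        np.testing.assert_allclose(vel[:, valid], 0.0, atol=1e-9)

    def test_linear_ramp_exact(self):
        t = np.arange(200) * 0.002
        pos = np.vstack([5.0 * t, np.zeros_like(t), np.zeros_like(t)])
        vel, valid = hand_velocity(self._traj(pos), sigma_s=None)
        np.testing.assert_allclose(vel[0, valid], 5.0, atol=1e-9)

    def test_degree7_polynomial_derivative_exact(self):
        t = np.arange(300) * 0.002
        coef = np.array([0.3, -1.2, 0.8, 2.0, -0.5, 0.1, 0.05, -0.01])
        pos0 = np.polyval(coef, t)
        dcoef = np.polyder(coef)
        pos = np.vstack([pos0, pos0, pos0])
        vel, valid = hand_velocity(self._traj(pos), sigma_s=None)
        np.testing.assert_allclose(vel[0, valid], np.polyval(dcoef, t)[valid],
                                   rtol=1e-8, atol=1e-8)

    def test_integrated_velocity_round_trip(self):
        """Differentiating the exact antiderivative recovers the velocity."""
        t = np.arange(2000) * 0.002
        w1, w2 = 2 * np.pi * 0.7, 2 * np.pi * 1.3
        v_true = 20 * np.sin(w1 * t) + 5 * np.cos(w2 * t)
        pos_scalar = -20 / w1 * np.cos(w1 * t) + 5 / w2 * np.sin(w2 * t)
        pos = np.vstack([pos_scalar] * 3)
        vel, valid = hand_velocity(self._traj(pos), sigma_s=None)
        rel = np.abs(vel[0, valid] - v_true[valid]) / np.max(np.abs(v_true))
        assert rel.max() < 1e-6

    def test_short_trajectory_raises(self):
        with pytest.raises(ValueError):
            hand_velocity(self._traj(np.zeros((3, 5))), sigma_s=None)


def _probe(voltage, fs=30000.0, depths=None, pulses=(0.1, 0.5)):
    depths = depths if depths is not None else np.arange(voltage.shape[0]) * 20.0
    return RawProbeSnippet(channel_positions_um=depths, sample_rate_hz=fs,
                           voltage=voltage, pulse_onsets=np.asarray(pulses))


class TestDepthProfile:
    def test_dc_voltage_removed_by_highpass(self):
        volt = np.full((8, 30000), 3.7)
        depths, profile = multiunit_depth_profile(_probe(volt))
        np.testing.assert_allclose(profile, 0.0, atol=1e-6)

    def test_evoked_burst_localized_in_depth(self):
        rng = np.random.default_rng(0)
        fs = 30000.0
        n = int(fs)
        volt = rng.normal(0, 0.5, (16, n))
        depths = 5000.0 + np.arange(16) * 100.0  # 5.0-6.5 mm
        pulses = np.array([0.1, 0.4, 0.7])
        burst_ch = (depths >= 5500) & (depths <= 6000)
        for p in pulses:
            i0 = int((p + 0.006) * fs)
            i1 = int((p + 0.010) * fs)
            volt[burst_ch, i0:i1] += 40 * np.sin(
                2 * np.pi * 2000 * np.arange(i1 - i0) / fs
            )
        d, profile = multiunit_depth_profile(_probe(volt, depths=depths, pulses=pulses))
        assert 5500 <= d[np.argmax(profile)] <= 6000

    def test_doubling_identical_pulses_leaves_profile(self):
        rng = np.random.default_rng(1)
        fs = 30000.0
        base = rng.normal(0, 1, (4, int(0.4 * fs)))
        volt = np.concatenate([base, base], axis=1)
        d1, p1 = multiunit_depth_profile(_probe(volt, pulses=[0.1]))
        d2, p2 = multiunit_depth_profile(_probe(volt, pulses=[0.1, 0.5]))
        np.testing.assert_allclose(p1, p2, rtol=1e-6)

    def test_channel_order_equivariance(self):
        rng = np.random.default_rng(2)
        fs = 30000.0
        volt = rng.normal(0, 1, (6, int(0.5 * fs)))
        depths = np.array([0.0, 30, 60, 90, 120, 150])
        d1, p1 = multiunit_depth_profile(_probe(volt, depths=depths, pulses=[0.1]))
        perm = np.array([3, 1, 5, 0, 2, 4])
        d2, p2 = multiunit_depth_profile(
            _probe(volt[perm], depths=depths[perm], pulses=[0.1])
        )
        np.testing.assert_array_equal(d1, d2)
        np.testing.assert_allclose(p1, p2, rtol=1e-10)


class TestStimPower:
    def test_sinusoid_power_concentrated_at_40(self):
        fs = 1000.0
        t = np.arange(2000) / fs
        env = np.sin(2 * np.pi * 40 * t)[None, :]
        p40 = stim_power_density(env, fs, 40.0)[0]
        p25 = stim_power_density(env, fs, 25.0)[0]
        assert p40 > 100 * max(p25, 1e-30)

    def test_zero_signal_zero_power(self):
        assert stim_power_density(np.zeros((2, 1000)), 1000.0, 40.0).sum() == 0

    def test_white_noise_power_flat_in_expectation(self):
        rng = np.random.default_rng(3)
        ratios = []
        for _ in range(30):
            env = rng.normal(0, 1, (1, 4000))
            p40 = stim_power_density(env, 1000.0, 40.0)[0]
            p60 = stim_power_density(env, 1000.0, 60.0)[0]
            ratios.append(p40 / p60)
        m = np.mean(ratios)
        assert 0.1 < m < 10.0
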