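import itertools

import numpy as np
import pytest

from reachloop import SpikeTrain
from reachloop.response_stats import (
    classify_laser_response,
    classify_lift_modulation,
    paired_window_test,
    sliding_window_latency,
)
from reachloop.stats import bh_qvalues, signed_rank_p


def train_from(times, unit_id="u", region="PN"):
    return SpikeTrain(unit_id=unit_id, region=region,
                      spike_times=np.unique(np.asarray(times, float)))


def exact_signed_rank_p(diffs):
    """Two-sided signed-rank p by enumerating all 2^n sign patterns."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = d.size
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    mean_w = n * (n + 1) / 4.0
    stats = []
    for signs in itertools.product([0, 1], repeat=n):
        stats.append(np.sum(ranks * np.array(signs)))
    stats = np.array(stats)
    tail = np.mean(np.abs(stats - mean_w) >= abs(w_obs - mean_w) - 1e-12)
    return tail


class TestPairedWindowTest:
    events = 100.0 + 2.0 * np.arange(20)

    def test_identical_counts_not_modulated(self):
        times = np.sort(np.concatenate([self.events - 0.01, self.events + 0.01]))
        res = paired_window_test([train_from(times)], self.events,
                                 (-0.02, 0.0), (0.0, 0.02))
        assert res.p[0] == 1.0 and not res.modulated[0]

    def test_uniform_positive_difference_matches_exact_oracle(self):
        # post = pre + 1 on every one of 20 events
        rng = np.random.default_rng(0)
        pre_counts = rng.integers(0, 4, 20)
        times = []
        for e, c in zip(self.events, pre_counts):
            times += list(e - 0.015 + 0.001 * np.arange(c))  # pre window
            times += list(e + 0.001 + 0.0005 * np.arange(c + 1))  # post = pre + 1
        res = paired_window_test([train_from(times)], self.events,
                                 (-0.02, 0.0), (0.0, 0.02))
        oracle = exact_signed_rank_p(np.ones(20))
        assert res.p[0] == pytest.approx(oracle, rel=1e-9)
        assert res.direction[0] == 1

    def test_synthetic_tagged_unit_detected_untagged_not(self):
        detected, false_pos = 0, 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            # tagged: 8 ms latency burst after each pulse on a 10 Hz background
            bg = np.sort(rng.uniform(99, 145, 500))
            burst = np.concatenate(
                [e + 0.008 + rng.uniform(0, 0.004, 3) for e in self.events]
            )
            tagged = train_from(np.concatenate([bg, burst]), "tag")
            untagged = train_from(np.sort(rng.uniform(99, 145, 500)), "untag")
            res = paired_window_test([tagged, untagged], self.events,
                                     (-0.02, 0.0), (0.0, 0.02))
            detected += bool(res.modulated[0])
            false_pos += bool(res.modulated[1])
        assert detected == n_seeds
        assert false_pos <= 0.05 * n_seeds  # untagged clean in >= 95% of seeds

    def test_too_few_events_flagged_untestable(self):
        res = paired_window_test([train_from([1.0])], np.array([1.0, 2.0]),
                                 (-0.02, 0.0), (0.0, 0.02))
        assert not res.testable[0] and np.isnan(res.p[0])

    def test_type_one_error_controlled_under_null(self):
        """Homogeneous units: per-unit rejection rate at alpha stays
        below 1.5 * alpha over 1000 replicates (no FDR, raw test)."""
        rng = np.random.default_rng(7)
        alpha = 0.05
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            pre = rng.poisson(2.0, 20)
            post = rng.poisson(2.0, 20)
            hits += signed_rank_p(post, pre) < alpha
        assert hits / n_rep <= 1.5 * alpha


class TestLaserClassification:
    onsets = 50.0 + 10.0 * np.arange(25)

    def _constant(self, rate, seed=0):
        rng = np.random.default_rng(seed)
        return train_from(np.sort(rng.uniform(0, 300, int(rate * 300))))

    def test_constant_rate_unit_is_none(self):
        res = classify_laser_response([self._constant(20)], self.onsets)
        assert res["classes"][0] == "none"

    def test_rate_halved_for_two_seconds_is_sustained_down(self):
        rng = np.random.default_rng(1)
        times = []
        for seg0, seg1 in zip(
            np.concatenate([[0.0], self.onsets + 2.0]),
            np.concatenate([self.onsets, [300.0]]),
        ):
            times += list(rng.uniform(seg0, seg1, int(30 * (seg1 - seg0))))
        for on in self.onsets:  # halved rate during the laser
            times += list(rng.uniform(on, on + 2.0, 30))
        res = classify_laser_response([train_from(times)], self.onsets)
        assert res["classes"][0] == "sustained_down"

    def test_transient_burst_is_transient_up(self):
        """Phasic motif: onset burst followed by a compensating pause, so
        the 2 s mean is unchanged while the first 100 ms is elevated."""
        rng = np.random.default_rng(2)
        times = list(rng.uniform(0, 300, 6000))  # 20 Hz background
        keep = np.asarray(times)
        for on in self.onsets:  # silence 80-500 ms into the laser
            keep = keep[~((keep >= on + 0.08) & (keep < on + 0.5))]
        times = list(keep)
        for on in self.onsets:  # 80 ms onset burst
            times += list(rng.uniform(on, on + 0.08, 8))
        res = classify_laser_response([train_from(times)], self.onsets)
        assert res["classes"][0] == "transient_up"


class TestSlidingLatency:
    pulses = 20.0 + 0.5 * np.arange(40)

    def test_unit_responding_at_7_to_17_ms_first_lag_at_most_8(self):
        rng = np.random.default_rng(3)
        times = np.concatenate(
            [p + rng.uniform(0.007, 0.017, 5) for p in self.pulses]
        )
        res = sliding_window_latency([train_from(times)], self.pulses)
        assert np.isfinite(res.first_lag_ms[0])
        assert res.first_lag_ms[0] <= 8.0

    def test_silent_unit_has_no_recruitment_lag(self):
        res = sliding_window_latency([train_from([1.0])], self.pulses)
        assert np.isnan(res.first_lag_ms[0])
        assert res.n_responsive == 0

    def test_recruitment_curve_monotone_and_normalized(self):
        rng = np.random.default_rng(4)
        trains = [
            train_from(np.concatenate(
                [p + rng.uniform(0.005 + 0.005 * k, 0.015 + 0.005 * k, 4)
                 for p in self.pulses]
            ), unit_id=f"u{k}")
            for k in range(4)
        ]
        res = sliding_window_latency(trains, self.pulses)
        assert np.all(np.diff(res.recruitment) >= 0)
        assert res.n_responsive == 4
        assert res.recruitment_normalized[-1] == pytest.approx(1.0)

    def test_too_few_pulses_raises(self):
        with pytest.raises(ValueError):
            sliding_window_latency([train_from([1.0])], np.arange(5.0))


class TestLiftModulation:
    @staticmethod
    def _fake_result(classes):
        from reachloop.response_stats import PairedWindowResult

        classes = np.asarray(classes)
        modulated = classes != "none"
        direction = np.where(classes == "increase", 1.0,
                             np.where(classes == "decrease", -1.0, 0.0))
        n = classes.size
        return PairedWindowResult(
            unit_ids=[f"u{i}" for i in range(n)], p=np.full(n, 0.01),
            q=np.full(n, 0.01), direction=direction, modulated=modulated,
            testable=np.ones(n, bool),
        )

    def test_identical_distributions_chi2_zero(self):
        classes = ["increase"] * 5 + ["decrease"] * 5 + ["none"] * 5
        res = classify_lift_modulation(
            self._fake_result(classes * 2),
            np.array([True] * 15 + [False] * 15),
        )
        assert res["chi2"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_chi2_matches_hand_computed_pearson(self):
        classes = (["increase"] * 30 + ["decrease"] * 10 + ["none"] * 10
                   + ["increase"] * 10 + ["decrease"] * 30 + ["none"] * 10)
        tagged = np.array([True] * 50 + [False] * 50)
        res = classify_lift_modulation(self._fake_result(classes), tagged)
        table = np.array([[30, 10, 10], [10, 30, 10]], dtype=float)
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        oracle = ((table - expected) ** 2 / expected).sum()
        assert res["chi2"] == pytest.approx(oracle, rel=1e-12)

    def test_single_unit_group_flags_low_count(self):
        classes = ["increase"] + ["none"] * 10
        tagged = np.array([True] + [False] * 10)
        res = classify_lift_modulation(self._fake_result(classes), tagged)
        assert res["low_count_warning"]


class TestBH:
    def test_bh_matches_step_up_oracle_and_dominates_bonferroni(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            m = rng.integers(1, 40)
            p = rng.uniform(0, 1, m) ** rng.uniform(0.5, 3)
            q = bh_qvalues(p)
            # brute-force step-up: q_i = min over j>=rank(i) of m*p_(j)/j
            order = np.argsort(p)
            q_oracle = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                running = min(running, m * p[order[rank - 1]] / rank)
                q_oracle[order[rank - 1]] = running
            np.testing.assert_allclose(q, q_oracle, atol=1e-12)
            # BH rejects everything Bonferroni rejects
            alpha = 0.05
            assert np.all(q[p < alpha / m] <= alpha + 1e-12)
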