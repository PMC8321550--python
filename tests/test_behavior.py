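import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from reachloop import HandTrajectory
from reachloop.behavior import (
    analyze_session,
    dispersion_test,
    duration_test,
    endpoint_difference,
    frame_overlay,
    initiation_test,
    success_test,
    summarize_sessions,
)
from reachloop.data_model import validate_trials
from conftest import trial_row


def hand_with_endpoints(trials, endpoints):
    """Trajectory that holds each trial's endpoint around its grab time."""
    t_end = trials.grab_time.max() + 1.0
    t = np.arange(int(t_end * 500)) / 500.0
    pos = np.zeros((3, t.size))
    for row, ep in zip(trials.itertuples(index=False), endpoints):
        if np.isfinite(row.grab_time):
            i = int(round(row.grab_time * 500))
            pos[:, i - 5:i + 5] = np.asarray(ep)[:, None]
    return HandTrajectory(t=t, position=pos)


def reach_trials(ctl_endpoints, las_endpoints, ctl_dur=0.25, las_dur=0.25):
    rows = []
    tid = 0
    for eps, ttype, dur in ((ctl_endpoints, "control", ctl_dur),
                            (las_endpoints, "laser_cue", las_dur)):
        durs = np.atleast_1d(dur)
        for k, ep in enumerate(eps):
            t0 = 2.0 + 2.0 * tid
            d = float(durs[k % durs.size])
            kw = {}
            if ttype == "laser_cue":
                kw = dict(laser_on=t0 - 0.05, laser_off=t0 + 1.95, laser_freq_hz=40.0)
            rows.append(trial_row(trial_id=tid, trial_type=ttype, cue_time=t0,
                                  lift_time=t0 + 0.3, grab_time=t0 + 0.3 + d,
                                  reach_initiated=True, success_first=True,
                                  success_any=True, **kw))
            tid += 1
    return validate_trials(pd.DataFrame(rows))


def exact_rank_sum_p(x, y):
    """Two-sided rank-sum p by enumerating all group assignments."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n, m = len(x), len(y)
    obs = ranks[:n].sum()
    mean = n * (n + m + 1) / 2.0
    stats = [
        ranks[list(c)].sum() for c in itertools.combinations(range(n + m), n)
    ]
    stats = np.array(stats)
    return float(np.mean(np.abs(stats - mean) >= abs(obs - mean) - 1e-12))


class TestEndpoint:
    def test_identical_distributions_no_difference(self):
        rng = np.random.default_rng(0)
        eps = rng.normal([10, 0, 5], 1.0, (40, 3))
        trials = reach_trials(eps[:20], eps[20:])
        hand = hand_with_endpoints(trials, eps)
        res = endpoint_difference(trials, hand)
        assert np.all(np.abs(res["diff_mm"]) < 1.0)
        assert np.all(res["p"] > 0.05)

    def test_disjoint_forward_shift_hits_extreme_tail(self):
        rng = np.random.default_rng(1)
        ctl = rng.uniform(9.0, 10.0, (30, 1)) * [1, 0, 0]
        las = ctl + [2.0, 0, 0]
        trials = reach_trials(ctl, las)
        hand = hand_with_endpoints(trials, np.vstack([ctl, las]))
        res = endpoint_difference(trials, hand)
        # disjoint supports: exact two-sided extreme tail = 2/C(60,30)
        from math import comb

        assert res["p"][0] == pytest.approx(2.0 / comb(60, 30), rel=1e-6)
        assert res["diff_mm"][0] == pytest.approx(2.0, abs=1e-6)

    def test_rank_sum_matches_enumeration_oracle_8v8(self):
        rng = np.random.default_rng(2)
        ctl = np.column_stack([rng.normal(10, 1, 8), np.zeros(8), np.zeros(8)])
        las = np.column_stack([rng.normal(11, 1, 8), np.zeros(8), np.zeros(8)])
        trials = reach_trials(ctl, las)
        hand = hand_with_endpoints(trials, np.vstack([ctl, las]))
        res = endpoint_difference(trials, hand)
        oracle = exact_rank_sum_p(las[:, 0], ctl[:, 0])
        assert res["p"][0] == pytest.approx(oracle, rel=1e-9)

    def test_missing_hand_raises(self):
        trials = reach_trials(np.zeros((5, 3)), np.zeros((5, 3)))
        with pytest.raises(ValueError):
            endpoint_difference(trials, None)


class TestDuration:
    def test_all_tied_durations_p_one(self):
        trials = reach_trials(np.zeros((10, 3)), np.zeros((10, 3)),
                              ctl_dur=0.25, las_dur=0.25)
        res = duration_test(trials)
        assert res["p"] == 1.0 and res["diff_s"] == 0.0

    def test_disjoint_shift_minimal_two_sided_p(self):
        rng = np.random.default_rng(3)
        ctl_d = rng.uniform(0.20, 0.25, 10)
        las_d = ctl_d + 0.1
        trials = reach_trials(np.zeros((10, 3)), np.zeros((10, 3)),
                              ctl_dur=ctl_d, las_dur=las_d)
        res = duration_test(trials)
        from math import comb

        assert res["p"] == pytest.approx(2.0 / comb(20, 10), rel=1e-9)
        assert res["diff_s"] == pytest.approx(0.1, abs=1e-9)

    def test_single_trial_condition_untestable(self):
        trials = reach_trials(np.zeros((5, 3)), np.zeros((1, 3)))
        assert not duration_test(trials)["testable"]


class TestCountTests:
    @staticmethod
    def _trials(ctl_init, ctl_not, las_init, las_not, ctl_succ=None, las_succ=None):
        rows = []
        tid = 0
        for ttype, n_init, n_not, succ in (("control", ctl_init, ctl_not, ctl_succ),
                                           ("laser_cue", las_init, las_not, las_succ)):
            for k in range(n_init + n_not):
                t0 = 2.0 + 2.0 * tid
                init = k < n_init
                s = bool(succ[k]) if (init and succ is not None) else False
                kw = {}
                if ttype == "laser_cue":
                    kw = dict(laser_on=t0, laser_off=t0 + 2, laser_freq_hz=40.0)
                rows.append(trial_row(
                    trial_id=tid, trial_type=ttype, cue_time=t0,
                    lift_time=t0 + 0.3 if init else np.nan,
                    grab_time=t0 + 0.55 if init else np.nan,
                    reach_initiated=init, success_first=s, success_any=s, **kw))
                tid += 1
        return validate_trials(pd.DataFrame(rows))

    def test_equal_initiation_chi2_zero(self):
        trials = self._trials(20, 30, 20, 30)
        res = initiation_test(trials)
        assert res["chi2"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_initiation_chi2_matches_hand_formula(self):
        trials = self._trials(30, 10, 10, 30)
        res = initiation_test(trials)
        # all expected counts are 20: chi2 = 4 * 100/20 = 20
        assert res["chi2"] == pytest.approx(20.0, rel=1e-12)

    def test_all_initiated_degenerate(self):
        trials = self._trials(20, 0, 20, 0)
        res = initiation_test(trials)
        assert res["degenerate"] and res["p"] == 1.0

    def test_success_chi2_matches_hand_oracle(self):
        ctl = [True] * 40 + [False] * 10
        las = [True] * 25 + [False] * 25
        trials = self._trials(50, 0, 50, 0, ctl_succ=ctl, las_succ=las)
        res = success_test(trials)
        table = np.array([[40, 10], [25, 25]], dtype=float)
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        oracle = ((table - expected) ** 2 / expected).sum()
        assert res["chi2"] == pytest.approx(oracle, rel=1e-12)

    def test_no_initiated_laser_trials_untestable(self):
        trials = self._trials(20, 0, 0, 10)
        assert not success_test(trials)["testable"]


class TestDispersion:
    def test_same_samples_f_one(self):
        rng = np.random.default_rng(4)
        eps = rng.normal([10, 0, 5], 1.0, (20, 3))
        trials = reach_trials(eps, eps)
        hand = hand_with_endpoints(trials, np.vstack([eps, eps]))
        res = dispersion_test(trials, hand)
        np.testing.assert_allclose(res["F"], 1.0, atol=1e-9)
        np.testing.assert_allclose(res["p"], 1.0, atol=1e-9)

    def test_variance_ratio_matches_f_cdf_oracle(self):
        rng = np.random.default_rng(5)
        ctl = rng.normal(0, 1.0, (30, 3))
        las = rng.normal(0, 2.0, (30, 3))
        trials = reach_trials(ctl, las)
        hand = hand_with_endpoints(trials, np.vstack([ctl, las]))
        res = dispersion_test(trials, hand)
        for a in range(3):
            f = np.var(las[:, a], ddof=1) / np.var(ctl[:, a], ddof=1)
            dist = sps.f(29, 29)
            oracle = 2 * min(dist.cdf(f), dist.sf(f))
            assert res["p"][a] == pytest.approx(oracle, rel=1e-9)
        assert res["summed_sd_laser_mm"] == pytest.approx(res["sd_laser_mm"].sum())


class TestStudySummary:
    @staticmethod
    def _summary(session_id, p_endpoint, p_duration=1.0):
        from reachloop.behavior import SessionBehaviorSummary

        return SessionBehaviorSummary(
            session_id=session_id,
            endpoint={"p": np.asarray(p_endpoint, float), "diff_mm": np.zeros(3),
                      "n_control": 20, "n_laser": 20, "testable": True},
            duration={"p": p_duration, "diff_s": 0.0, "testable": True,
                      "median_control_s": 0.25, "median_laser_s": 0.25},
            initiation={"p": 1.0, "chi2": 0.0, "prob_control": 1.0,
                        "prob_laser": 1.0, "testable": True, "degenerate": False},
            success={"p": 1.0, "chi2": 0.0, "rate_control": 0.7,
                     "rate_laser": 0.7, "testable": True, "degenerate": False},
            dispersion={"p": np.ones(3), "F": np.ones(3),
                        "sd_control_mm": np.ones(3), "sd_laser_mm": np.ones(3),
                        "summed_sd_control_mm": 3.0, "summed_sd_laser_mm": 3.0,
                        "testable": True},
        )

    def test_all_p_one_no_effects(self):
        summaries = [self._summary(f"s{i}", [1, 1, 1]) for i in range(10)]
        out = summarize_sessions(summaries)
        assert out["n_any_effect"] == 0

    def test_single_tiny_p_among_45_sessions_flagged_alone(self):
        summaries = [self._summary(f"s{i}", [1, 1, 1]) for i in range(45)]
        summaries[7] = self._summary("s7", [1e-9, 1, 1])
        out = summarize_sessions(summaries)
        assert out["n_any_effect"] == 1
        assert summaries[7].any_effect and summaries[7].effects["endpoint"]
        assert not summaries[8].any_effect

    def test_q_values_match_bh_oracle(self):
        rng = np.random.default_rng(6)
        ps = rng.uniform(0, 1, 45)
        summaries = [self._summary(f"s{i}", [1, 1, 1], p_duration=ps[i])
                     for i in range(45)]
        summarize_sessions(summaries)
        from statsmodels.stats.multitest import multipletests

        q_oracle = multipletests(ps, method="fdr_bh")[1]
        got = np.array([s.q["duration"] for s in summaries])
        np.testing.assert_allclose(got, q_oracle, atol=1e-12)


class TestLabelSwap:
    def test_swapping_conditions_negates_differences(self):
        rng = np.random.default_rng(7)
        ctl = rng.normal([10, 0, 5], 1.0, (15, 3))
        las = rng.normal([12, 0, 5], 1.0, (15, 3))
        trials = reach_trials(ctl, las)
        hand = hand_with_endpoints(trials, np.vstack([ctl, las]))
        res = endpoint_difference(trials, hand)
        swapped = reach_trials(las, ctl)
        hand_sw = hand_with_endpoints(swapped, np.vstack([las, ctl]))
        res_sw = endpoint_difference(swapped, hand_sw)
        np.testing.assert_allclose(res_sw["diff_mm"], -res["diff_mm"], atol=1e-9)
        np.testing.assert_allclose(res_sw["p"], res["p"], atol=1e-12)


class TestFrameOverlay:
    def test_identical_stacks_uniform_hue(self):
        rng = np.random.default_rng(8)
        stack = rng.uniform(0, 0.5, (10, 8, 8))
        comp = frame_overlay(stack, stack)
        # equal orange/blue weighting: R channel equals B channel
        np.testing.assert_allclose(comp[..., 0], comp[..., 2], atol=1e-12)

    def test_laser_only_blob_is_blue_dominated(self):
        ctl = np.zeros((10, 8, 8))
        las = np.zeros((10, 8, 8))
        las[:, 2:4, 2:4] = 0.9
        comp = frame_overlay(ctl, las)
        assert np.all(comp[2:4, 2:4, 2] > comp[2:4, 2:4, 0])
        assert comp[6, 6, 2] == 0.0

    def test_constant_stack_template_is_constant(self):
        ctl = np.full((5, 4, 4), 0.3)
        las = np.zeros((5, 4, 4))
        comp = frame_overlay(ctl, las)
        np.testing.assert_allclose(comp[..., 0], 0.3, atol=1e-12)

    def test_geometry_mismatch_raises(self):
        with pytest.raises(ValueError):
            frame_overlay(np.zeros((3, 4, 4)), np.zeros((3, 5, 5)))
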