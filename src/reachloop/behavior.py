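"""Per-session behavioral effects of laser stimulation.

Five measures per session, each comparing laser-cue against control
trials: (1) per-axis median hand position at grab (rank-sum per
axis), (2) median lift-to-grab duration (rank-sum), (3) probability
of initiating a reach (chi-square), (4) first-attempt success rate
among initiated trials (chi-square), (5) per-axis endpoint standard
deviation (two-sided F-test per axis). Across sessions, p-values are
Benjamini–Hochberg-corrected per measure (axes count as separate
tests within the endpoint and dispersion measures), and a session
shows "any effect" if any q < alpha. A frame-overlay visualization
composites 90th-percentile control/laser pixel templates in
orange/blue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import HandTrajectory, Session
from .stats import bh_qvalues, chi2_test, f_variance_test, rank_sum_p

AXES = ("forward", "left", "up")


def _grab_positions(trials: pd.DataFrame, hand: HandTrajectory) -> np.ndarray:
    """3 × n hand positions at the frame nearest each grab time."""
    grabs = trials["grab_time"].to_numpy(dtype=float)
    grabs = grabs[np.isfinite(grabs)]
    idx = [hand.index_at(g) for g in grabs]
    return hand.position[:, idx]


def _split(trials: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    return trials[trials.trial_type == "control"], trials[trials.trial_type == "laser_cue"]


def endpoint_difference(trials: pd.DataFrame, hand: HandTrajectory | None) -> dict:
    """Per-axis median grab-position difference (laser − control) + rank-sum p."""
    if hand is None:
        raise ValueError("endpoint difference requires a hand trajectory")
    ctl, las = _split(trials)
    pc, pl = _grab_positions(ctl, hand), _grab_positions(las, hand)
    testable = pc.shape[1] >= 3 and pl.shape[1] >= 3
    diff = np.full(3, np.nan)
    p = np.full(3, np.nan)
    if testable:
        diff = np.median(pl, axis=1) - np.median(pc, axis=1)
        p = np.array([rank_sum_p(pl[a], pc[a]) for a in range(3)])
    return {"diff_mm": diff, "p": p, "n_control": pc.shape[1],
            "n_laser": pl.shape[1], "testable": testable}


def duration_test(trials: pd.DataFrame) -> dict:
    """Median lift-to-grab duration per condition + rank-sum p."""
    ctl, las = _split(trials)
    dc = (ctl.grab_time - ctl.lift_time).dropna().to_numpy()
    dl = (las.grab_time - las.lift_time).dropna().to_numpy()
    testable = dc.size >= 3 and dl.size >= 3
    return {
        "median_control_s": float(np.median(dc)) if dc.size else np.nan,
        "median_laser_s": float(np.median(dl)) if dl.size else np.nan,
        "diff_s": float(np.median(dl) - np.median(dc)) if testable else np.nan,
        "p": rank_sum_p(dl, dc) if testable else np.nan,
        "testable": testable,
    }


def initiation_test(trials: pd.DataFrame) -> dict:
    """Reach-initiation probability per condition + chi-square p."""
    ctl, las = _split(trials)
    if len(ctl) == 0 or len(las) == 0:
        return {"prob_control": np.nan, "prob_laser": np.nan, "p": np.nan,
                "chi2": np.nan, "testable": False, "degenerate": True}
    table = np.array(
        [[ctl.reach_initiated.sum(), (~ctl.reach_initiated).sum()],
         [las.reach_initiated.sum(), (~las.reach_initiated).sum()]],
        dtype=float,
    )
    chi2, p, _, degenerate = chi2_test(table)
    return {
        "prob_control": float(ctl.reach_initiated.mean()),
        "prob_laser": float(las.reach_initiated.mean()),
        "chi2": chi2, "p": p, "testable": True, "degenerate": degenerate,
    }


def success_test(trials: pd.DataFrame) -> dict:
    """First-attempt success rate among initiated trials + chi-square p."""
    ctl, las = _split(trials)
    ctl = ctl[ctl.reach_initiated]
    las = las[las.reach_initiated]
    if len(ctl) == 0 or len(las) == 0:
        return {"rate_control": np.nan, "rate_laser": np.nan, "p": np.nan,
                "chi2": np.nan, "testable": False, "degenerate": True}
    table = np.array(
        [[ctl.success_first.sum(), (~ctl.success_first).sum()],
         [las.success_first.sum(), (~las.success_first).sum()]],
        dtype=float,
    )
    chi2, p, _, degenerate = chi2_test(table)
    return {
        "rate_control": float(ctl.success_first.mean()),
        "rate_laser": float(las.success_first.mean()),
        "chi2": chi2, "p": p, "testable": True, "degenerate": degenerate,
    }


def dispersion_test(trials: pd.DataFrame, hand: HandTrajectory | None) -> dict:
    """Per-axis endpoint SD per condition + two-sided F p; summed-SD display."""
    if hand is None:
        raise ValueError("dispersion test requires a hand trajectory")
    ctl, las = _split(trials)
    pc, pl = _grab_positions(ctl, hand), _grab_positions(las, hand)
    testable = pc.shape[1] >= 3 and pl.shape[1] >= 3
    sd_c = np.full(3, np.nan)
    sd_l = np.full(3, np.nan)
    p = np.full(3, np.nan)
    f = np.full(3, np.nan)
    if testable:
        sd_c = pc.std(axis=1, ddof=1)
        sd_l = pl.std(axis=1, ddof=1)
        for a in range(3):
            f[a], p[a] = f_variance_test(pl[a], pc[a])
    return {
        "sd_control_mm": sd_c, "sd_laser_mm": sd_l, "F": f, "p": p,
        "summed_sd_control_mm": float(sd_c.sum()),
        "summed_sd_laser_mm": float(sd_l.sum()),
        "testable": testable,
    }


@dataclass
class SessionBehaviorSummary:
    session_id: str
    endpoint: dict
    duration: dict
    initiation: dict
    success: dict
    dispersion: dict
    q: dict = field(default_factory=dict)  # per measure, arrays or scalars
    effects: dict = field(default_factory=dict)  # per measure, bool
    any_effect: bool = False


def analyze_session(session: Session) -> SessionBehaviorSummary:
    """The five behavioral measures for one session (raw p-values only)."""
    trials = session.trials
    return SessionBehaviorSummary(
        session_id=session.session_id,
        endpoint=endpoint_difference(trials, session.hand),
        duration=duration_test(trials),
        initiation=initiation_test(trials),
        success=success_test(trials),
        dispersion=dispersion_test(trials, session.hand),
    )


def summarize_sessions(
    summaries: list[SessionBehaviorSummary], fdr_alpha: float = 0.05
) -> dict:
    """BH correction per measure across sessions (axes pooled as tests
    within the endpoint and dispersion measures); fills each summary's
    q-values and effect flags and returns study-level tallies."""
    if not summaries:
        raise ValueError("need at least one session")
    n = len(summaries)

    def correct(pmat: np.ndarray) -> np.ndarray:
        return bh_qvalues(pmat.ravel()).reshape(pmat.shape)

    q_end = correct(np.array([s.endpoint["p"] for s in summaries]))
    q_dis = correct(np.array([s.dispersion["p"] for s in summaries]))
    q_dur = correct(np.array([[s.duration["p"]] for s in summaries]))
    q_ini = correct(np.array([[s.initiation["p"]] for s in summaries]))
    q_suc = correct(np.array([[s.success["p"]] for s in summaries]))

    def hit(q) -> bool:
        q = np.atleast_1d(q)
        return bool(np.any(np.isfinite(q) & (q < fdr_alpha)))

    tallies = {m: 0 for m in ("endpoint", "duration", "initiation", "success", "dispersion")}
    for i, s in enumerate(summaries):
        s.q = {
            "endpoint": q_end[i], "duration": float(q_dur[i, 0]),
            "initiation": float(q_ini[i, 0]), "success": float(q_suc[i, 0]),
            "dispersion": q_dis[i],
        }
        s.effects = {m: hit(s.q[m]) for m in tallies}
        s.any_effect = any(s.effects.values())
        for m in tallies:
            tallies[m] += s.effects[m]
    return {
        "n_sessions": n,
        "n_with_effect": {m: int(v) for m, v in tallies.items()},
        "n_any_effect": int(sum(s.any_effect for s in summaries)),
    }


def frame_overlay(
    control_stack: np.ndarray,
    laser_stack: np.ndarray,
    percentile: float = 90.0,
) -> np.ndarray:
    """Composite control/laser frame templates for one lift offset.

    Stacks are trials × H × W intensity arrays in [0, 1] aligned to
    lift. Per pixel, the 90th percentile over trials gives a template
    per condition; the composite weights orange [1, .5, 0] by the
    control template and blue [0, .5, 1] by the laser template,
    clipped to [0, 1]. Returns H × W × 3.
    """
    control_stack = np.asarray(control_stack, dtype=float)
    laser_stack = np.asarray(laser_stack, dtype=float)
    if control_stack.shape[1:] != laser_stack.shape[1:]:
        raise ValueError("control and laser stacks must share frame geometry")
    tc = np.percentile(control_stack, percentile, axis=0)
    tl = np.percentile(laser_stack, percentile, axis=0)
    orange = np.array([1.0, 0.5, 0.0])
    blue = np.array([0.0, 0.5, 1.0])
    comp = tc[..., None] * orange + tl[..., None] * blue
    return np.clip(comp, 0.0, 1.0)
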