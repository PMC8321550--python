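"""Optogenetic tagging, laser/lift response classification, and
sliding-window latency (recruitment) analysis.

Per-unit modulation is assessed with paired signed-rank tests on
event-locked spike counts under Benjamini–Hochberg control across
units; latency uses a rank-sum comparison of a 10 ms window slid in
1 ms steps against pooled pre-pulse windows; group composition of
lift responses is compared with a Pearson chi-square test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import SpikeTrain
from .stats import bh_qvalues, chi2_test, rank_sum_p, signed_rank_p


def _window_counts(times: np.ndarray, events: np.ndarray, w0: float, w1: float) -> np.ndarray:
    """Per-event spike counts in [event + w0, event + w1)."""
    lo = np.searchsorted(times, events + w0, side="left")
    hi = np.searchsorted(times, events + w1, side="left")
    return (hi - lo).astype(float)


@dataclass
class PairedWindowResult:
    unit_ids: list[str]
    p: np.ndarray
    q: np.ndarray
    direction: np.ndarray  # sign of median paired difference
    modulated: np.ndarray
    testable: np.ndarray


def paired_window_test(
    trains: list[SpikeTrain],
    event_times: np.ndarray,
    pre_window: tuple[float, float],
    post_window: tuple[float, float],
    fdr_alpha: float = 0.05,
    min_events: int = 5,
) -> PairedWindowResult:
    """Two-sided signed-rank on paired pre/post event counts, BH across units.

    Units observed on fewer than ``min_events`` events are flagged
    untestable (p = NaN, not counted in the correction).
    """
    events = np.asarray(event_times, dtype=float)
    events = events[np.isfinite(events)]
    n_units = len(trains)
    p = np.full(n_units, np.nan)
    direction = np.zeros(n_units)
    testable = np.full(n_units, events.size >= min_events)
    for i, tr in enumerate(trains):
        if not testable[i]:
            continue
        pre = _window_counts(tr.spike_times, events, *pre_window)
        post = _window_counts(tr.spike_times, events, *post_window)
        p[i] = signed_rank_p(post, pre)
        direction[i] = np.sign(np.median(post - pre))
    q = bh_qvalues(p)
    modulated = np.isfinite(q) & (q < fdr_alpha)
    return PairedWindowResult(
        unit_ids=[t.unit_id for t in trains], p=p, q=q,
        direction=direction, modulated=modulated, testable=testable,
    )


LASER_CLASSES = ("sustained_up", "sustained_down", "transient_up", "transient_down", "none")


def classify_laser_response(
    trains: list[SpikeTrain],
    laser_onsets: np.ndarray,
    laser_duration_s: float = 2.0,
    initial_window_s: float = 0.1,
    fdr_alpha: float = 0.05,
) -> dict:
    """Classify each unit's long-stimulation response.

    Rate changes from the pre-laser baseline (same duration as the
    stimulus) are computed over the full laser window and over its
    first 100 ms; significance of each via BH-corrected paired
    signed-rank tests on per-trial rates. sustained = full-window
    change significant (sign of the full-window change); transient =
    only the initial change significant (sign of the initial change).
    """
    onsets = np.asarray(laser_onsets, dtype=float)
    onsets = onsets[np.isfinite(onsets)]
    n = len(trains)
    d_full = np.zeros(n)
    d_init = np.zeros(n)
    p_full = np.full(n, np.nan)
    p_init = np.full(n, np.nan)
    for i, tr in enumerate(trains):
        base = _window_counts(tr.spike_times, onsets, -laser_duration_s, 0.0) / laser_duration_s
        full = _window_counts(tr.spike_times, onsets, 0.0, laser_duration_s) / laser_duration_s
        init = _window_counts(tr.spike_times, onsets, 0.0, initial_window_s) / initial_window_s
        d_full[i] = np.mean(full - base)
        d_init[i] = np.mean(init - base)
        p_full[i] = signed_rank_p(full, base)
        p_init[i] = signed_rank_p(init, base)
    q_full = bh_qvalues(p_full)
    q_init = bh_qvalues(p_init)
    classes = []
    for i in range(n):
        if np.isfinite(q_full[i]) and q_full[i] < fdr_alpha:
            classes.append("sustained_up" if d_full[i] >= 0 else "sustained_down")
        elif np.isfinite(q_init[i]) and q_init[i] < fdr_alpha:
            classes.append("transient_up" if d_init[i] >= 0 else "transient_down")
        else:
            classes.append("none")
    return {
        "unit_ids": [t.unit_id for t in trains],
        "classes": classes,
        "delta_full_hz": d_full,
        "delta_initial_hz": d_init,
        "q_full": q_full,
        "q_initial": q_init,
    }


@dataclass
class LatencyResult:
    unit_ids: list[str]
    lags_ms: np.ndarray  # window end times
    q: np.ndarray  # units x lags
    first_lag_ms: np.ndarray  # NaN for never-recruited units
    recruitment: np.ndarray  # cumulative fraction of all units recruited
    recruitment_normalized: np.ndarray
    n_responsive: int


def sliding_window_latency(
    trains: list[SpikeTrain],
    pulse_times: np.ndarray,
    window_ms: float = 10.0,
    step_ms: float = 1.0,
    span_ms: tuple[float, float] = (-30.0, 50.0),
    fdr_alpha: float = 0.05,
    min_pulses: int = 10,
) -> LatencyResult:
    """Sliding-window recruitment analysis around stimulation pulses.

    Windows of ``window_ms`` are labeled by their end time, slid in
    ``step_ms`` increments across ``span_ms``. At each lag, per-pulse
    window counts are compared against the pooled counts of all
    windows fully inside the pre-pulse span (rank-sum), with BH across
    units at each lag. A unit's latency is the first lag with
    q < fdr_alpha; the recruitment curve is the cumulative fraction of
    units recruited at or before each lag, and its normalized variant
    divides by the fraction of ever-responsive units.
    """
    pulses = np.asarray(pulse_times, dtype=float)
    if pulses.size < min_pulses:
        raise ValueError(f"need at least {min_pulses} pulses")
    w = window_ms / 1000.0
    lags_ms = np.arange(span_ms[0], span_ms[1] + 0.5 * step_ms, step_ms)
    # pre-pulse reference: all windows fully inside (span_ms[0], 0)
    pre_ends = lags_ms[(lags_ms - window_ms >= span_ms[0]) & (lags_ms <= 0.0)]
    n_units, n_lags = len(trains), lags_ms.size
    p = np.full((n_units, n_lags), np.nan)
    for i, tr in enumerate(trains):
        pre_counts = np.concatenate(
            [_window_counts(tr.spike_times, pulses, (e - window_ms) / 1000.0, e / 1000.0)
             for e in pre_ends]
        )
        for j, lag in enumerate(lags_ms):
            counts = _window_counts(
                tr.spike_times, pulses, (lag - window_ms) / 1000.0, lag / 1000.0
            )
            p[i, j] = rank_sum_p(counts, pre_counts, method="asymptotic")
    q = np.stack([bh_qvalues(p[:, j]) for j in range(n_lags)], axis=1)
    sig = np.isfinite(q) & (q < fdr_alpha)
    first_lag = np.full(n_units, np.nan)
    for i in range(n_units):
        hits = np.flatnonzero(sig[i])
        if hits.size:
            first_lag[i] = lags_ms[hits[0]]
    recruited = np.array(
        [np.mean(np.nan_to_num(first_lag, nan=np.inf) <= lag) for lag in lags_ms]
    )
    n_responsive = int(np.isfinite(first_lag).sum())
    frac_responsive = n_responsive / n_units if n_units else 0.0
    normalized = recruited / frac_responsive if frac_responsive > 0 else np.zeros_like(recruited)
    return LatencyResult(
        unit_ids=[t.unit_id for t in trains], lags_ms=lags_ms, q=q,
        first_lag_ms=first_lag, recruitment=recruited,
        recruitment_normalized=normalized, n_responsive=n_responsive,
    )


def classify_lift_modulation(
    lift_result: PairedWindowResult, tagged: np.ndarray
) -> dict:
    """Per-unit lift response class and tagged-vs-untagged composition.

    Classes from the paired lift-window test (increase / decrease /
    none); the 2 × 3 contingency table (tagged × class) is compared
    with a Pearson chi-square test. An expected cell count < 1 sets a
    low-count warning flag.
    """
    tagged = np.asarray(tagged, dtype=bool)
    classes = np.where(
        lift_result.modulated,
        np.where(lift_result.direction > 0, "increase", "decrease"),
        "none",
    )
    table = np.zeros((2, 3))
    order = ("increase", "decrease", "none")
    for g, is_tag in enumerate((True, False)):
        for c, name in enumerate(order):
            table[g, c] = np.sum((tagged == is_tag) & (classes == name))
    chi2, p, dof, degenerate = chi2_test(table)
    low_count = False
    if not degenerate:
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        low_count = bool(np.any(expected < 1.0))
    return {
        "unit_ids": lift_result.unit_ids,
        "classes": classes.tolist(),
        "table": table,
        "class_order": order,
        "chi2": chi2,
        "p": p,
        "dof": dof,
        "low_count_warning": low_count or degenerate,
    }
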