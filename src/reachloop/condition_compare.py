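"""Control-vs-laser population similarity and superposition prediction.

All comparisons operate on baseline z-scored firing rates (not raw
rates, whose correlated baselines would dominate). Similarity is
quantified by Spearman correlations (a) across units at each time
point between condition-average z-scores, and (b) over time per unit;
per-unit significance uses the large-sample normal approximation to
the permutation null (rho·sqrt(n−1) ~ N(0,1)). The superposition
prediction shifts each unit's laser-only z-score response by the
per-trial lift-to-laser delay and averages, predicting the laser −
control difference expected if task and laser responses added
linearly.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .stats import bh_qvalues, spearman_normal_p, spearman_rho


def timepoint_correlation(
    z_control: np.ndarray, z_laser: np.ndarray, fdr_alpha: float = 0.05
) -> dict:
    """Across-unit Spearman rho at each time point, BH across time.

    Inputs are units × time condition-average z-scores over matched
    unit sets (>= 5 units).
    """
    z_control = np.asarray(z_control, float)
    z_laser = np.asarray(z_laser, float)
    if z_control.shape != z_laser.shape:
        raise ValueError("condition matrices must have matching shape")
    n_units, n_t = z_control.shape
    if n_units < 5:
        raise ValueError("need at least 5 units")
    rho = np.full(n_t, np.nan)
    p = np.full(n_t, np.nan)
    for j in range(n_t):
        r = spearman_rho(z_control[:, j], z_laser[:, j])
        rho[j] = r
        if np.isfinite(r):
            # large-sample t approximation for Spearman's rho
            res = sps.spearmanr(z_control[:, j], z_laser[:, j])
            p[j] = float(res.pvalue)
    q = bh_qvalues(p)
    return {"rho": rho, "p": p, "q": q,
            "significant": np.isfinite(q) & (q < fdr_alpha)}


def per_unit_correlation(
    z_control: np.ndarray, z_laser: np.ndarray, fdr_alpha: float = 0.05
) -> dict:
    """Per-unit Spearman rho over the whole peri-event window, BH
    across units; constant curves give NaN with a flag."""
    z_control = np.asarray(z_control, float)
    z_laser = np.asarray(z_laser, float)
    if z_control.shape != z_laser.shape:
        raise ValueError("condition matrices must have matching shape")
    n_units, n_t = z_control.shape
    rho = np.array([spearman_rho(z_control[i], z_laser[i]) for i in range(n_units)])
    p = np.array([spearman_normal_p(rho[i], n_t) for i in range(n_units)])
    q = bh_qvalues(p)
    ok = np.isfinite(rho)
    return {
        "rho": rho, "p": p, "q": q,
        "significant": np.isfinite(q) & (q < fdr_alpha),
        "undefined": ~ok,
        "median_rho": float(np.median(rho[ok])) if ok.any() else np.nan,
        "n_positive": int(np.sum(rho[ok] > 0)),
        "n_defined": int(ok.sum()),
    }


def predict_laser_difference(
    z_laser_only: np.ndarray,
    t_laser: np.ndarray,
    delays_s: np.ndarray,
    t_out: np.ndarray,
) -> np.ndarray:
    """Superposition prediction of the laser − control z difference.

    ``z_laser_only`` is units × time on the peri-laser-onset grid
    ``t_laser`` (seconds relative to laser onset), z-scored against
    the pre-lift baseline. For each laser trial with lift-to-laser
    delay d = lift − laser_on, the curve is placed on the peri-lift
    output grid ``t_out`` as z(t + d), padded with 0 (baseline z)
    where shifted out of window, then averaged across trials.
    """
    z = np.atleast_2d(np.asarray(z_laser_only, float))
    delays = np.atleast_1d(np.asarray(delays_s, float))
    if delays.size == 0:
        raise ValueError("need at least one laser trial delay")
    dt = t_laser[1] - t_laser[0]
    out = np.zeros((z.shape[0], t_out.size))
    for d in delays:
        idx = np.round((t_out + d - t_laser[0]) / dt).astype(int)
        valid = (idx >= 0) & (idx < t_laser.size)
        shifted = np.zeros((z.shape[0], t_out.size))
        shifted[:, valid] = z[:, idx[valid]]
        out += shifted
    return out / delays.size


def correlate_predicted_observed(
    predicted: np.ndarray, observed: np.ndarray, fdr_alpha: float = 0.05
) -> dict:
    """Across-unit Spearman rho(t) between predicted and observed
    laser − control z differences, BH over time points."""
    return timepoint_correlation(predicted, observed, fdr_alpha)
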