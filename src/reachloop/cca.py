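"""Canonical correlation analysis between simultaneously recorded
cortical and DCN population activity.

The first four PC dimensions per region are concatenated over all
control and laser trials in the [lift − 100 ms, lift + 300 ms]
window, standardized, and mean-centered; classical CCA (whitening of
each region followed by an SVD of the cross-correlation) yields
canonical variates whose scores are maximally correlated across
regions. Variance accounting follows the standardized-variables
convention: the fraction of a region's standardized sample variance
explained by its i-th canonical variate is ‖corr(X, U_i)‖²/p (these
sum to 1 over the complete set), and the fraction explained in the
opposite region is that own-region fraction times the squared
canonical correlation. Comparing the totals between laser-only and
matched-control CCAs quantifies whether the perturbation degrades
cross-region similarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .data_model import Session
from .decoding import (
    _window_samples,
    fit_pca,
    pc_scores,
    region_zscores,
    regular_interval_indices,
    select_trials,
    trial_average_z,
)


@dataclass
class CCAResult:
    weights_a: np.ndarray  # p x p, columns map standardized PCs -> variates
    weights_b: np.ndarray
    canonical_corrs: np.ndarray  # non-increasing, in [0, 1]
    scores_a: np.ndarray  # variates x samples, unit variance each
    scores_b: np.ndarray
    varexp_own_a: np.ndarray
    varexp_own_b: np.ndarray
    varexp_opp_a: np.ndarray  # variance of A explained by B's variates
    varexp_opp_b: np.ndarray

    @property
    def total_opposite_a(self) -> float:
        """Total fraction of region A variance explained by region B."""
        return float(self.varexp_opp_a.sum())

    @property
    def total_opposite_b(self) -> float:
        return float(self.varexp_opp_b.sum())


def concat_center_scores(
    pc_scores_by_trial: list[np.ndarray], standardize: bool = True
) -> np.ndarray:
    """Concatenate per-trial PC scores (p × samples each) and center
    each dimension over the concatenation; optionally scale each
    dimension to unit variance (the standardized-variance convention)."""
    if not pc_scores_by_trial:
        raise ValueError("need at least one trial")
    X = np.concatenate(pc_scores_by_trial, axis=1)
    X = X - X.mean(axis=1, keepdims=True)
    if standardize:
        sd = X.std(axis=1)
        if np.any(sd == 0):
            raise ValueError(f"degenerate (constant) dimensions: {np.flatnonzero(sd == 0)}")
        X = X / sd[:, None]
    return X


def fit_cca(x_a: np.ndarray, x_b: np.ndarray) -> CCAResult:
    """Classical CCA of two centered p × N matrices.

    Whitens each region by the inverse symmetric square root of its
    covariance and takes the SVD of the whitened cross-covariance;
    correlations are returned descending, scores have unit variance,
    and each pair's correlation is non-negative (sign convention:
    score A's largest-magnitude weight is positive).
    """
    x_a = np.asarray(x_a, float)
    x_b = np.asarray(x_b, float)
    n = x_a.shape[1]
    if x_b.shape[1] != n:
        raise ValueError("regions must share the sample axis")
    if n <= x_a.shape[0] + x_b.shape[0]:
        raise ValueError("need more samples than total dimensions")

    def inv_sqrt(S: np.ndarray, name: str) -> np.ndarray:
        w, V = np.linalg.eigh(S)
        if np.any(w < 1e-10 * w.max()):
            raise ValueError(
                f"rank-deficient region {name}: degenerate dimensions "
                f"{np.flatnonzero(w < 1e-10 * w.max())}"
            )
        return V @ np.diag(1.0 / np.sqrt(w)) @ V.T

    Saa = x_a @ x_a.T / (n - 1)
    Sbb = x_b @ x_b.T / (n - 1)
    Sab = x_a @ x_b.T / (n - 1)
    Wa = inv_sqrt(Saa, "A")
    Wb = inv_sqrt(Sbb, "B")
    U, s, Vt = np.linalg.svd(Wa @ Sab @ Wb)
    A = Wa @ U  # columns: weights on region A
    B = Wb @ Vt.T
    # sign convention for reproducible scores
    for j in range(A.shape[1]):
        if A[np.argmax(np.abs(A[:, j])), j] < 0:
            A[:, j] *= -1
            B[:, j] *= -1
    scores_a = A.T @ x_a
    scores_b = B.T @ x_b
    corrs = np.clip(s, 0.0, 1.0)

    p_a, p_b = x_a.shape[0], x_b.shape[0]
    # corr(X_k, U_i) = (Saa A)_ki / sd(X_k); scores already unit variance
    sd_a = np.sqrt(np.diag(Saa))
    sd_b = np.sqrt(np.diag(Sbb))
    load_a = (Saa @ A) / sd_a[:, None]
    load_b = (Sbb @ B) / sd_b[:, None]
    own_a = (load_a**2).sum(axis=0) / p_a
    own_b = (load_b**2).sum(axis=0) / p_b
    return CCAResult(
        weights_a=A, weights_b=B, canonical_corrs=corrs,
        scores_a=scores_a, scores_b=scores_b,
        varexp_own_a=own_a, varexp_own_b=own_b,
        varexp_opp_a=own_a * corrs**2, varexp_opp_b=own_b * corrs**2,
    )


def variance_explained(result: CCAResult) -> dict:
    """Cumulative own-/opposite-region variance-explained tables."""
    return {
        "own_a": result.varexp_own_a,
        "own_b": result.varexp_own_b,
        "opp_a": result.varexp_opp_a,
        "opp_b": result.varexp_opp_b,
        "cum_own_a": np.cumsum(result.varexp_own_a),
        "cum_own_b": np.cumsum(result.varexp_own_b),
        "cum_opp_a": np.cumsum(result.varexp_opp_a),
        "cum_opp_b": np.cumsum(result.varexp_opp_b),
        "total_opp_a": result.total_opposite_a,
        "total_opp_b": result.total_opposite_b,
    }


def _trial_scores(activity, pca, n_dims, trials, fs) -> list[np.ndarray]:
    scores = pc_scores(activity, pca, n_dims)
    return [
        scores[:, _window_samples(activity.t, L, fs)]
        for L in trials.lift_time.to_numpy()
    ]


def session_cca(
    session: Session,
    regions: tuple[str, str] = ("CTX", "DCN"),
    n_dims: int = 4,
    config: AnalysisConfig | None = None,
    trial_subset: str = "all",
) -> CCAResult:
    """CCA between two regions' PC scores over lift-window activity.

    ``trial_subset``: "all" (control + laser, PCA from control trial
    averages as in the decoder), "laser" or "control_matched" (both
    with PCA from the mean of the control and laser trial averages,
    the balanced-decoder convention; the matched-control variant uses
    as many regularly spaced control trials as there are laser
    trials).
    """
    config = config or session.config
    selected = select_trials(session.trials)
    fs = session.hand.sample_rate_hz
    inc = selected[selected.include]
    ctl = inc[inc.trial_type == "control"].reset_index(drop=True)
    las = inc[inc.trial_type == "laser_cue"].reset_index(drop=True)
    if trial_subset == "laser" or trial_subset == "control_matched":
        if len(las) < 2:
            raise ValueError("need at least 2 included laser trials")
    mats = []
    for region in regions:
        activity = region_zscores(session, region, config, selected)
        if trial_subset == "all":
            avg = trial_average_z(activity, ctl.lift_time.to_numpy(), fs)
            use = pd.concat([ctl, las])
        else:
            avg = 0.5 * (
                trial_average_z(activity, ctl.lift_time.to_numpy(), fs)
                + trial_average_z(activity, las.lift_time.to_numpy(), fs)
            )
            if trial_subset == "laser":
                use = las
            else:
                use = ctl.iloc[regular_interval_indices(len(ctl), len(las))]
        pca = fit_pca(avg)
        if pca.components_.shape[0] < n_dims:
            raise ValueError(f"region {region} has fewer than {n_dims} PC dimensions")
        mats.append(concat_center_scores(_trial_scores(activity, pca, n_dims, use, fs)))
    return fit_cca(mats[0], mats[1])


def compare_laser_control_cca(
    session: Session,
    regions: tuple[str, str] = ("CTX", "DCN"),
    n_dims: int = 4,
    config: AnalysisConfig | None = None,
) -> dict:
    """Laser-only vs matched-control CCA similarity totals per region."""
    laser = session_cca(session, regions, n_dims, config, trial_subset="laser")
    control = session_cca(session, regions, n_dims, config, trial_subset="control_matched")
    return {
        "laser_total_opp_a": laser.total_opposite_a,
        "laser_total_opp_b": laser.total_opposite_b,
        "control_total_opp_a": control.total_opposite_a,
        "control_total_opp_b": control.total_opposite_b,
        "diff_a": laser.total_opposite_a - control.total_opposite_a,
        "diff_b": laser.total_opposite_b - control.total_opposite_b,
    }
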