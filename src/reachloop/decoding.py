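"""Lagged linear decoding of 3D hand velocity from PCA-reduced
multiunit activity.

Channel rates (σ = 25 ms smoothed spike counts, or carried rate
matrices) on the 500 Hz kinematic clock are z-scored against rest
(the 1.5 s preceding each trial start); channels with mean |z| > 100
during movement are dropped as artifactual. PCA is fit on the
lift-aligned trial-averaged control activity; the decoder regresses
velocity at each 2 ms sample on the 15 most recent PC-score samples
(28 ms of history) plus an intercept. The number of PCA dimensions is
chosen by fourfold cross-validation over training trials: the
smallest count whose mean held-out MSE is within 1% of the overall
minimum, with coefficients averaged across folds. Variants: a
balanced decoder trained on all odd laser trials plus an equal number
of regularly spaced control trials (PCA from the mean of the two
conditions' trial averages, 5 dimensions fixed), and an augmented
decoder on the concatenated CTX+DCN PC scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .config import AnalysisConfig
from .data_model import Session
from .signal_prep import bin_spikes, hand_velocity, smooth_rate

#: analysis window around lift, seconds
LIFT_WINDOW = (-0.1, 0.3)


def select_trials(trials: pd.DataFrame, min_laser: int = 2,
                  laser_margin_s: float = 0.3) -> pd.DataFrame:
    """Trial inclusion for decoding, with machine-readable reasons.

    Included trials must have a complete lift→grab sequence; laser
    trials additionally require it to fall inside the laser window
    with lift at least 300 ms before laser offset; control trials on
    table sessions must complete within 2 s of the cue (post sessions
    also allow lifts up to 0.5 s before the cue). Returns a copy with
    ``include`` and ``reason`` columns, plus a ``session_flagged``
    attribute in ``df.attrs`` when fewer than ``min_laser`` laser
    trials survive.
    """
    out = trials.copy().reset_index(drop=True)
    include = np.zeros(len(out), dtype=bool)
    reason = np.array(["included"] * len(out), dtype=object)
    for i, row in enumerate(out.itertuples(index=False)):
        if row.trial_type == "laser_only":
            reason[i] = "laser_only"
            continue
        if not row.reach_initiated or not np.isfinite(row.lift_time):
            reason[i] = "no_reach"
            continue
        if not np.isfinite(row.grab_time):
            reason[i] = "no_grab"
            continue
        if row.trial_type == "laser_cue":
            if not (row.lift_time >= row.laser_on and row.grab_time <= row.laser_off):
                reason[i] = "outside_laser"
                continue
            if row.lift_time > row.laser_off - laser_margin_s:
                reason[i] = "late_lift"
                continue
        else:  # control
            early_ok = row.cue_time - (0.5 if row.delivery_mode == "post" else 0.0)
            if not (row.lift_time >= early_ok and row.grab_time <= row.cue_time + 2.0):
                reason[i] = "atypical_control"
                continue
        include[i] = True
    out["include"] = include
    out["reason"] = reason
    n_laser = int(np.sum(include & (out.trial_type == "laser_cue").to_numpy()))
    out.attrs["session_flagged"] = n_laser < min_laser
    return out


def regular_interval_indices(n: int, m: int) -> np.ndarray:
    """m regularly spaced 0-based indices out of n: floor(j·n/m)."""
    if m > n:
        raise ValueError("cannot sample more indices than available")
    return (np.arange(m) * n // m).astype(int)


@dataclass
class RegionActivity:
    """Z-scored channel activity for one region on the kinematic clock."""

    region: str
    t: np.ndarray
    z: np.ndarray  # kept channels x T
    kept_channels: np.ndarray
    dropped_channels: np.ndarray


def region_zscores(
    session: Session, region: str, config: AnalysisConfig | None = None,
    selected: pd.DataFrame | None = None, artifact_z: float = 100.0,
) -> RegionActivity:
    """Rest-z-scored channel rates for a region.

    Rates come from the session's carried rate matrix when present,
    otherwise from σ = 25 ms smoothing of the region's multiunit spike
    trains binned on the kinematic clock. Rest is the 1.5 s preceding
    each trial start (cue, or laser onset when there is no cue).
    """
    config = config or session.config
    if session.hand is None:
        raise ValueError("decoding requires a hand trajectory")
    t = session.hand.t
    dt = 1.0 / session.hand.sample_rate_hz
    if region in session.rates:
        # carried rate matrices get the same decode-grade kernel as
        # spike counts, so both inputs see identical temporal filtering
        from .signal_prep import gaussian_kernel

        k = gaussian_kernel(config.decode_kernel_sigma_s, dt)
        half = k.size // 2
        padded = np.pad(session.rates[region].values, ((0, 0), (half, half)), mode="edge")
        rates = np.vstack([np.convolve(row, k, mode="valid") for row in padded])
    else:
        mus = session.units(region=region, multiunit=True)
        if not mus:
            raise ValueError(f"no multiunit channels or rate matrix for region {region}")
        rates = np.vstack([
            smooth_rate(bin_spikes(u, t[0], t[-1] + dt, dt), dt, config.decode_kernel_sigma_s)
            for u in mus
        ])[:, : t.size]

    starts = session.trials["cue_time"].to_numpy(dtype=float)
    lasers = session.trials["laser_on"].to_numpy(dtype=float)
    starts = np.where(np.isfinite(starts), starts, lasers)
    rest = np.zeros(t.size, dtype=bool)
    for s in starts[np.isfinite(starts)]:
        rest |= (t >= s - 1.5) & (t < s)
    if not rest.any():
        raise ValueError("no rest samples before trial starts")
    mean = rates[:, rest].mean(axis=1)
    sd = np.maximum(rates[:, rest].std(axis=1), 1e-6)
    z = (rates - mean[:, None]) / sd[:, None]

    if selected is None:
        selected = select_trials(session.trials)
    move = np.zeros(t.size, dtype=bool)
    for row in selected[selected.include].itertuples(index=False):
        move |= (t >= row.lift_time + LIFT_WINDOW[0]) & (t < row.lift_time + LIFT_WINDOW[1])
    if move.any():
        bad = np.abs(z[:, move]).mean(axis=1) > artifact_z
    else:
        bad = np.zeros(z.shape[0], dtype=bool)
    if bad.all():
        raise ValueError("all channels excluded by the artifact rule")
    return RegionActivity(
        region=region, t=t, z=z[~bad],
        kept_channels=np.flatnonzero(~bad), dropped_channels=np.flatnonzero(bad),
    )


def _window_samples(t: np.ndarray, lift: float, fs: float) -> np.ndarray:
    i0 = int(round((lift + LIFT_WINDOW[0] - t[0]) * fs))
    n = int(round((LIFT_WINDOW[1] - LIFT_WINDOW[0]) * fs))
    return np.arange(i0, i0 + n)


def trial_average_z(
    activity: RegionActivity, lifts: np.ndarray, fs: float
) -> np.ndarray:
    """Lift-aligned trial-averaged z: channels × window samples."""
    wins = [_window_samples(activity.t, L, fs) for L in lifts]
    return np.mean([activity.z[:, w] for w in wins], axis=0)


def fit_pca(trial_avg: np.ndarray, n_components: int | None = None) -> PCA:
    """PCA of lift-aligned trial-averaged activity (samples × channels)."""
    n_max = min(trial_avg.shape)
    pca = PCA(n_components=min(n_components or n_max, n_max), svd_solver="full")
    pca.fit(trial_avg.T)
    return pca


@dataclass
class DecoderModel:
    region: str
    variant: str
    pca_mean: np.ndarray
    pca_components: np.ndarray  # n_dims x channels
    n_dims: int
    n_taps: int
    tap_dt_s: float
    coefficients: np.ndarray  # (n_dims*n_taps + 1) x 3, last row = intercept
    train_trial_ids: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    test_trial_ids: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    rank_deficient: bool = False

    @property
    def history_span_s(self) -> float:
        """Age of the oldest tap: (n_taps − 1) · tap_dt."""
        return (self.n_taps - 1) * self.tap_dt_s


def pc_scores(activity: RegionActivity, pca: PCA, n_dims: int) -> np.ndarray:
    """PC scores of the full-session z matrix: n_dims × T."""
    return (pca.components_[:n_dims] @ (activity.z - pca.mean_[:, None]))


def build_features(
    scores: np.ndarray, sample_idx: np.ndarray, n_taps: int = 15
) -> np.ndarray:
    """Lagged feature rows: PC scores at taps 0..n_taps−1 samples back.

    Row for sample s is [scores[:, s], scores[:, s−1], ...,
    scores[:, s−(n_taps−1)]] flattened dimension-major; lag history may
    reach before the trial window (the recording exists there).
    """
    d = scores.shape[0]
    F = np.empty((sample_idx.size, d * n_taps))
    for tap in range(n_taps):
        F[:, tap * d:(tap + 1) * d] = scores[:, sample_idx - tap].T
    return F


def fit_decoder(features: np.ndarray, targets: np.ndarray) -> tuple[np.ndarray, bool]:
    """OLS with intercept per axis; least-norm on rank deficiency.

    Returns (coefficients (p+1) × 3 with intercept last, rank_deficient).
    """
    A = np.column_stack([features, np.ones(features.shape[0])])
    coef, _, rank, _ = np.linalg.lstsq(A, targets, rcond=None)
    return coef, rank < A.shape[1]


def predict(coef: np.ndarray, features: np.ndarray) -> np.ndarray:
    return features @ coef[:-1] + coef[-1]


def pooled_r2(pred: np.ndarray, obs: np.ndarray) -> tuple[float, np.ndarray]:
    """R² = 1 − SSE/SST with axes pooled, plus per-axis values."""
    obs = np.asarray(obs, float)
    pred = np.asarray(pred, float)
    sse = ((obs - pred) ** 2).sum(axis=0)
    sst = ((obs - obs.mean(axis=0)) ** 2).sum(axis=0)
    per_axis = np.where(sst > 0, 1.0 - sse / np.maximum(sst, 1e-300), np.nan)
    if sst.sum() == 0:
        return np.nan, per_axis
    return float(1.0 - sse.sum() / sst.sum()), per_axis


def select_dim_from_mse(
    mse: np.ndarray, tolerance: float = 0.01, target_var: float | None = None
) -> int:
    """Smallest dimension count whose mean MSE is within ``tolerance``
    (multiplicative) of the overall minimum.

    MSEs below 1e-10 of the target variance are clamped before the
    comparison: residuals that small are numerically indistinguishable
    (exactly collinear extra dimensions produce machine-noise ratios),
    and the clamp is inert for any data with a genuine noise floor.
    Returns the 1-based dimension count.
    """
    mse = np.asarray(mse, dtype=float)
    if target_var is not None and target_var > 0:
        mse = np.maximum(mse, 1e-10 * target_var)
    best = np.nanmin(mse)
    return int(np.flatnonzero(mse <= (1.0 + tolerance) * best)[0]) + 1


def cv_select_dims(
    scores_by_dim: np.ndarray,
    trial_sample_idx: list[np.ndarray],
    targets_by_trial: list[np.ndarray],
    max_dims: int,
    n_taps: int = 15,
    k: int = 4,
    tolerance: float = 0.01,
) -> tuple[int, np.ndarray, np.ndarray]:
    """Fourfold CV over trials; smallest dim count within 1% of the
    minimum mean held-out MSE; coefficients averaged over folds.

    Returns (n_dims, averaged coefficients, mean MSE per dim count).
    """
    n_trials = len(trial_sample_idx)
    if n_trials < k:
        raise ValueError(f"need at least {k} training trials")
    folds = [np.arange(n_trials)[j::k] for j in range(k)]
    mse = np.full(max_dims, np.nan)
    coefs: dict[int, list[np.ndarray]] = {d: [] for d in range(1, max_dims + 1)}
    for d in range(1, max_dims + 1):
        errs = []
        for fold in folds:
            train = np.setdiff1d(np.arange(n_trials), fold)
            Ftr = np.vstack([
                build_features(scores_by_dim[:d], trial_sample_idx[i], n_taps)
                for i in train
            ])
            ytr = np.vstack([targets_by_trial[i] for i in train])
            coef, _ = fit_decoder(Ftr, ytr)
            coefs[d].append(coef)
            Fte = np.vstack([
                build_features(scores_by_dim[:d], trial_sample_idx[i], n_taps)
                for i in fold
            ])
            yte = np.vstack([targets_by_trial[i] for i in fold])
            errs.append(np.mean((predict(coef, Fte) - yte) ** 2))
        mse[d - 1] = np.mean(errs)
    y_all = np.vstack(targets_by_trial)
    n_dims = select_dim_from_mse(mse, tolerance, float(y_all.var()))
    coef = np.mean(coefs[n_dims], axis=0)
    return n_dims, coef, mse


@dataclass
class DecodeResult:
    model: DecoderModel
    r2_control_test: float
    r2_laser: float
    r2_control_test_axes: np.ndarray
    r2_laser_axes: np.ndarray
    mse_by_dim: np.ndarray | None = None
    session_flagged: bool = False


def _prepare(session: Session, region: str, config: AnalysisConfig | None):
    config = config or session.config
    selected = select_trials(session.trials)
    activity = region_zscores(session, region, config, selected)
    fs = session.hand.sample_rate_hz
    vel, _ = hand_velocity(session.hand, config.decode_kernel_sigma_s)
    inc = selected[selected.include]
    ctl = inc[inc.trial_type == "control"].reset_index(drop=True)
    las = inc[inc.trial_type == "laser_cue"].reset_index(drop=True)
    return config, selected, activity, fs, vel, ctl, las


def _trial_data(activity, vel, trials, fs):
    idx = [_window_samples(activity.t, L, fs) for L in trials.lift_time.to_numpy()]
    targets = [vel[:, w].T for w in idx]
    return idx, targets


def fit_standard_decoder(
    session: Session, region: str, config: AnalysisConfig | None = None,
    max_dims: int = 8,
) -> DecodeResult:
    """Control-trained decoder with CV-selected PCA dimensionality.

    Every 5th included control trial (time order) is held out as the
    control-test set; PCA is fit on the lift-aligned trial average of
    the remaining (training) control trials.
    """
    config, selected, activity, fs, vel, ctl, las = _prepare(session, region, config)
    test_mask = np.zeros(len(ctl), dtype=bool)
    test_mask[4::5] = True
    train_ctl, test_ctl = ctl[~test_mask], ctl[test_mask]

    avg = trial_average_z(activity, train_ctl.lift_time.to_numpy(), fs)
    pca = fit_pca(avg)
    max_dims = min(max_dims, pca.components_.shape[0])
    scores = pc_scores(activity, pca, max_dims)

    tr_idx, tr_y = _trial_data(activity, vel, train_ctl, fs)
    n_dims, coef, mse = cv_select_dims(
        scores, tr_idx, tr_y, max_dims, config.decoder_n_taps
    )
    model = DecoderModel(
        region=region, variant="standard", pca_mean=pca.mean_,
        pca_components=pca.components_[:n_dims], n_dims=n_dims,
        n_taps=config.decoder_n_taps, tap_dt_s=config.decoder_feature_dt_s,
        coefficients=coef,
        train_trial_ids=train_ctl.trial_id.to_numpy(),
        test_trial_ids=test_ctl.trial_id.to_numpy(),
    )
    return _evaluate(model, activity, vel, fs, test_ctl, las,
                     selected.attrs.get("session_flagged", False), mse)


def _evaluate(model, activity, vel, fs, test_ctl, las, flagged, mse=None) -> DecodeResult:
    scores = model.pca_components @ (activity.z - model.pca_mean[:, None])

    def score_set(trials):
        if len(trials) == 0:
            return np.nan, np.full(3, np.nan)
        idx, ys = _trial_data(activity, vel, trials, fs)
        F = np.vstack([build_features(scores, w, model.n_taps) for w in idx])
        return pooled_r2(predict(model.coefficients, F), np.vstack(ys))

    r2c, r2c_ax = score_set(test_ctl)
    r2l, r2l_ax = score_set(las)
    return DecodeResult(
        model=model, r2_control_test=r2c, r2_laser=r2l,
        r2_control_test_axes=r2c_ax, r2_laser_axes=r2l_ax,
        mse_by_dim=mse, session_flagged=flagged,
    )


def fit_balanced_decoder(
    session: Session, region: str, config: AnalysisConfig | None = None,
    n_dims: int = 5,
) -> DecodeResult:
    """Decoder trained on all odd laser trials plus a matching number
    of regularly spaced control trials; PCA from the mean of the two
    conditions' lift-aligned trial averages; dimensionality fixed."""
    config, selected, activity, fs, vel, ctl, las = _prepare(session, region, config)
    if len(las) < 2:
        raise ValueError("balanced decoder needs at least 2 included laser trials")
    odd = np.arange(len(las)) % 2 == 0  # 1st, 3rd, ... in time order
    train_las, test_las = las[odd], las[~odd]
    m = min(len(train_las), len(ctl))
    ctl_train_idx = regular_interval_indices(len(ctl), m)
    train_ctl = ctl.iloc[ctl_train_idx]
    test_ctl = ctl.drop(ctl.index[ctl_train_idx])

    avg = 0.5 * (
        trial_average_z(activity, train_las.lift_time.to_numpy(), fs)
        + trial_average_z(activity, train_ctl.lift_time.to_numpy(), fs)
    )
    pca = fit_pca(avg)
    n_dims = min(n_dims, pca.components_.shape[0])
    scores = pc_scores(activity, pca, n_dims)

    train = pd.concat([train_ctl, train_las]).sort_values("trial_id")
    idx, ys = _trial_data(activity, vel, train, fs)
    F = np.vstack([build_features(scores, w, config.decoder_n_taps) for w in idx])
    coef, rank_def = fit_decoder(F, np.vstack(ys))
    model = DecoderModel(
        region=region, variant="balanced", pca_mean=pca.mean_,
        pca_components=pca.components_[:n_dims], n_dims=n_dims,
        n_taps=config.decoder_n_taps, tap_dt_s=config.decoder_feature_dt_s,
        coefficients=coef, rank_deficient=rank_def,
        train_trial_ids=train.trial_id.to_numpy(),
        test_trial_ids=np.concatenate(
            [test_ctl.trial_id.to_numpy(), test_las.trial_id.to_numpy()]
        ),
    )
    return _evaluate(model, activity, vel, fs, test_ctl, test_las,
                     selected.attrs.get("session_flagged", False))


def fit_augmented_decoder(
    session: Session, config: AnalysisConfig | None = None,
    regions: tuple[str, str] = ("CTX", "DCN"), max_dims: int = 8,
) -> DecodeResult:
    """CTX+DCN decoder on concatenated per-region PC scores.

    Each region contributes its own standard-decoder PCA and selected
    dimensionality; training/test splits match the single-region
    decoders (all regions must be simultaneously recorded).
    """
    config = config or session.config
    for r in regions:
        if r not in session.rates and not session.units(region=r, multiunit=True):
            raise ValueError(f"augmented decoder requires simultaneous {r} activity")
    singles = [fit_standard_decoder(session, r, config, max_dims) for r in regions]
    selected = select_trials(session.trials)
    acts = [region_zscores(session, r, config, selected) for r in regions]
    fs = session.hand.sample_rate_hz
    vel, _ = hand_velocity(session.hand, config.decode_kernel_sigma_s)
    scores = np.vstack([
        res.model.pca_components @ (a.z - res.model.pca_mean[:, None])
        for res, a in zip(singles, acts)
    ])
    inc = selected[selected.include]
    ctl = inc[inc.trial_type == "control"].reset_index(drop=True)
    las = inc[inc.trial_type == "laser_cue"].reset_index(drop=True)
    test_mask = np.zeros(len(ctl), dtype=bool)
    test_mask[4::5] = True
    train_ctl, test_ctl = ctl[~test_mask], ctl[test_mask]
    idx, ys = _trial_data(acts[0], vel, train_ctl, fs)
    # fold-averaged coefficients with the same fold assignment as the
    # single-region CV path, so a duplicated region reproduces it exactly
    n_trials = len(idx)
    folds = [np.arange(n_trials)[j::4] for j in range(4)]
    coefs = []
    rank_def = False
    for fold in folds:
        train = np.setdiff1d(np.arange(n_trials), fold)
        F = np.vstack([build_features(scores, idx[i], config.decoder_n_taps)
                       for i in train])
        c, rd = fit_decoder(F, np.vstack([ys[i] for i in train]))
        coefs.append(c)
        rank_def |= rd
    coef = np.mean(coefs, axis=0)
    model = DecoderModel(
        region="+".join(regions), variant="augmented",
        pca_mean=np.zeros(scores.shape[0]),
        pca_components=np.eye(scores.shape[0]),  # scores are the features
        n_dims=scores.shape[0], n_taps=config.decoder_n_taps,
        tap_dt_s=config.decoder_feature_dt_s, coefficients=coef,
        rank_deficient=rank_def,
        train_trial_ids=train_ctl.trial_id.to_numpy(),
        test_trial_ids=test_ctl.trial_id.to_numpy(),
    )
    scores_holder = RegionActivity(
        region=model.region, t=acts[0].t, z=scores,
        kept_channels=np.arange(scores.shape[0]), dropped_channels=np.empty(0, int),
    )
    return _evaluate(model, scores_holder, vel, fs, test_ctl, las,
                     selected.attrs.get("session_flagged", False))


def decoded_observed_difference(
    result: DecodeResult, session: Session, config: AnalysisConfig | None = None,
    region: str | None = None,
) -> dict:
    """Observed vs decoded mean laser − control-test velocity difference.

    Returns the two 3 × T difference curves over the lift window and
    the per-axis Spearman rho between them over time.
    """
    from .stats import spearman_rho

    config = config or session.config
    model = result.model
    reg = region or model.region
    selected = select_trials(session.trials)
    if model.variant == "augmented":
        raise NotImplementedError("difference analysis targets single-region decoders")
    activity = region_zscores(session, reg, config, selected)
    fs = session.hand.sample_rate_hz
    vel, _ = hand_velocity(session.hand, config.decode_kernel_sigma_s)
    scores = model.pca_components @ (activity.z - model.pca_mean[:, None])
    inc = selected[selected.include]
    las = inc[inc.trial_type == "laser_cue"]
    test_ctl = inc[inc.trial_id.isin(model.test_trial_ids)]
    test_ctl = test_ctl[test_ctl.trial_type == "control"]
    if len(las) == 0 or len(test_ctl) == 0:
        raise ValueError("need both laser and control-test trials")

    def mean_curves(trials):
        obs, dec = [], []
        for L in trials.lift_time.to_numpy():
            w = _window_samples(activity.t, L, fs)
            obs.append(vel[:, w].T)
            dec.append(predict(model.coefficients, build_features(scores, w, model.n_taps)))
        return np.mean(obs, axis=0), np.mean(dec, axis=0)

    obs_l, dec_l = mean_curves(las)
    obs_c, dec_c = mean_curves(test_ctl)
    obs_diff = (obs_l - obs_c).T  # 3 x T
    dec_diff = (dec_l - dec_c).T
    rho = np.array([spearman_rho(obs_diff[a], dec_diff[a]) for a in range(3)])
    return {"observed_diff": obs_diff, "decoded_diff": dec_diff, "rho_by_axis": rho}


def difference_correlation_test(rhos: np.ndarray) -> float:
    """Across sessions: two-sided signed-rank test of median rho = 0."""
    from .stats import signed_rank_p

    return signed_rank_p(np.asarray(rhos, dtype=float))
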