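"""Rate estimation, z-scoring, event alignment, hand velocity, and
multiunit depth profiles — preprocessing shared by all analysis stages.

Conventions: spike counts are binned at 1 ms on half-open bins and
convolved with a unit-mass Gaussian kernel truncated at ±4σ; z-scores
are relative to a named pre-event baseline window pooled across
trials; hand velocity is Gaussian smoothing (σ = 25 ms) followed by an
8th-order central difference, with the 4 stencil-edge samples marked
invalid rather than estimated one-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from scipy import signal as spsig

from .data_model import HandTrajectory, RawProbeSnippet, Session, SpikeTrain

#: 8th-order central first-difference stencil (unit sample spacing)
CD8_COEF = np.array(
    [1 / 280, -4 / 105, 1 / 5, -4 / 5, 0.0, 4 / 5, -1 / 5, 4 / 105, -1 / 280]
)


def bin_spikes(train: SpikeTrain | np.ndarray, t0: float, t1: float, bin_s: float) -> np.ndarray:
    """Spike counts over half-open bins [t0 + k·bin, t0 + (k+1)·bin)."""
    if t1 <= t0 or bin_s <= 0:
        raise ValueError("need t1 > t0 and bin_s > 0")
    times = train.spike_times if isinstance(train, SpikeTrain) else np.asarray(train, dtype=float)
    n = int(np.ceil(round((t1 - t0) / bin_s, 6)))
    edges = t0 + bin_s * np.arange(n + 1)
    idx = np.searchsorted(times, edges, side="left")
    return np.diff(idx).astype(float)


def gaussian_kernel(sigma_s: float, bin_s: float) -> np.ndarray:
    """Unit-mass Gaussian kernel on the bin grid, truncated at ±4σ."""
    if sigma_s <= 0:
        raise ValueError("sigma_s must be > 0")
    half = max(int(np.ceil(4.0 * sigma_s / bin_s)), 1)
    x = np.arange(-half, half + 1) * bin_s
    k = np.exp(-0.5 * (x / sigma_s) ** 2)
    return k / k.sum()


def smooth_rate(counts: np.ndarray, bin_s: float, sigma_s: float) -> np.ndarray:
    """Kernel-smoothed firing rate (Hz) from binned counts."""
    counts = np.asarray(counts, dtype=float)
    k = gaussian_kernel(sigma_s, bin_s)
    if counts.size == 0:
        return counts.copy()
    return np.convolve(counts, k, mode="same") / bin_s


@dataclass
class AlignedRateTensor:
    """units × time × trials smoothed rates aligned to a named event."""

    unit_ids: list[str]
    t: np.ndarray  # seconds relative to the event
    values: np.ndarray  # units x time x trials, Hz (or z after z-scoring)
    trial_ids: np.ndarray
    event: str
    n_excluded: int = 0

    def trial_average(self) -> np.ndarray:
        return self.values.mean(axis=2)


def align_to_event(
    session: Session,
    units: list[SpikeTrain] | None,
    event: str,
    window: tuple[float, float],
    condition: str | None = None,
    sigma_s: float = 0.050,
    bin_s: float = 0.001,
) -> AlignedRateTensor:
    """Event-aligned smoothed rates on a 1 ms grid over ``window``.

    Trials lacking the event are excluded and counted; spikes outside
    the window contribute through the kernel (binned with ±4σ padding
    and cropped) so edge rates are unbiased.
    """
    if units is None:
        units = session.spikes
    trials = session.trials if condition is None else session.trials_of_type(condition)
    ev = trials[event].to_numpy(dtype=float)
    keep = np.isfinite(ev)
    n_excluded = int((~keep).sum())
    ev = ev[keep]
    trial_ids = trials["trial_id"].to_numpy()[keep]
    if ev.size == 0:
        raise ValueError(f"no trials with event {event!r}")
    w0, w1 = window
    pad = int(np.ceil(4.0 * sigma_s / bin_s))
    n = int(round((w1 - w0) / bin_s))
    t = w0 + bin_s * (np.arange(n) + 0.5)
    values = np.empty((len(units), n, ev.size))
    for i, u in enumerate(units):
        for j, e in enumerate(ev):
            counts = bin_spikes(u, e + w0 - pad * bin_s, e + w1 + pad * bin_s, bin_s)
            values[i, :, j] = smooth_rate(counts, bin_s, sigma_s)[pad:pad + n]
    return AlignedRateTensor(
        unit_ids=[u.unit_id for u in units], t=t, values=values,
        trial_ids=trial_ids, event=event, n_excluded=n_excluded,
    )


def zscore_to_baseline(
    values: np.ndarray,
    t: np.ndarray,
    baseline_window: tuple[float, float],
    sd_floor: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Z-score aligned rates against a pre-event baseline window.

    ``values`` is units × time × trials; the baseline mean and sd are
    pooled over all trials' baseline samples per unit. Returns
    (z, mean, sd, floored) where ``floored`` flags units whose sd hit
    the floor (their z is 0 wherever the rate equals the mean).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 3 or values.shape[2] == 0:
        raise ValueError("values must be units x time x trials with >= 1 trial")
    w0, w1 = baseline_window
    mask = (t >= w0) & (t < w1)
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    base = values[:, mask, :].reshape(values.shape[0], -1)
    mean = base.mean(axis=1)
    sd = base.std(axis=1)
    floored = sd < sd_floor
    sd = np.maximum(sd, sd_floor)
    z = (values - mean[:, None, None]) / sd[:, None, None]
    return z, mean, sd, floored


def hand_velocity(
    traj: HandTrajectory, sigma_s: float | None = 0.025
) -> tuple[np.ndarray, np.ndarray]:
    """3 × T hand velocity (mm/s): Gaussian smoothing then an 8th-order
    central difference. Returns (velocity, valid); the 4 samples at each
    edge are marked invalid. ``sigma_s=None`` skips smoothing."""
    pos = traj.position
    T = pos.shape[1]
    if T < CD8_COEF.size:
        raise ValueError("trajectory shorter than the difference stencil")
    if sigma_s is not None:
        dt = 1.0 / traj.sample_rate_hz
        k = gaussian_kernel(sigma_s, dt)
        half = k.size // 2
        padded = np.pad(pos, ((0, 0), (half, half)), mode="edge")
        pos = np.vstack([np.convolve(padded[a], k, mode="valid") for a in range(3)])
    vel = np.empty_like(pos)
    for a in range(3):
        vel[a] = np.convolve(pos[a], CD8_COEF[::-1], mode="same")
    vel *= traj.sample_rate_hz
    valid = traj.valid.copy() if traj.valid is not None else np.ones(T, bool)
    valid[:4] = False
    valid[-4:] = False
    return vel, valid


def multiunit_depth_profile(
    raw: RawProbeSnippet,
    blank_window_s: tuple[float, float] = (0.0, 0.006),
    highpass_hz: float = 650.0,
    t_sigma_s: float = 333e-6,
    d_sigma_um: float = 30.0,
    avg_window_s: tuple[float, float] = (0.006, 0.010),
) -> tuple[np.ndarray, np.ndarray]:
    """Depth profile of stimulation-evoked multiunit activity.

    Per channel: blank the optical-artifact window after each pulse,
    high-pass (zero-phase 4th-order Butterworth), full-wave rectify,
    average across pulses, smooth over time (σ = 333 µs); then smooth
    across depth (σ = 30 µm) and average the 6–10 ms post-pulse window.
    Returns (depths_um sorted ascending, profile).
    """
    if raw.pulse_onsets.size == 0:
        raise ValueError("need at least one pulse")
    fs = raw.sample_rate_hz
    if fs < 2 * highpass_hz:
        raise ValueError("sample rate too low for the high-pass cutoff")
    b0, b1 = blank_window_s
    a0, a1 = avg_window_s
    if a1 <= b1 and a0 >= b0:
        raise ValueError("averaging window entirely blanked")

    # remove per-channel DC before blanking so the blanked samples are
    # neutral (the high-pass removes DC anyway; this avoids step edges)
    volt = raw.voltage - raw.voltage.mean(axis=1, keepdims=True)
    n = volt.shape[1]
    for p in raw.pulse_onsets:
        i0 = max(int(round((p + b0) * fs)), 0)
        i1 = min(int(round((p + b1) * fs)), n)
        volt[:, i0:i1] = 0.0

    sos = spsig.butter(4, highpass_hz, btype="highpass", fs=fs, output="sos")
    env = np.abs(spsig.sosfiltfilt(sos, volt, axis=1))

    # pulse-triggered average of the rectified envelope
    pre = 0
    post = int(round(a1 * fs)) + 1
    snips = []
    for p in raw.pulse_onsets:
        i0 = int(round(p * fs))
        if i0 + post <= n:
            snips.append(env[:, i0 - pre:i0 + post])
    if not snips:
        raise ValueError("no complete pulse windows in the snippet")
    avg = np.mean(snips, axis=0)

    tk = gaussian_kernel(t_sigma_s, 1.0 / fs)
    avg = np.apply_along_axis(lambda r: np.convolve(r, tk, mode="same"), 1, avg)

    # spatial smoothing over (possibly irregular) channel depths
    order = np.argsort(raw.channel_positions_um)
    depths = raw.channel_positions_um[order]
    avg = avg[order]
    w = np.exp(-0.5 * ((depths[:, None] - depths[None, :]) / d_sigma_um) ** 2)
    w /= w.sum(axis=1, keepdims=True)
    avg = w @ avg

    j0, j1 = int(round(a0 * fs)), int(round(a1 * fs))
    profile = avg[:, j0:j1 + 1].mean(axis=1)
    return depths, profile


def stim_power_density(
    envelope: np.ndarray, sample_rate_hz: float, freq_hz: float = 40.0
) -> np.ndarray:
    """Periodogram power density at the stimulation frequency, per channel."""
    env = np.atleast_2d(np.asarray(envelope, dtype=float))
    freqs, pxx = spsig.periodogram(env, fs=sample_rate_hz, axis=1)
    j = int(np.argmin(np.abs(freqs - freq_hz)))
    return pxx[:, j]
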