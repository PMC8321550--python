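"""Synthetic sessions with known ground truth.

The generator emulates the statistical structure each analysis stage
assumes: inhomogeneous-Poisson pontine (PN) spiking with cue- and
lift-locked multiplicative gain (the event GLM's own forward model,
sampled exactly by thinning), Purkinje/DCN spiking phase-locked to a
40 Hz sinusoidal laser with controllable mean resultant length (von
Mises phases, concentration solved from the MRL–κ relation),
short-latency pulse-tagged responses, latent-factor-driven multiunit
channel rates in cortex and DCN linearly related to 3D hand velocity,
and laser-induced behavioral shifts (forward endpoint overshoot,
longer lift-to-grab duration, reduced initiation/success
probabilities, inflated endpoint variance).

Hand trajectories are minimum-jerk reaches from the perch to a
per-trial endpoint draw, plus a smooth bounded positional jitter;
velocity is the analytic plan derivative plus the jitter derivative,
and positions are recovered by cumulative integration, so the
velocity really is a known (lag-free) linear readout of the first
three latent factors. Channel rates pass through a softplus whose
operating point is far into its linear range, so linear decoding
remains essentially exact in the noiseless configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, optimize
from scipy.ndimage import gaussian_filter1d

from .config import AnalysisConfig
from .data_model import (
    HandTrajectory,
    RateMatrix,
    Session,
    SpikeTrain,
    validate_trials,
)
from .event_glm import build_basis

KINEMATIC_FS = 500.0


@dataclass
class SimSpec:
    """Generative parameters for one synthetic session.

    Defaults are the desk-scale study conditions used throughout the
    test-suite: 60 control / 30 laser-cue / 30 laser-only trials, a
    40 Hz, 2 s laser, region MRLs near the weak-Purkinje / strong-DCN
    regime, and laser behavioral effects in the reported directions
    (+1.5 mm forward endpoint shift, +0.1 s lift-to-grab duration,
    −0.10 initiation and −0.20 first-success probability, 1.3×
    endpoint sd).
    """

    rng_seed: int = 0
    # trial structure
    n_control: int = 60
    n_laser_cue: int = 30
    n_laser_only: int = 30
    trial_spacing_s: float = 5.0
    delivery_mode: str = "table"
    laser_freq_hz: float = 40.0
    laser_duration_s: float = 2.0
    laser_lead_s: float = 0.05  # laser onset precedes the cue by this much
    # pulse-tagging epoch (10 Hz pulse train before the task)
    n_pulses: int = 50
    pulse_period_s: float = 0.1
    # PN event-GLM units
    n_pn: int = 12
    baseline_log_mean: float = float(np.log(10.0))
    baseline_log_sd: float = 0.5
    glm_weight_sd: float = 0.5
    p_tagged: float = 0.25
    tag_latency_s: float = 0.006
    tag_duration_s: float = 0.008
    tag_gain: float = 4.0
    laser_class_probs: dict = field(
        default_factory=lambda: {
            "sustained_up": 0.30, "sustained_down": 0.15,
            "transient_up": 0.10, "none": 0.45,
        }
    )
    # entrained single units
    n_pkj: int = 8
    n_dcn: int = 12
    entrain_rate_hz: float = 30.0
    rho_pkj: float = 0.06
    rho_dcn: float = 0.22
    rho_unit_sd: float = 0.02
    pref_phase_pkj_deg: float = 90.0
    pref_phase_dcn_deg: float = 185.0
    pref_phase_jitter_deg: float = 15.0
    # latent factors and multiunit channels
    n_ctx_channels: int = 16
    n_dcn_channels: int = 12
    n_extra_factors: int = 1
    n_shared_extra: int = 1  # extra factors loaded by both regions
    factor_tau_s: float = 0.10
    velocity_factor_scale: float = 20.0  # mm/s per factor unit
    loading_scale: float = 3.0
    channel_baseline_hz: float = 40.0
    channel_noise_hz: float = 2.0
    laser_extra_factor_scale: float = 1.0
    make_channel_spikes: bool = False
    # behavior
    endpoint_mm: tuple = (12.0, 3.0, 8.0)
    endpoint_sd_mm: float = 1.0
    position_jitter_mm: float = 0.3
    lift_delay_mean_s: float = 0.30
    lift_delay_min_s: float = 0.15  # reaction times: min + exponential tail
    reach_duration_mean_s: float = 0.25
    reach_duration_sd_s: float = 0.04
    p_init_control: float = 0.95
    p_success_control: float = 0.70
    # laser behavioral effects
    endpoint_shift_mm: tuple = (1.5, 0.0, 0.0)
    duration_increase_s: float = 0.10
    initiation_delta: float = -0.10
    success_delta: float = -0.20
    endpoint_sd_scale: float = 1.3

    def validate(self) -> None:
        for name in ("rho_pkj", "rho_dcn"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("p_init_control", "p_success_control", "p_tagged"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if abs(sum(self.laser_class_probs.values()) - 1.0) > 1e-9:
            raise ValueError("laser_class_probs must sum to 1")
        if self.endpoint_sd_scale < 0 or self.endpoint_sd_mm < 0:
            raise ValueError("endpoint dispersions must be >= 0")
        if self.n_extra_factors < 0 or self.n_shared_extra > self.n_extra_factors:
            raise ValueError("invalid latent factor counts")


@dataclass
class GroundTruth:
    """Every generative parameter drawn while building a session."""

    spec: SimSpec
    pulse_times: np.ndarray
    pn_units: list = field(default_factory=list)
    entrain_units: list = field(default_factory=list)
    loadings: dict = field(default_factory=dict)
    factors: np.ndarray | None = None
    velocity: np.ndarray | None = None
    endpoints: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# circular helpers


def kappa_from_mrl(rho: float) -> float:
    """Solve A(κ) = I1(κ)/I0(κ) = ρ for the von Mises concentration."""
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    if rho < 1e-9:
        return 0.0
    if rho > 1.0 - 1e-9:
        return np.inf
    f = lambda k: special.i1e(k) / special.i0e(k) - rho
    return float(optimize.brentq(f, 1e-9, 1e4))


# ---------------------------------------------------------------------------
# unit-level simulators


def simulate_glm_unit(
    k_cue: np.ndarray,
    k_reach: np.ndarray,
    baseline_hz: float,
    trials: pd.DataFrame,
    seed: int | np.random.Generator,
    bin_s: float = 0.001,
    t_end: float | None = None,
    rate_multiplier: np.ndarray | None = None,
) -> SpikeTrain:
    """Inhomogeneous-Poisson spikes with λ(t) = baseline·exp(Σ event filters).

    Filters (log-gain curves on the 1 ms grid, starting at the event)
    are added at every finite cue and lift time; sampling is exact
    thinning against sup λ computed on the grid with a 5% margin.
    ``rate_multiplier``, if given, scales λ bin-wise (laser responses).
    """
    if baseline_hz <= 0:
        raise ValueError("baseline_hz must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    events = np.concatenate(
        [trials["cue_time"].to_numpy(dtype=float), trials["lift_time"].to_numpy(dtype=float)]
    )
    if t_end is None:
        t_end = (np.nanmax(events) if np.isfinite(events).any() else 0.0) + 3.0
    n = int(np.ceil(t_end / bin_s))
    log_gain = np.zeros(n)
    for curve, col in ((np.asarray(k_cue, float), "cue_time"),
                       (np.asarray(k_reach, float), "lift_time")):
        if curve.size == 0:
            continue
        for ev in trials[col].to_numpy(dtype=float):
            if not np.isfinite(ev):
                continue
            k0 = int(round(ev / bin_s))
            a, b = max(k0, 0), min(k0 + curve.size, n)
            if b > a:
                log_gain[a:b] += curve[a - k0:b - k0]
    lam = baseline_hz * np.exp(log_gain)
    if rate_multiplier is not None:
        lam = lam * rate_multiplier[:n]
    sup = float(lam.max()) * 1.05
    n_cand = rng.poisson(sup * t_end)
    cand = np.sort(rng.uniform(0.0, t_end, n_cand))
    lam_at = lam[np.minimum((cand / bin_s).astype(int), n - 1)]
    if np.any(lam_at > sup):
        raise RuntimeError("thinning bound violated")  # cannot happen: sup from same grid
    keep = rng.uniform(0.0, sup, n_cand) < lam_at
    times = np.unique(cand[keep])
    return SpikeTrain(unit_id="sim", region="PN", spike_times=times)


def simulate_entrained_unit(
    rho_true: float,
    pref_phase: float,
    rate_hz: float,
    laser_windows: np.ndarray,
    freq_hz: float,
    seed: int | np.random.Generator,
    t_end: float | None = None,
    unit_id: str = "sim",
    region: str = "DCN",
    laser_rate_hz: float | None = None,
) -> SpikeTrain:
    """Spikes homogeneous outside laser windows; inside, spike phases
    follow a von Mises law around ``pref_phase`` whose mean resultant
    length is ``rho_true`` (phase 0 at each sinusoid cycle onset)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    windows = np.atleast_2d(np.asarray(laser_windows, dtype=float))
    if t_end is None:
        t_end = (windows[:, 1].max() if windows.size else 0.0) + 1.0
    laser_rate = rate_hz if laser_rate_hz is None else laser_rate_hz
    kappa = kappa_from_mrl(rho_true)
    times = []
    cursor = 0.0
    for on, off in windows:
        if on > cursor:
            n_bg = rng.poisson(rate_hz * (on - cursor))
            times.append(rng.uniform(cursor, on, n_bg))
        dur = off - on
        n_cycles = int(np.floor(dur * freq_hz))
        n_spk = rng.poisson(laser_rate * dur)
        cycle = rng.integers(0, n_cycles, n_spk)
        if np.isinf(kappa):
            theta = np.full(n_spk, pref_phase)
        elif kappa == 0.0:
            theta = rng.uniform(0.0, 2 * np.pi, n_spk)
        else:
            theta = np.mod(rng.vonmises(pref_phase, kappa, n_spk), 2 * np.pi)
        t = on + (cycle + theta / (2 * np.pi)) / freq_hz
        times.append(t[t < off])
        cursor = off
    if t_end > cursor:
        n_bg = rng.poisson(rate_hz * (t_end - cursor))
        times.append(rng.uniform(cursor, t_end, n_bg))
    spk = np.unique(np.concatenate(times)) if times else np.empty(0)
    return SpikeTrain(unit_id=unit_id, region=region, spike_times=spk)


# ---------------------------------------------------------------------------
# latent kinematics


def _min_jerk_profile(tau: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normalized minimum-jerk position and velocity profiles on [0, 1]."""
    pos = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    vel = 30 * tau**2 - 60 * tau**3 + 30 * tau**4
    return pos, vel


def _smooth_noise(rng: np.random.Generator, shape: tuple, sigma_samples: float, sd: float) -> np.ndarray:
    if sd == 0.0:
        return np.zeros(shape)
    x = gaussian_filter1d(rng.standard_normal(shape), sigma_samples, axis=-1, mode="constant")
    s = x.std(axis=-1, keepdims=True)
    s[s == 0] = 1.0
    return sd * x / s


def simulate_latent_kinematics(
    spec: SimSpec,
    trials: pd.DataFrame,
    seed: int | np.random.Generator,
    t_end: float,
    endpoints: dict[int, np.ndarray] | None = None,
) -> tuple[HandTrajectory, dict[str, np.ndarray], np.ndarray, dict]:
    """Session-long hand trajectory, latent factors, and channel rates.

    Returns (hand, region rate matrices {region: channels × T},
    factors (n_factors × T), info) where info carries the loading
    matrices and velocity scale. The first three factors are the 3D
    hand velocity divided by ``velocity_factor_scale``; extra factors
    are smooth unit-variance noise, optionally rescaled inside laser
    windows by ``laser_extra_factor_scale``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fs = KINEMATIC_FS
    dt = 1.0 / fs
    T = int(round(t_end * fs))
    t = np.arange(T) * dt

    vel = np.zeros((3, T))
    used_endpoints: dict[int, np.ndarray] = {}
    for row in trials.itertuples(index=False):
        if not (np.isfinite(row.lift_time) and np.isfinite(row.grab_time)):
            continue
        is_laser = row.trial_type == "laser_cue"
        if endpoints is not None and row.trial_id in endpoints:
            target = np.asarray(endpoints[row.trial_id], dtype=float)
        else:
            sd = spec.endpoint_sd_mm * (spec.endpoint_sd_scale if is_laser else 1.0)
            target = np.asarray(spec.endpoint_mm, float) + \
                (np.asarray(spec.endpoint_shift_mm, float) if is_laser else 0.0) + \
                rng.normal(0.0, sd, 3)
        used_endpoints[int(row.trial_id)] = target
        i0, i1 = int(round(row.lift_time * fs)), int(round(row.grab_time * fs))
        i1 = min(i1, T - 1)
        dur = (i1 - i0) * dt
        if i1 <= i0:
            continue
        tau = (np.arange(i0, i1 + 1) - i0) / (i1 - i0)
        _, vprof = _min_jerk_profile(tau)
        vel[:, i0:i1 + 1] += target[:, None] * vprof[None, :] / dur
        # smooth return to the perch
        r0 = i1 + int(round(0.10 * fs))
        r1 = min(r0 + int(round(0.30 * fs)), T - 1)
        if r1 > r0:
            tau_r = (np.arange(r0, r1 + 1) - r0) / (r1 - r0)
            _, vprof_r = _min_jerk_profile(tau_r)
            vel[:, r0:r1 + 1] -= target[:, None] * vprof_r[None, :] / ((r1 - r0) * dt)

    # bounded positional jitter; its derivative is the velocity noise
    jit = _smooth_noise(rng, (3, T), 0.020 * fs, spec.position_jitter_mm)
    vel = vel + np.gradient(jit, dt, axis=1)
    pos = np.cumsum(vel, axis=1) * dt  # integration from the perch (origin)

    n_factors = 3 + spec.n_extra_factors
    factors = np.zeros((n_factors, T))
    factors[:3] = vel / spec.velocity_factor_scale
    if spec.n_extra_factors:
        factors[3:] = _smooth_noise(
            rng, (spec.n_extra_factors, T), spec.factor_tau_s * fs, 1.0
        )
        if spec.laser_extra_factor_scale != 1.0:
            for row in trials.itertuples(index=False):
                if np.isfinite(row.laser_on) and np.isfinite(row.laser_off):
                    a, b = int(round(row.laser_on * fs)), int(round(row.laser_off * fs))
                    factors[3:, a:b] *= spec.laser_extra_factor_scale

    rate_mats: dict[str, np.ndarray] = {}
    loadings: dict[str, np.ndarray] = {}
    region_channels = {"CTX": spec.n_ctx_channels, "DCN": spec.n_dcn_channels}
    for region, nch in region_channels.items():
        if nch == 0:
            continue
        B = rng.normal(0.0, 1.0, (nch, n_factors)) * spec.loading_scale
        # regions share the velocity factors and the first n_shared_extra
        # extra factors; region-private extras are zeroed in the other region
        if spec.n_extra_factors > spec.n_shared_extra:
            private = np.arange(3 + spec.n_shared_extra, n_factors)
            if region == "CTX":
                B[:, private[: private.size // 2]] = 0.0
            else:
                B[:, private[private.size // 2:]] = 0.0
        baseline = spec.channel_baseline_hz * np.exp(rng.normal(0.0, 0.2, nch))
        drive = baseline[:, None] + B @ factors
        drive += _smooth_noise(rng, (nch, T), 0.010 * fs, spec.channel_noise_hz)
        rate_mats[region] = np.log1p(np.exp(-np.abs(drive))) + np.maximum(drive, 0.0)
        loadings[region] = B

    hand = HandTrajectory(t=t, position=pos, sample_rate_hz=fs)
    info = {
        "loadings": loadings,
        "velocity_factor_scale": spec.velocity_factor_scale,
        "endpoints": used_endpoints,
        "velocity": vel,
    }
    return hand, rate_mats, factors, info


# ---------------------------------------------------------------------------
# trial table


def _make_trials(spec: SimSpec, rng: np.random.Generator, t_task_start: float) -> pd.DataFrame:
    types = (
        ["control"] * spec.n_control
        + ["laser_cue"] * spec.n_laser_cue
        + ["laser_only"] * spec.n_laser_only
    )
    types = [types[i] for i in rng.permutation(len(types))]
    rows = []
    for k, ttype in enumerate(types):
        t0 = t_task_start + k * spec.trial_spacing_s
        row = dict(
            trial_id=k, trial_type=ttype, cue_time=np.nan, laser_on=np.nan,
            laser_off=np.nan, laser_freq_hz=np.nan, lift_time=np.nan,
            handopen_time=np.nan, grab_time=np.nan, atmouth_time=np.nan,
            reach_initiated=False, success_first=False, success_any=False,
            delivery_mode=spec.delivery_mode,
        )
        if ttype in ("control", "laser_cue"):
            row["cue_time"] = t0
            p_init = spec.p_init_control + (spec.initiation_delta if ttype == "laser_cue" else 0.0)
            p_succ = spec.p_success_control + (spec.success_delta if ttype == "laser_cue" else 0.0)
            if ttype == "laser_cue":
                row["laser_on"] = t0 - spec.laser_lead_s
                row["laser_off"] = row["laser_on"] + spec.laser_duration_s
                row["laser_freq_hz"] = spec.laser_freq_hz
            if rng.uniform() < p_init:
                # right-skewed reaction times: floor plus exponential tail
                lift = t0 + spec.lift_delay_min_s + rng.exponential(
                    max(spec.lift_delay_mean_s - spec.lift_delay_min_s, 1e-6)
                )
                dur = max(rng.normal(spec.reach_duration_mean_s, spec.reach_duration_sd_s), 0.08)
                if ttype == "laser_cue":
                    dur += spec.duration_increase_s
                row.update(
                    reach_initiated=True, lift_time=lift,
                    handopen_time=lift + 0.6 * dur, grab_time=lift + dur,
                    atmouth_time=lift + dur + 0.2,
                )
                succ = rng.uniform() < np.clip(p_succ, 0.0, 1.0)
                row["success_first"] = bool(succ)
                row["success_any"] = bool(succ or rng.uniform() < 0.5)
        else:  # laser_only
            row["laser_on"] = t0
            row["laser_off"] = t0 + spec.laser_duration_s
            row["laser_freq_hz"] = spec.laser_freq_hz
        rows.append(row)
    return validate_trials(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# full session


def make_session(spec: SimSpec, session_id: str = "sim") -> tuple[Session, GroundTruth]:
    """Generate one full synthetic session; identical seed ⇒ identical output."""
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    bin_s = 0.001

    pulse_times = 0.5 + spec.pulse_period_s * np.arange(spec.n_pulses)
    t_task_start = (pulse_times[-1] if spec.n_pulses else 0.0) + 2.0
    trials = _make_trials(spec, rng, t_task_start)
    n_trials = len(trials)
    t_end = t_task_start + n_trials * spec.trial_spacing_s + 2.0

    hand, rate_mats, factors, kin_info = simulate_latent_kinematics(
        spec, trials, rng, t_end
    )

    laser_rows = trials[np.isfinite(trials.laser_on)]
    laser_windows = laser_rows[["laser_on", "laser_off"]].to_numpy(dtype=float)

    truth = GroundTruth(spec=spec, pulse_times=pulse_times)
    truth.loadings = kin_info["loadings"]
    truth.factors = factors
    truth.velocity = kin_info["velocity"]
    truth.endpoints = kin_info["endpoints"]

    spikes: list[SpikeTrain] = []

    # --- PN units: event-GLM truth + pulse tagging + long-laser response
    basis = build_basis()
    n_grid = int(np.ceil(t_end / bin_s))
    classes = list(spec.laser_class_probs)
    class_p = np.array([spec.laser_class_probs[c] for c in classes])
    for i in range(spec.n_pn):
        baseline = float(np.exp(rng.normal(spec.baseline_log_mean, spec.baseline_log_sd)))
        w_cue = rng.normal(0.0, spec.glm_weight_sd, basis.n_basis)
        w_reach = rng.normal(0.0, spec.glm_weight_sd, basis.n_basis)
        k_cue = w_cue @ basis.matrix
        k_reach = w_reach @ basis.matrix
        tagged = bool(rng.uniform() < spec.p_tagged)
        laser_class = classes[int(rng.choice(len(classes), p=class_p))]

        mult = np.ones(n_grid)
        if tagged:
            for pt in pulse_times:
                a = int(round((pt + spec.tag_latency_s) / bin_s))
                b = int(round((pt + spec.tag_latency_s + spec.tag_duration_s) / bin_s))
                mult[a:b] = spec.tag_gain
        for on, off in laser_windows:
            a, b = int(round(on / bin_s)), int(round(off / bin_s))
            if laser_class == "sustained_up":
                mult[a:b] *= 1.8
            elif laser_class == "sustained_down":
                mult[a:b] *= 0.4
            elif laser_class == "transient_up":
                mult[a:a + int(round(0.080 / bin_s))] *= 3.0
        train = simulate_glm_unit(
            k_cue, k_reach, baseline, trials, rng,
            bin_s=bin_s, t_end=t_end, rate_multiplier=mult,
        )
        train.unit_id = f"PN{i:03d}"
        spikes.append(train)
        truth.pn_units.append(
            dict(unit_id=train.unit_id, baseline_hz=baseline, w_cue=w_cue,
                 w_reach=w_reach, k_cue=k_cue, k_reach=k_reach,
                 tagged=tagged, laser_class=laser_class)
        )

    # --- entrained single units (PKJ, DCN)
    for region, count, rho0, pref0 in (
        ("PKJ", spec.n_pkj, spec.rho_pkj, spec.pref_phase_pkj_deg),
        ("DCN", spec.n_dcn, spec.rho_dcn, spec.pref_phase_dcn_deg),
    ):
        for i in range(count):
            rho = float(np.clip(rng.normal(rho0, spec.rho_unit_sd), 0.0, 1.0))
            pref = np.deg2rad(pref0 + rng.normal(0.0, spec.pref_phase_jitter_deg))
            pref = float(np.mod(pref, 2 * np.pi))
            rate = float(spec.entrain_rate_hz * np.exp(rng.normal(0.0, 0.3)))
            train = simulate_entrained_unit(
                rho, pref, rate, laser_windows, spec.laser_freq_hz, rng,
                t_end=t_end, unit_id=f"{region}{i:03d}", region=region,
            )
            spikes.append(train)
            truth.entrain_units.append(
                dict(unit_id=train.unit_id, region=region, rho=rho,
                     pref_phase=pref, rate_hz=rate)
            )

    # --- multiunit channel populations
    rates: dict[str, RateMatrix] = {}
    for region, mat in rate_mats.items():
        rates[region] = RateMatrix(region=region, t=hand.t.copy(), values=mat)
        if spec.make_channel_spikes:
            dt = 1.0 / KINEMATIC_FS
            for ch in range(mat.shape[0]):
                counts = rng.poisson(np.maximum(mat[ch], 0.0) * dt)
                reps = np.repeat(np.arange(mat.shape[1]), counts)
                times = np.unique(hand.t[reps] + rng.uniform(0, dt, reps.size))
                spikes.append(
                    SpikeTrain(unit_id=f"{region}mu{ch:03d}", region=region,
                               spike_times=times, channel=ch, is_multiunit=True)
                )

    session = Session(
        session_id=session_id,
        animal_id="simM000",
        spikes=spikes,
        trials=trials,
        hand=hand,
        rates=rates,
        config=AnalysisConfig(rng_seed=spec.rng_seed),
        meta={"pulse_times": [float(x) for x in pulse_times],
              "synthetic": True},
    )
    return session, truth
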