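"""Core domain types and session I/O.

A recording session bundles sorted spike trains, a per-trial event
table, an optional 500 Hz 3D hand trajectory, optional per-channel
rate matrices (multiunit firing-rate estimates on the kinematic
clock), and optional raw probe voltage snippets. All event and spike
times are absolute seconds from session start; alignment to events is
done at analysis time. Missing events are encoded as NaN in tabular
form and treated as absent.

On disk a session is a directory of delimited text files
(``spikes.csv``, ``trials.csv``, ``kinematics.csv``,
``rates_<REGION>.csv``) plus ``session.yaml`` metadata and an optional
``raw_probe.h5``. Floats are written with full ``repr`` precision so
that write/read round-trips are lossless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import AnalysisConfig

REGIONS = ("PN", "CTX", "DCN", "PKJ")
TRIAL_TYPES = ("control", "laser_only", "laser_cue")
DELIVERY_MODES = ("table", "post")

TRIAL_COLUMNS = [
    "trial_id",
    "trial_type",
    "cue_time",
    "laser_on",
    "laser_off",
    "laser_freq_hz",
    "lift_time",
    "handopen_time",
    "grab_time",
    "atmouth_time",
    "reach_initiated",
    "success_first",
    "success_any",
    "delivery_mode",
]

_EVENT_COLUMNS = [
    "cue_time",
    "laser_on",
    "laser_off",
    "lift_time",
    "handopen_time",
    "grab_time",
    "atmouth_time",
]


class SessionValidationError(ValueError):
    """A domain invariant was violated; message names the unit/trial."""


class SessionLoadError(IOError):
    """A required session file is missing or unreadable."""


@dataclass
class SpikeTrain:
    """One sorted unit (or multiunit channel): spike times plus metadata."""

    unit_id: str
    region: str
    spike_times: np.ndarray
    channel: int | None = None
    depth_um: float | None = None
    is_multiunit: bool = False

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.region not in REGIONS:
            raise SessionValidationError(
                f"unit {self.unit_id}: region {self.region!r} not in {REGIONS}"
            )
        t = self.spike_times
        if t.size and (not np.all(np.isfinite(t)) or t[0] < 0):
            raise SessionValidationError(
                f"unit {self.unit_id}: spike times must be finite and >= 0"
            )
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise SessionValidationError(
                f"unit {self.unit_id}: spike times must be strictly increasing"
            )

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)


@dataclass
class HandTrajectory:
    """3D hand position (mm, axes forward/left/up) sampled at 500 Hz."""

    t: np.ndarray
    position: np.ndarray  # 3 x T, millimeters
    valid: np.ndarray | None = None
    sample_rate_hz: float = 500.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3, self.t.size):
            raise SessionValidationError(
                f"hand position must be 3 x {self.t.size}, got {self.position.shape}"
            )
        if self.valid is None:
            self.valid = np.ones(self.t.size, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        dt = 1.0 / self.sample_rate_hz
        if self.t.size > 1:
            if np.max(np.abs(np.diff(self.t) - dt)) > 1e-9:
                raise SessionValidationError(
                    "hand trajectory must be uniformly sampled at 1/sample_rate_hz"
                )
        if not np.all(np.isfinite(self.position[:, self.valid])):
            raise SessionValidationError("hand position must be finite where valid")

    def index_at(self, time_s: float) -> int:
        """Index of the sample nearest to ``time_s`` (clipped to range)."""
        i = int(round((time_s - self.t[0]) * self.sample_rate_hz))
        return min(max(i, 0), self.t.size - 1)


@dataclass
class RateMatrix:
    """Per-channel firing-rate (or z-score) matrix on the kinematic clock.

    Used for multiunit populations where continuous rate estimates are
    carried instead of (or in addition to) spike times, e.g. by the
    latent-factor generator feeding the decoding and CCA stages.
    """

    region: str
    t: np.ndarray
    values: np.ndarray  # channels x T, Hz

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.region not in REGIONS:
            raise SessionValidationError(f"rate matrix region {self.region!r} invalid")
        if self.values.ndim != 2 or self.values.shape[1] != self.t.size:
            raise SessionValidationError(
                f"rate matrix must be channels x {self.t.size}"
            )


@dataclass
class RawProbeSnippet:
    """Raw multichannel voltage around stimulation pulses, for depth profiles."""

    channel_positions_um: np.ndarray
    sample_rate_hz: float
    voltage: np.ndarray  # channels x samples
    pulse_onsets: np.ndarray  # seconds, on the snippet time base starting at 0

    def __post_init__(self) -> None:
        self.channel_positions_um = np.asarray(self.channel_positions_um, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)
        self.pulse_onsets = np.asarray(self.pulse_onsets, dtype=float)
        pos = self.channel_positions_um
        if not np.all(np.isfinite(pos)) or np.unique(pos).size != pos.size:
            raise SessionValidationError("channel positions must be finite and distinct")
        if not np.all(np.isfinite(self.voltage)):
            raise SessionValidationError("raw voltage must be finite")


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a trial table; raises naming the offending trial."""
    missing = set(TRIAL_COLUMNS) - set(trials.columns)
    if missing:
        raise SessionValidationError(f"trial table missing columns: {sorted(missing)}")
    trials = trials[TRIAL_COLUMNS].copy().reset_index(drop=True)
    for col in ("reach_initiated", "success_first", "success_any"):
        trials[col] = trials[col].astype(bool)
    for col in _EVENT_COLUMNS + ["laser_freq_hz"]:
        trials[col] = pd.to_numeric(trials[col], errors="coerce").astype(float)
    for row in trials.itertuples(index=False):
        tid = row.trial_id
        if row.trial_type not in TRIAL_TYPES:
            raise SessionValidationError(
                f"trial {tid}: trial_type {row.trial_type!r} invalid"
            )
        if row.delivery_mode not in DELIVERY_MODES:
            raise SessionValidationError(
                f"trial {tid}: delivery_mode {row.delivery_mode!r} invalid"
            )
        is_laser = row.trial_type in ("laser_only", "laser_cue")
        if is_laser:
            if math.isnan(row.laser_on) or math.isnan(row.laser_off):
                raise SessionValidationError(f"trial {tid}: laser trial lacks laser window")
            if not row.laser_off > row.laser_on:
                raise SessionValidationError(f"trial {tid}: laser_off must exceed laser_on")
            if not row.laser_freq_hz > 0:
                raise SessionValidationError(f"trial {tid}: laser_freq_hz must be > 0")
        if not math.isnan(row.grab_time):
            if math.isnan(row.lift_time):
                raise SessionValidationError(f"trial {tid}: grab without lift")
            if not row.lift_time < row.grab_time:
                raise SessionValidationError(f"trial {tid}: lift_time must precede grab_time")
        if row.success_first and not row.success_any:
            raise SessionValidationError(f"trial {tid}: success_first implies success_any")
    return trials


@dataclass
class Session:
    session_id: str
    animal_id: str
    spikes: list[SpikeTrain] = field(default_factory=list)
    trials: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=TRIAL_COLUMNS))
    hand: HandTrajectory | None = None
    rates: dict[str, RateMatrix] = field(default_factory=dict)
    raw_probe: RawProbeSnippet | None = None
    config: AnalysisConfig = field(default_factory=AnalysisConfig)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.trials = validate_trials(self.trials)
        # events must fall inside the continuously sampled span, when one exists
        spans = []
        if self.hand is not None and self.hand.t.size:
            spans.append(float(self.hand.t[-1]))
        spans += [float(rm.t[-1]) for rm in self.rates.values() if rm.t.size]
        ev = self.trials[_EVENT_COLUMNS].to_numpy(dtype=float)
        if spans and ev.size and np.isfinite(ev).any():
            end = max(spans)
            if np.nanmax(ev) > end + 1e-9:
                raise SessionValidationError(
                    f"session {self.session_id}: event time {np.nanmax(ev):.3f}s "
                    f"beyond recording span {end:.3f}s"
                )

    def span_end(self) -> float:
        """Recording span: end of the latest carried signal (or last event)."""
        ends = [0.0]
        for tr in self.spikes:
            if tr.n_spikes:
                ends.append(float(tr.spike_times[-1]))
        if self.hand is not None and self.hand.t.size:
            ends.append(float(self.hand.t[-1]))
        for rm in self.rates.values():
            if rm.t.size:
                ends.append(float(rm.t[-1]))
        ev = self.trials[_EVENT_COLUMNS].to_numpy(dtype=float)
        if ev.size and np.isfinite(ev).any():
            ends.append(float(np.nanmax(ev)))
        return max(ends)

    def units(self, region: str | None = None, multiunit: bool | None = None) -> list[SpikeTrain]:
        out = self.spikes
        if region is not None:
            out = [u for u in out if u.region == region]
        if multiunit is not None:
            out = [u for u in out if u.is_multiunit == multiunit]
        return out

    def trials_of_type(self, trial_type: str) -> pd.DataFrame:
        return self.trials[self.trials.trial_type == trial_type].reset_index(drop=True)


# ---------------------------------------------------------------------------
# session directory I/O


def write_session(session: Session, path: str | Path) -> None:
    """Write a session directory; ``read_session`` inverts it losslessly."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    rows = []
    for u in session.spikes:
        for t in u.spike_times:
            rows.append(
                (u.unit_id, u.region, float(t),
                 -1 if u.channel is None else u.channel,
                 np.nan if u.depth_um is None else u.depth_um,
                 int(u.is_multiunit))
            )
    spikes_df = pd.DataFrame(
        rows, columns=["unit_id", "region", "spike_time_s", "channel", "depth_um", "is_multiunit"]
    )
    # units with zero spikes still need a manifest so they round-trip
    unit_meta = [
        {
            "unit_id": u.unit_id,
            "region": u.region,
            "channel": None if u.channel is None else int(u.channel),
            "depth_um": None if u.depth_um is None else float(u.depth_um),
            "is_multiunit": bool(u.is_multiunit),
        }
        for u in session.spikes
    ]
    spikes_df.to_csv(path / "spikes.csv", index=False)
    session.trials.to_csv(path / "trials.csv", index=False)

    if session.hand is not None:
        kin = pd.DataFrame(
            {
                "t_s": session.hand.t,
                "x_mm": session.hand.position[0],
                "y_mm": session.hand.position[1],
                "z_mm": session.hand.position[2],
                "valid": session.hand.valid.astype(int),
            }
        )
        kin.to_csv(path / "kinematics.csv", index=False)

    for region in sorted(session.rates):
        rm = session.rates[region]
        df = pd.DataFrame(rm.values.T, columns=[f"ch{i}" for i in range(rm.values.shape[0])])
        df.insert(0, "t_s", rm.t)
        df.to_csv(path / f"rates_{region}.csv", index=False)

    if session.raw_probe is not None:
        import h5py

        with h5py.File(path / "raw_probe.h5", "w") as f:
            rp = session.raw_probe
            f.create_dataset("channel_positions_um", data=rp.channel_positions_um)
            f.create_dataset("voltage", data=rp.voltage)
            f.create_dataset("pulse_onsets", data=rp.pulse_onsets)
            f.attrs["sample_rate_hz"] = rp.sample_rate_hz

    meta = {
        "session_id": session.session_id,
        "animal_id": session.animal_id,
        "units": unit_meta,
        "hand_sample_rate_hz": None if session.hand is None else session.hand.sample_rate_hz,
        "config": session.config.to_dict(),
        "meta": session.meta,
    }
    (path / "session.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))


def read_session(path: str | Path) -> Session:
    """Read and validate a session directory written by :func:`write_session`."""
    path = Path(path)
    for required in ("session.yaml", "spikes.csv", "trials.csv"):
        if not (path / required).exists():
            raise SessionLoadError(f"missing required session file: {path / required}")
    meta = yaml.safe_load((path / "session.yaml").read_text())
    config = AnalysisConfig.from_dict(meta.get("config", {}))

    spikes_df = pd.read_csv(path / "spikes.csv", float_precision="round_trip")
    by_unit = {
        uid: g["spike_time_s"].to_numpy(dtype=float)
        for uid, g in spikes_df.groupby("unit_id", sort=False)
    }
    spikes = []
    for um in meta.get("units", []):
        spikes.append(
            SpikeTrain(
                unit_id=str(um["unit_id"]),
                region=um["region"],
                spike_times=by_unit.get(um["unit_id"], np.empty(0)),
                channel=um.get("channel"),
                depth_um=um.get("depth_um"),
                is_multiunit=bool(um.get("is_multiunit", False)),
            )
        )

    trials = pd.read_csv(
        path / "trials.csv", dtype={"trial_type": str, "delivery_mode": str},
        float_precision="round_trip",
    )

    hand = None
    if (path / "kinematics.csv").exists():
        kin = pd.read_csv(path / "kinematics.csv", float_precision="round_trip")
        hand = HandTrajectory(
            t=kin["t_s"].to_numpy(),
            position=np.vstack([kin["x_mm"], kin["y_mm"], kin["z_mm"]]),
            valid=kin["valid"].to_numpy(dtype=bool),
            sample_rate_hz=float(meta.get("hand_sample_rate_hz") or 500.0),
        )

    rates: dict[str, RateMatrix] = {}
    for f in sorted(path.glob("rates_*.csv")):
        region = f.stem.split("_", 1)[1]
        df = pd.read_csv(f, float_precision="round_trip")
        rates[region] = RateMatrix(
            region=region,
            t=df["t_s"].to_numpy(),
            values=df.drop(columns="t_s").to_numpy().T,
        )

    raw_probe = None
    if (path / "raw_probe.h5").exists():
        import h5py

        with h5py.File(path / "raw_probe.h5", "r") as f:
            raw_probe = RawProbeSnippet(
                channel_positions_um=f["channel_positions_um"][...],
                sample_rate_hz=float(f.attrs["sample_rate_hz"]),
                voltage=f["voltage"][...],
                pulse_onsets=f["pulse_onsets"][...],
            )

    return Session(
        session_id=str(meta["session_id"]),
        animal_id=str(meta["animal_id"]),
        spikes=spikes,
        trials=trials,
        hand=hand,
        rates=rates,
        raw_probe=raw_probe,
        config=config,
        meta=meta.get("meta", {}),
    )
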