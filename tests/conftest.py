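import numpy as np
import pandas as pd
import pytest

from reachloop import SimSpec, make_session
from reachloop.data_model import validate_trials


def trial_row(trial_id=0, trial_type="control", cue_time=np.nan, laser_on=np.nan,
              laser_off=np.nan, laser_freq_hz=np.nan, lift_time=np.nan,
              handopen_time=np.nan, grab_time=np.nan, atmouth_time=np.nan,
              reach_initiated=False, success_first=False, success_any=False,
              delivery_mode="table"):
    return dict(
        trial_id=trial_id, trial_type=trial_type, cue_time=cue_time,
        laser_on=laser_on, laser_off=laser_off, laser_freq_hz=laser_freq_hz,
        lift_time=lift_time, handopen_time=handopen_time, grab_time=grab_time,
        atmouth_time=atmouth_time, reach_initiated=reach_initiated,
        success_first=success_first, success_any=success_any,
        delivery_mode=delivery_mode,
    )


def make_cue_lift_trials(n_trials: int, seed: int = 0, spacing: float = 4.0) -> pd.DataFrame:
    """Trial table with cue and right-skewed reaction-time lifts."""
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(n_trials):
        cue = 2.0 + spacing * k
        lift = cue + 0.15 + rng.exponential(0.15)
        rows.append(trial_row(trial_id=k, cue_time=cue, lift_time=lift,
                              grab_time=lift + 0.25, reach_initiated=True,
                              success_first=True, success_any=True))
    return validate_trials(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def small_session():
    """One compact full-featured synthetic session, shared read-only."""
    spec = SimSpec(rng_seed=42, n_control=40, n_laser_cue=20, n_laser_only=20,
                   n_pn=8, n_pkj=6, n_dcn=8, n_pulses=40)
    return make_session(spec)


@pytest.fixture(scope="session")
def kinematic_session():
    """Kinematics/decoding-oriented session: channels only, no single units."""
    spec = SimSpec(rng_seed=7, n_control=40, n_laser_cue=16, n_laser_only=0,
                   n_pn=0, n_pkj=0, n_dcn=0, n_pulses=0)
    return make_session(spec)
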