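import numpy as np
import pytest

from oscipp.constants import hydrostatic_swing_mmhg
from oscipp.signal_sim import SimConfig, simulate_session, simulate_touch
from oscipp.signal_sim.sessions import SensorSession, _pulse_shape, oscillation_amplitude


@pytest.fixture
def default_config():
    return SimConfig(seed=11)


@pytest.fixture
def clean_session(default_config):
    """Noise-free default session (PP=40, b=5, Pc=mean BP) + ground truth."""
    return simulate_session(default_config)


@pytest.fixture
def noisy_session():
    cfg = SimConfig(noise_sd_ppg=0.005, noise_sd_accel=0.01, seed=12)
    return simulate_session(cfg)


def make_custom_session(config: SimConfig, z_of_t):
    """Build a session from an arbitrary z(t) trajectory using the same
    physics as the simulator.  Used to construct validity counterexamples
    (e.g. V-shaped hydrostatic traces) with a self-consistent PPG.
    """
    duration = config.raise_duration_s
    t_accel = np.arange(int(duration * config.accel_rate_hz) + 1) / config.accel_rate_hz
    t_ppg = np.arange(int(duration * config.ppg_rate_hz) + 1) / config.ppg_rate_hz
    t_touch = np.arange(int(duration * config.touch_rate_hz) + 1) / config.touch_rate_hz

    swing = hydrostatic_swing_mmhg(config.arm_length_m)
    z_ppg = np.asarray([z_of_t(t) for t in t_ppg], dtype=float)
    rhogh = swing * z_ppg
    pc = config.pc0 + config.pc_drift_mmHg * (t_ppg / duration)
    env = oscillation_amplitude(config.dp_heart + rhogh - pc, config.pp,
                                config.sigmoid_scale_mmHg)
    ppg = 1.0 + env * _pulse_shape(t_ppg, config.hr_bpm)

    pc_touch = config.pc0 + config.pc_drift_mmHg * (t_touch / duration)
    touch = simulate_touch(config, pc_touch, times=t_touch)
    accel = np.asarray([z_of_t(t) for t in t_accel], dtype=float)
    return SensorSession(
        t_ppg=t_ppg, ppg=ppg, t_accel=t_accel, accel_z=accel,
        t_touch=t_touch, touch_x=touch, arm_length_m=config.arm_length_m,
        metadata={"seed": config.seed, "ppg_rate_hz": config.ppg_rate_hz},
    )
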