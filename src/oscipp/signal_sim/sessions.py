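"""Physics-based simulator for hand-raise sensor sessions.

A session consists of three asynchronous channels — photoplethysmogram (PPG)
from the front camera, accelerometer z-axis in units of g, and the screen
touch x-centroid — plus the user's arm length.  The simulator produces these
from a small mechanistic model with known ground truth so the whole
estimation pipeline can be tested end to end:

* the hand raise is a raised-cosine trajectory taking the accelerometer
  z-channel from +1 (hand fully lowered) to -1 (fully raised);
* the hydrostatic offset is ``rho * g * L * z(t)`` converted to mmHg;
* the diastolic transmural pressure of the thumb artery is
  ``DP + rho*g*h(t) - Pc(t)`` where ``Pc`` is the thumb contact pressure;
* the pulse-volume oscillation amplitude follows a logistic-sigmoid
  blood-volume model of the artery, so sweeping transmural pressure through
  zero traces out an inverted-U oscillogram;
* the touch x-centroid saturates exponentially with contact pressure,
  optionally through a first-order viscoelastic lag.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.special import expit

from ..constants import DEFAULT_ARM_LENGTH_M, hydrostatic_swing_mmhg

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SensorSession",
    "simulate_hand_raise",
    "oscillation_amplitude",
    "simulate_touch",
    "simulate_session",
]

#: Touch-model defaults (screen-coordinate units / mmHg).  The exponential
#: saturation parameters are placeholders for unpublished device constants.
TOUCH_X_MAX = 200.0
TOUCH_TAU_MMHG = 50.0


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth physiology plus acquisition settings for one session."""

    sp_heart: float = 120.0
    dp_heart: float = 80.0
    hr_bpm: float = 70.0
    arm_length_m: float = DEFAULT_ARM_LENGTH_M
    #: Thumb contact pressure at raise onset; ``None`` means mean BP
    #: (DP + PP/2), the app's target.
    contact_pressure_mmHg: Optional[float] = None
    #: Linear drift of the contact pressure over the raise (mmHg end-start).
    pc_drift_mmHg: float = 0.0
    #: Arterial compliance width b of the logistic blood-volume sigmoid.
    sigmoid_scale_mmHg: float = 5.0
    raise_duration_s: float = 30.0
    ppg_rate_hz: float = 30.0
    accel_rate_hz: float = 50.0
    touch_rate_hz: float = 10.0
    noise_sd_ppg: float = 0.0
    noise_sd_accel: float = 0.0
    #: Multiplicative sensor drift of the touch channel over the raise.
    touch_drift_frac: float = 0.0
    #: First-order viscoelastic lag of contact area behind pressure (s).
    touch_lag_s: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (self.sp_heart > self.dp_heart > 0):
            raise ValueError(
                f"need sp_heart > dp_heart > 0, got {self.sp_heart}/{self.dp_heart}"
            )
        if self.sigmoid_scale_mmHg <= 0:
            raise ValueError("sigmoid_scale_mmHg must be positive")
        if self.raise_duration_s <= 0:
            raise ValueError("raise_duration_s must be positive")
        for name in ("ppg_rate_hz", "accel_rate_hz", "touch_rate_hz", "hr_bpm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.arm_length_m <= 0:
            raise ValueError("arm_length_m must be positive")

    @property
    def pp(self) -> float:
        return self.sp_heart - self.dp_heart

    @property
    def pc0(self) -> float:
        """Contact pressure at onset (defaults to mean BP)."""
        if self.contact_pressure_mmHg is None:
            return self.dp_heart + self.pp / 2.0
        return self.contact_pressure_mmHg

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class GroundTruth:
    pp_mmHg: float
    sp_heart: float
    dp_heart: float
    hr_bpm: float
    rhogh_t_s: np.ndarray
    rhogh_mmHg: np.ndarray
    beat_times_s: np.ndarray

    def __post_init__(self):
        assert abs(self.pp_mmHg - (self.sp_heart - self.dp_heart)) < 1e-9


@dataclass
class SensorSession:
    """Synchronized raw channels of one measurement attempt."""

    t_ppg: np.ndarray
    ppg: np.ndarray
    t_accel: np.ndarray
    accel_z: np.ndarray
    t_touch: np.ndarray
    touch_x: np.ndarray
    arm_length_m: float
    metadata: dict = field(default_factory=dict)

    def validate(self):
        from ..errors import SchemaError

        if self.arm_length_m <= 0:
            raise SchemaError(f"arm_length_m must be positive, got {self.arm_length_m}")
        for tname, vname in (("t_ppg", "ppg"), ("t_accel", "accel_z"), ("t_touch", "touch_x")):
            t = np.asarray(getattr(self, tname), dtype=float)
            v = np.asarray(getattr(self, vname), dtype=float)
            if t.shape != v.shape:
                raise SchemaError(f"{tname} and {vname} lengths differ")
            if t.size and np.any(np.diff(t) <= 0):
                raise SchemaError(f"{tname} is not strictly increasing")
        if self.accel_z.size and np.max(np.abs(self.accel_z)) > 2.0:
            raise SchemaError(
                "accel_z magnitude exceeds 2 g; expected unit-normalized z-channel",
                max_abs=float(np.max(np.abs(self.accel_z))),
            )


def _raise_profile(t: np.ndarray, duration_s: float) -> np.ndarray:
    """Noise-free raised-cosine z trajectory: +1 at t=0 to -1 at t=duration."""
    u = np.clip(np.asarray(t, dtype=float) / duration_s, 0.0, 1.0)
    return np.cos(np.pi * u)


def simulate_hand_raise(config: SimConfig, rng: Optional[np.random.Generator] = None):
    """Accelerometer z-channel (units of g) for a continuous hand raise.

    Returns ``(t_accel, accel_z)``.  The clean trajectory is a raised cosine
    from +1 to -1 over ``raise_duration_s``; Gaussian noise of sd
    ``noise_sd_accel`` is added and clipped to ±(1 + 3 sd).
    """
    if config.raise_duration_s <= 0:
        raise ValueError("raise_duration_s must be positive")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = int(np.floor(config.raise_duration_s * config.accel_rate_hz)) + 1
    t = np.arange(n) / config.accel_rate_hz
    z = _raise_profile(t, config.raise_duration_s)
    if config.noise_sd_accel > 0:
        z = z + rng.normal(0.0, config.noise_sd_accel, size=n)
        lim = 1.0 + 3.0 * config.noise_sd_accel
        z = np.clip(z, -lim, lim)
    return t, z


def oscillation_amplitude(p_tm_dia, pp: float, b: float):
    """Blood-volume oscillation amplitude at diastolic transmural pressure.

    With a logistic-sigmoid volume curve ``s(p) = expit(p / b)``, the
    peak-to-peak volume excursion of a beat spanning transmural pressures
    ``[p_tm_dia, p_tm_dia + pp]`` is ``s(p_tm_dia + pp) - s(p_tm_dia)``.
    Strictly positive, symmetric about ``p_tm_dia = -pp/2`` where it peaks,
    and vanishing as ``p_tm_dia -> ±inf``.

    Evaluated in the algebraically equivalent log-space form
    ``sinh(d/2) / (2 cosh(u/2) cosh(v/2))`` (``u, v`` the scaled sigmoid
    arguments, ``d = u - v``), which is exactly symmetric and avoids the
    cancellation of subtracting two near-saturated sigmoids.
    """
    if pp <= 0:
        raise ValueError("pp must be positive")
    if b <= 0:
        raise ValueError("b must be positive")
    p = np.asarray(p_tm_dia, dtype=float)
    u = (p + pp) / b
    v = p / b
    d = pp / b

    def logcosh_half(x):
        ax = np.abs(x) / 2.0
        return ax + np.log1p(np.exp(-2.0 * ax)) - np.log(2.0)

    logsinh_half = d / 2.0 + np.log1p(-np.exp(-d)) - np.log(2.0)
    out = np.exp(logsinh_half - logcosh_half(u) - logcosh_half(v) - np.log(2.0))
    return out if out.shape else float(out)


def simulate_touch(
    config: SimConfig,
    pc_trajectory,
    times=None,
    lag_s: Optional[float] = None,
):
    """Touch x-centroid series for a thumb contact-pressure trajectory.

    The centroid saturates exponentially with pressure,
    ``x = X_max * (1 - exp(-Pc / tau))``, optionally passed through a
    first-order lag modelling the slow viscoelastic response of thumb
    contact area to pressure changes.
    """
    pc = np.asarray(pc_trajectory, dtype=float)
    if np.any(pc < 0):
        raise ValueError("contact pressure must be non-negative")
    x = TOUCH_X_MAX * (1.0 - np.exp(-pc / TOUCH_TAU_MMHG))
    if lag_s is None:
        lag_s = config.touch_lag_s
    if lag_s and lag_s > 0 and x.size > 1:
        if times is None:
            times = np.arange(x.size) / config.touch_rate_hz
        times = np.asarray(times, dtype=float)
        y = np.empty_like(x)
        y[0] = x[0]
        # exact exponential step of dy/dt = (x - y)/lag with piecewise-const x
        a = 1.0 - np.exp(-np.diff(times) / lag_s)
        for i in range(1, x.size):
            y[i] = y[i - 1] + a[i - 1] * (x[i] - y[i - 1])
        x = y
    return x


def _pulse_shape(t: np.ndarray, hr_bpm: float) -> np.ndarray:
    """Rectified half-sine beat train at constant heart rate, peak 1."""
    f = hr_bpm / 60.0
    return np.maximum(np.sin(2.0 * np.pi * f * t), 0.0)


def simulate_session(config: SimConfig):
    """Generate one complete sensor session plus its ground truth.

    Returns ``(SensorSession, GroundTruth)``.  Deterministic: the same
    config (including seed) yields bit-identical output.
    """
    root = np.random.SeedSequence([config.seed, 0])
    rng_accel = np.random.default_rng(root.spawn(1)[0])
    rng_ppg = np.random.default_rng(root.spawn(1)[0])

    duration = config.raise_duration_s
    t_accel, accel_z = simulate_hand_raise(config, rng=rng_accel)

    n_ppg = int(np.floor(duration * config.ppg_rate_hz)) + 1
    t_ppg = np.arange(n_ppg) / config.ppg_rate_hz
    swing = hydrostatic_swing_mmhg(config.arm_length_m)
    rhogh_ppg = swing * _raise_profile(t_ppg, duration)

    pc_ppg = config.pc0 + config.pc_drift_mmHg * (t_ppg / duration)
    p_tm_dia = config.dp_heart + rhogh_ppg - pc_ppg
    envelope = oscillation_amplitude(p_tm_dia, config.pp, config.sigmoid_scale_mmHg)
    ppg = 1.0 + envelope * _pulse_shape(t_ppg, config.hr_bpm)
    if config.noise_sd_ppg > 0:
        ppg = ppg + rng_ppg.normal(0.0, config.noise_sd_ppg, size=n_ppg)

    n_touch = int(np.floor(duration * config.touch_rate_hz)) + 1
    t_touch = np.arange(n_touch) / config.touch_rate_hz
    pc_touch = config.pc0 + config.pc_drift_mmHg * (t_touch / duration)
    touch_x = simulate_touch(config, pc_touch, times=t_touch)
    if config.touch_drift_frac:
        touch_x = touch_x * (1.0 + config.touch_drift_frac * (t_touch / duration))

    # peak of the oscillogram sits at P_tm,dia = -PP/2; if the sweep never
    # crosses it the oscillogram cannot have both limbs
    crosses_peak = p_tm_dia.min() <= -config.pp / 2.0 <= p_tm_dia.max()

    beat_period = 60.0 / config.hr_bpm
    k = np.arange(int(np.floor((duration - 0.25 * beat_period) / beat_period)) + 1)
    beat_times = (k + 0.25) * beat_period  # half-sine crest times

    session = SensorSession(
        t_ppg=t_ppg,
        ppg=ppg,
        t_accel=t_accel,
        accel_z=accel_z,
        t_touch=t_touch,
        touch_x=touch_x,
        arm_length_m=config.arm_length_m,
        metadata={
            "seed": config.seed,
            "ppg_rate_hz": config.ppg_rate_hz,
            "accel_rate_hz": config.accel_rate_hz,
            "touch_rate_hz": config.touch_rate_hz,
            "raise_duration_s": duration,
            "incomplete_by_construction": not crosses_peak,
        },
    )
    truth = GroundTruth(
        pp_mmHg=config.pp,
        sp_heart=config.sp_heart,
        dp_heart=config.dp_heart,
        hr_bpm=config.hr_bpm,
        rhogh_t_s=t_ppg,
        rhogh_mmHg=rhogh_ppg,
        beat_times_s=beat_times,
    )
    return session, truth
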