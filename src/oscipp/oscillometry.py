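"""Pulse-pressure computation from a hand-raise sensor session.

Pipeline: detect pulse-volume beats in the PPG, convert the accelerometer
z-channel to the hydrostatic pressure offset rho*g*h, pair each beat's
peak-to-peak amplitude with its beat-averaged rho*g*h to form a discrete
(shifted) oscillogram, smooth with a 5-point unweighted moving average, fit
a five-parameter difference-of-logistic-CDFs model, and read PP off as the
width between the maximum-slope and minimum-slope points of the fitted
curve (the classic derivative algorithm).  Because the unknown thumb
contact pressure only shifts the oscillogram along the pressure axis, this
width is identifiable even though absolute systolic/diastolic pressures
are not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import maximum_filter1d, minimum_filter1d
from scipy.optimize import least_squares, minimize_scalar
from scipy.signal import butter, find_peaks, peak_prominences, sosfiltfilt
from scipy.special import expit

from .constants import G_M_S2, PA_PER_MMHG, RHO_BLOOD_KG_M3
from .errors import (
    BeatDetectionError,
    DerivativeError,
    FitError,
    OscillogramError,
    ValidityError,
)

__all__ = [
    "BeatSeries",
    "DiscreteOscillogram",
    "OscillogramFit",
    "PPResult",
    "detect_beats",
    "compute_rhogh",
    "build_oscillogram",
    "smooth_oscillogram",
    "fit_oscillogram",
    "oscillogram_model",
    "oscillogram_slope",
    "compute_pp",
    "compute_hr",
    "estimate",
]

MIN_BEATS_FOR_OSCILLOGRAM = 5  # a 5-point moving average needs 5 samples


@dataclass
class BeatSeries:
    """Per-beat detections: crest times, peak-to-peak amplitudes, spans."""

    beat_times_s: np.ndarray
    pa: np.ndarray
    intervals_s: np.ndarray
    spans_s: np.ndarray  # (n, 2) trough-to-trough time span of each beat
    no_oscillations: bool = False

    def __len__(self):
        return len(self.beat_times_s)


@dataclass
class DiscreteOscillogram:
    """(rho*g*h, normalized pulse amplitude) pairs, one per beat.

    Stored sorted by descending rho*g*h, i.e. chronological order during a
    hand raise.
    """

    rhogh: np.ndarray
    pa_norm: np.ndarray

    def __post_init__(self):
        self.rhogh = np.asarray(self.rhogh, dtype=float)
        self.pa_norm = np.asarray(self.pa_norm, dtype=float)
        if self.rhogh.shape != self.pa_norm.shape:
            raise OscillogramError("rhogh and pa_norm lengths differ")

    def __len__(self):
        return len(self.rhogh)


@dataclass
class OscillogramFit:
    """The five fitted parameters of the continuous oscillogram model.

    Model: ``O(x) = amp * [S((x - c1)/w1) - S((x - c2)/w2)]`` with S the
    logistic CDF; an inverted-U between the rising edge at ``c1`` and the
    falling edge at ``c2``.
    """

    amp: float
    c1: float
    c2: float
    w1: float
    w2: float
    rms_residual: float

    def __post_init__(self):
        if self.w1 <= 0 or self.w2 <= 0:
            raise FitError("widths must be positive", w1=self.w1, w2=self.w2)
        if not self.c1 < self.c2:
            raise FitError("fit collapsed: c1 >= c2", c1=self.c1, c2=self.c2)

    @property
    def params(self) -> np.ndarray:
        return np.array([self.amp, self.c1, self.c2, self.w1, self.w2])


@dataclass
class PPResult:
    pp_mmHg: Optional[float]
    hr_bpm: Optional[float]
    fit: Optional[OscillogramFit]
    validity: "object" = None  # ValidityReport; typed loosely to avoid cycle
    oscillogram: Optional[DiscreteOscillogram] = None
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# beat detection


def detect_beats(
    ppg,
    rate_hz: float,
    *,
    band_hz=(0.5, 10.0),
    prominence_frac: float = 0.3,
    env_window_s: float = 2.0,
    min_beat_interval_s: float = 0.25,
) -> BeatSeries:
    """Detect pulse-volume oscillations and their peak-to-peak amplitudes.

    The PPG is band-pass filtered (zero phase), candidate crests are found,
    and crests are kept when their prominence exceeds ``prominence_frac``
    of the local (rolling) signal amplitude — an adaptive threshold that
    follows the slowly varying oscillation envelope.  Each beat's amplitude
    is measured trough-to-peak.  A constant or oscillation-free signal
    yields an empty series with ``no_oscillations`` set.
    """
    x_raw = np.asarray(ppg, dtype=float)
    if rate_hz <= 0:
        raise BeatDetectionError("rate_hz must be positive")
    if x_raw.size / rate_hz < 10.0:
        raise BeatDetectionError("need at least 10 s of PPG signal",
                                 duration_s=x_raw.size / rate_hz)

    lo, hi = band_hz
    hi = min(hi, 0.45 * rate_hz)
    sos = butter(2, [lo, hi], btype="bandpass", fs=rate_hz, output="sos")
    x = sosfiltfilt(sos, x_raw)
    t = np.arange(x.size) / rate_hz

    w = max(3, int(env_window_s * rate_hz) | 1)
    env = maximum_filter1d(x, w) - minimum_filter1d(x, w)
    floor = 1e-8 * max(1.0, float(np.max(np.abs(x_raw))))

    cand, _ = find_peaks(x, distance=max(1, int(min_beat_interval_s * rate_hz)))
    empty = BeatSeries(
        beat_times_s=np.empty(0), pa=np.empty(0), intervals_s=np.empty(0),
        spans_s=np.empty((0, 2)), no_oscillations=True,
    )
    if cand.size == 0:
        return empty
    prom = peak_prominences(x, cand)[0]
    keep = (prom >= prominence_frac * env[cand]) & (env[cand] > floor)
    peaks = cand[keep]
    if peaks.size == 0:
        return empty

    # trough-to-peak amplitude; spans run trough-to-trough around each crest
    starts = np.empty(peaks.size, dtype=int)
    ends = np.empty(peaks.size, dtype=int)
    pa = np.empty(peaks.size)
    prev = 0
    for i, pk in enumerate(peaks):
        trough = prev + int(np.argmin(x[prev:pk + 1]))
        starts[i] = trough
        pa[i] = x[pk] - x[trough]
        prev = pk
    for i, pk in enumerate(peaks):
        nxt = peaks[i + 1] if i + 1 < peaks.size else x.size - 1
        ends[i] = pk + int(np.argmin(x[pk:nxt + 1]))

    good = pa > 0
    # a first crest whose "trough" is the signal boundary has no observed
    # trough-to-peak swing; discard it
    if starts[0] == 0:
        good[0] = False
    peaks, pa, starts, ends = peaks[good], pa[good], starts[good], ends[good]
    if peaks.size == 0:
        return empty
    return BeatSeries(
        beat_times_s=t[peaks],
        pa=pa,
        intervals_s=np.diff(t[peaks]),
        spans_s=np.column_stack([t[starts], t[ends]]),
        no_oscillations=False,
    )


# ---------------------------------------------------------------------------
# hydrostatic conversion


def compute_rhogh(
    accel_z,
    arm_length_m: float,
    *,
    rho: float = RHO_BLOOD_KG_M3,
    g: float = G_M_S2,
):
    """Convert accelerometer z (units of g) to hydrostatic pressure in mmHg.

    The z-channel reads +1 with the hand fully lowered and -1 fully raised;
    multiplying by blood density, gravity and the arm length gives the
    pressure offset of the thumb artery relative to heart level (positive
    below the heart).  Input is clipped to [-1, +1] before conversion.
    """
    if arm_length_m <= 0:
        raise ValueError(f"arm_length_m must be positive, got {arm_length_m}")
    z = np.clip(np.asarray(accel_z, dtype=float), -1.0, 1.0)
    out = rho * g * arm_length_m * z / PA_PER_MMHG
    return out if out.shape else float(out)


# ---------------------------------------------------------------------------
# oscillogram construction


def build_oscillogram(beats: BeatSeries, t_rhogh, rhogh) -> DiscreteOscillogram:
    """Pair each beat's amplitude with its beat-averaged rho*g*h.

    The amplitude of every beat is paired with the mean of rho*g*h over
    that beat's time span, then all amplitudes are normalized to a maximum
    of unity.
    """
    if len(beats) < MIN_BEATS_FOR_OSCILLOGRAM:
        raise OscillogramError(
            f"need at least {MIN_BEATS_FOR_OSCILLOGRAM} beats, got {len(beats)}"
        )
    t_rhogh = np.asarray(t_rhogh, dtype=float)
    rhogh = np.asarray(rhogh, dtype=float)
    if beats.spans_s[:, 0].min() < t_rhogh[0] - 1e-9 or \
       beats.spans_s[:, 1].max() > t_rhogh[-1] + 1e-9:
        raise OscillogramError("rhogh series does not cover all beat spans")

    mean_rhogh = np.empty(len(beats))
    for i, (a, b) in enumerate(beats.spans_s):
        if b <= a:
            mean_rhogh[i] = float(np.interp(a, t_rhogh, rhogh))
        else:
            tt = np.linspace(a, b, 51)
            mean_rhogh[i] = float(np.trapezoid(np.interp(tt, t_rhogh, rhogh), tt) / (b - a))

    pa_norm = beats.pa / beats.pa.max()
    order = np.argsort(-mean_rhogh, kind="stable")
    return DiscreteOscillogram(rhogh=mean_rhogh[order], pa_norm=pa_norm[order])


def smooth_oscillogram(osc: DiscreteOscillogram, window: int = 5) -> DiscreteOscillogram:
    """Unweighted centered moving average of the amplitudes.

    Edges use shrinking symmetric windows (1-point at the ends, 3-point one
    in, ...).  The pressure axis is unchanged.
    """
    n = len(osc)
    if n < window:
        raise OscillogramError(f"need at least {window} points, got {n}")
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    half = window // 2
    y = osc.pa_norm
    out = np.empty(n)
    for i in range(n):
        k = min(half, i, n - 1 - i)
        out[i] = y[i - k:i + k + 1].mean()
    return DiscreteOscillogram(rhogh=osc.rhogh.copy(), pa_norm=out)


# ---------------------------------------------------------------------------
# model fitting


def oscillogram_model(x, amp, c1, c2, w1, w2):
    """Five-parameter continuous oscillogram: difference of logistic CDFs."""
    x = np.asarray(x, dtype=float)
    return amp * (expit((x - c1) / w1) - expit((x - c2) / w2))


def oscillogram_slope(x, amp, c1, c2, w1, w2):
    """Analytic derivative of :func:`oscillogram_model` with respect to x."""
    x = np.asarray(x, dtype=float)
    s1 = expit((x - c1) / w1)
    s2 = expit((x - c2) / w2)
    return amp * (s1 * (1.0 - s1) / w1 - s2 * (1.0 - s2) / w2)


_DEFAULT_START_WIDTHS = (2.0, 5.0, 10.0)


def fit_oscillogram(
    osc: DiscreteOscillogram,
    *,
    start_widths=_DEFAULT_START_WIDTHS,
    tol: float = 1e-10,
    require_interior_peak: bool = True,
) -> OscillogramFit:
    """Fit the five-parameter model by bounded nonlinear least squares.

    Uses a fixed multi-start list (centers at rho*g*h quantiles, widths from
    ``start_widths``) for determinism and keeps the best solution.  Data
    whose amplitude peak sits at either end (a single-limb / monotone
    oscillogram) are rejected unless ``require_interior_peak`` is False.
    """
    x = osc.rhogh
    y = osc.pa_norm
    if len(osc) < MIN_BEATS_FOR_OSCILLOGRAM:
        raise FitError("too few oscillogram points", n=len(osc))
    peak = int(np.argmax(y))
    if require_interior_peak and (peak == 0 or peak == len(y) - 1):
        raise FitError(
            "oscillogram peak at boundary: one limb missing (monotone data)",
            peak_index=peak, n=len(y),
        )

    xmin, xmax = float(x.min()), float(x.max())
    span = max(xmax - xmin, 1.0)
    lb = np.array([1e-6, xmin - span, xmin - span, 0.05, 0.05])
    ub = np.array([10.0, xmax + span, xmax + span, 2.0 * span, 2.0 * span])

    def residuals(theta):
        return oscillogram_model(x, *theta) - y

    q = np.quantile(x, [0.15, 0.3, 0.45, 0.55, 0.7, 0.85])
    center_pairs = [(q[0], q[5]), (q[1], q[4]), (q[2], q[3])]
    amp0 = max(float(y.max()), 1e-3)
    best = None
    for c1_0, c2_0 in center_pairs:
        if c2_0 <= c1_0:  # degenerate quantiles on narrow data
            c1_0, c2_0 = c1_0 - 1.0, c1_0 + 1.0
        for w0 in start_widths:
            theta0 = np.clip([amp0, c1_0, c2_0, w0, w0], lb, ub)
            try:
                sol = least_squares(
                    residuals, theta0, bounds=(lb, ub),
                    xtol=tol, ftol=tol, gtol=tol, method="trf",
                )
            except Exception:  # pragma: no cover - scipy internal failure
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        raise FitError("all fit starts failed")

    amp, c1, c2, w1, w2 = best.x
    rms = float(np.sqrt(np.mean(residuals(best.x) ** 2)))
    if not c1 < c2:
        raise FitError("fit converged to a non-inverted-U solution",
                       c1=float(c1), c2=float(c2), rms=rms)
    return OscillogramFit(amp=float(amp), c1=float(c1), c2=float(c2),
                          w1=float(w1), w2=float(w2), rms_residual=rms)


# ---------------------------------------------------------------------------
# derivative algorithm


def _support(fit: OscillogramFit, pad_widths: float = 8.0):
    pad = pad_widths * max(fit.w1, fit.w2)
    return fit.c1 - pad, fit.c2 + pad


def compute_pp(fit: OscillogramFit, *, grid_points: int = 4001) -> float:
    """Pulse pressure as the slope-extrema width of the fitted oscillogram.

    The maximum and minimum of dO/dx are located on a dense grid over the
    fitted support and refined by bounded scalar optimization; PP is the
    pressure distance from the maximum-slope point (rising limb) to the
    minimum-slope point (falling limb).
    """
    lo, hi = _support(fit)
    grid = np.linspace(lo, hi, grid_points)
    d = oscillogram_slope(grid, *fit.params)
    i_max = int(np.argmax(d))
    i_min = int(np.argmin(d))
    if d[i_max] <= 0 or d[i_min] >= 0 or not grid[i_max] < grid[i_min]:
        raise DerivativeError(
            "fitted curve has no sign-changing slope-extrema pair",
            slope_max=float(d[i_max]), slope_min=float(d[i_min]),
        )
    step = grid[1] - grid[0]

    def refine(idx, sign):
        a = max(lo, grid[idx] - 2 * step)
        b = min(hi, grid[idx] + 2 * step)
        res = minimize_scalar(
            lambda u: sign * oscillogram_slope(u, *fit.params),
            bounds=(a, b), method="bounded",
            options={"xatol": 1e-10},
        )
        return float(res.x)

    x_max_slope = refine(i_max, -1.0)
    x_min_slope = refine(i_min, +1.0)
    pp = x_min_slope - x_max_slope
    if pp <= 0:
        raise DerivativeError("non-positive slope-extrema width", pp=pp)
    return pp


def compute_hr(beats: BeatSeries) -> float:
    """Heart rate in bpm from the median inter-beat interval."""
    if len(beats) < 2:
        raise BeatDetectionError("need at least 2 beats for heart rate",
                                 n=len(beats))
    return 60.0 / float(np.median(beats.intervals_s))


# ---------------------------------------------------------------------------
# orchestration


def estimate(session, config=None, *, force: bool = False) -> PPResult:
    """Run the full PP pipeline on a sensor session.

    Chains beat detection, hydrostatic conversion, oscillogram
    construction, smoothing, the three validity checks, model fitting and
    the derivative algorithm.  PP is reported only when the measurement is
    valid, unless ``force`` is set.  Stage failures raise errors carrying
    the failing stage's name.
    """
    from .config import RunConfig
    from .validity import evaluate_validity

    if config is None:
        config = RunConfig()
    session.validate()

    beats = detect_beats(
        session.ppg,
        config.algorithm.ppg_rate_of(session),
        band_hz=(config.algorithm.filter_lo_hz, config.algorithm.filter_hi_hz),
        prominence_frac=config.algorithm.prominence_frac,
    )
    if beats.no_oscillations:
        raise BeatDetectionError("no blood-volume oscillations detected")

    rhogh = compute_rhogh(session.accel_z, session.arm_length_m,
                          rho=config.physics.rho_blood_kg_m3,
                          g=config.physics.g_m_s2)
    osc = build_oscillogram(beats, session.t_accel, rhogh)
    smoothed = smooth_oscillogram(osc, window=config.algorithm.smooth_window)
    if config.algorithm.normalize_after_smooth:
        smoothed = DiscreteOscillogram(
            rhogh=smoothed.rhogh, pa_norm=smoothed.pa_norm / smoothed.pa_norm.max()
        )

    report = evaluate_validity(session, smoothed, rhogh, config=config)
    hr = compute_hr(beats) if len(beats) >= 2 else None

    if not report.overall and not force:
        return PPResult(pp_mmHg=None, hr_bpm=hr, fit=None, validity=report,
                        oscillogram=smoothed,
                        diagnostics={"reason": "validity failed"})

    fit = fit_oscillogram(smoothed,
                          require_interior_peak=not force,
                          tol=config.algorithm.fit_tol)
    pp = compute_pp(fit, grid_points=config.algorithm.pp_grid_points)
    return PPResult(pp_mmHg=pp, hr_bpm=hr, fit=fit, validity=report,
                    oscillogram=smoothed)
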