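"""Valid-measurement rules and thumb contact-area guidance.

A measurement is valid when (i) the thumb contact area changed by less
than 5% during the hand raise, (ii) the oscillogram falls below 50% of its
maximum on both the increasing and decreasing limbs (both limbs present),
and (iii) the hydrostatic pressure trace is close to linear in time.  The
"visually linear" rule is operationalized as an r-squared and a
dominant-sign monotone-fraction threshold, both configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidityError
from .oscillometry import DiscreteOscillogram

__all__ = [
    "ValidityReport",
    "check_contact_area",
    "check_completeness",
    "check_rhogh_linearity",
    "compute_target_area",
    "halve",
    "evaluate_validity",
]

CONTACT_AREA_MAX_FRAC = 0.05
LIMB_MAX_FRAC = 0.5
LINEARITY_MIN_R2 = 0.9
MONOTONE_MIN_FRAC = 0.9
DEFAULT_PERCENT_INCREASE = 0.10


@dataclass
class ValidityReport:
    contact_area_change_frac: float
    limb_min_frac_ascending: float
    limb_min_frac_descending: float
    rhogh_linearity_r2: float
    monotone_fraction: float
    contact_area_ok: bool
    completeness_ok: bool
    linearity_ok: bool
    notes: tuple = ()

    @property
    def overall(self) -> bool:
        return self.contact_area_ok and self.completeness_ok and self.linearity_ok

    def to_dict(self) -> dict:
        return {
            "contact_area_change_frac": self.contact_area_change_frac,
            "limb_min_frac_ascending": self.limb_min_frac_ascending,
            "limb_min_frac_descending": self.limb_min_frac_descending,
            "rhogh_linearity_r2": self.rhogh_linearity_r2,
            "monotone_fraction": self.monotone_fraction,
            "contact_area_ok": self.contact_area_ok,
            "completeness_ok": self.completeness_ok,
            "linearity_ok": self.linearity_ok,
            "overall": self.overall,
            "notes": list(self.notes),
        }


def check_contact_area(touch_x, max_frac: float = CONTACT_AREA_MAX_FRAC):
    """Fractional change of the contact-area surrogate during the raise.

    Returns ``(fraction, passed)`` where ``fraction = (max - min) / max``
    over the raise window; passes when strictly below ``max_frac``.
    """
    x = np.asarray(touch_x, dtype=float)
    if x.size == 0:
        raise ValidityError("empty touch series")
    hi = float(x.max())
    if hi <= 0:
        return float("nan"), False  # no-contact
    frac = float((hi - x.min()) / hi)
    return frac, frac < max_frac


def check_completeness(osc: DiscreteOscillogram, max_frac: float = LIMB_MAX_FRAC):
    """Both-limbs-present rule on a (smoothed) oscillogram.

    Locates the amplitude peak and checks that the minimum of each limb
    drops below ``max_frac`` of the maximum.  Returns
    ``((ascending_min_frac, descending_min_frac), passed)``; a peak at
    either end means a limb is missing and fails.
    """
    y = np.asarray(osc.pa_norm, dtype=float)
    if y.size < 5:
        raise ValidityError("need at least 5 oscillogram points", n=y.size)
    peak = int(np.argmax(y))
    top = float(y[peak])
    asc = float(y[: peak + 1].min() / top)
    desc = float(y[peak:].min() / top)
    if peak == 0 or peak == y.size - 1:
        return (asc, desc), False
    return (asc, desc), (asc < max_frac) and (desc < max_frac)


def check_rhogh_linearity(
    rhogh,
    times,
    min_r2: float = LINEARITY_MIN_R2,
    min_monotone_frac: float = MONOTONE_MIN_FRAC,
):
    """Linearity + monotonicity of the hydrostatic trace.

    Fits a least-squares line of rho*g*h against time and computes the
    fraction of successive differences sharing the dominant sign.  A
    non-monotone trace indicates a changing wrist-hand angle.  Returns
    ``(r2, monotone_fraction, passed)``.
    """
    y = np.asarray(rhogh, dtype=float)
    t = np.asarray(times, dtype=float)
    if y.size < 10:
        raise ValidityError("need at least 10 rhogh samples", n=y.size)
    if np.ptp(y) == 0:
        return 0.0, 0.0, False  # no raise detected
    res = stats.linregress(t, y)
    r2 = float(res.rvalue**2)
    d = np.diff(y)
    n_pos = int(np.sum(d > 0))
    n_neg = int(np.sum(d < 0))
    mono = float(max(n_pos, n_neg) / d.size)
    return r2, mono, (r2 >= min_r2) and (mono >= min_monotone_frac)


def compute_target_area(touch_x_at_onset: float, percent_increase: float) -> float:
    """Target contact-area surrogate shown to the user at raise onset.

    ``target = onset * (1 + percent_increase)``.
    """
    if touch_x_at_onset <= 0:
        raise ValueError("touch_x_at_onset must be positive")
    if percent_increase <= 0:
        raise ValueError("percent_increase must be positive")
    return touch_x_at_onset * (1.0 + percent_increase)


def halve(percent_increase: float) -> float:
    """Fallback when the oscillogram shows no ascending limb: halve the
    fixed percentage increase."""
    if percent_increase <= 0:
        raise ValueError("percent_increase must be positive")
    return percent_increase / 2.0


def evaluate_validity(session, smoothed_osc: DiscreteOscillogram, rhogh,
                      config=None) -> ValidityReport:
    """Run all three criteria on one session and assemble the report."""
    from .config import RunConfig

    if config is None:
        config = RunConfig()
    v = config.validity

    notes = []
    frac, area_ok = check_contact_area(session.touch_x, v.contact_area_max_frac)
    if np.isnan(frac):
        notes.append("no-contact")
    (asc, desc), comp_ok = check_completeness(smoothed_osc, v.limb_max_frac)
    r2, mono, lin_ok = check_rhogh_linearity(
        rhogh, session.t_accel, v.linearity_min_r2, v.monotone_min_frac
    )
    if session.metadata.get("incomplete_by_construction"):
        notes.append("incomplete-by-construction")
    return ValidityReport(
        contact_area_change_frac=frac,
        limb_min_frac_ascending=asc,
        limb_min_frac_descending=desc,
        rhogh_linearity_r2=r2,
        monotone_fraction=mono,
        contact_area_ok=area_ok,
        completeness_ok=comp_ok,
        linearity_ok=lin_ok,
        notes=tuple(notes),
    )
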