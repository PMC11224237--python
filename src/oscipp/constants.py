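"""Physical constants used for hydrostatic-pressure conversion."""

#: Blood density, kg/m^3.
RHO_BLOOD_KG_M3 = 1060.0

#: Standard gravity, m/s^2.
G_M_S2 = 9.81

#: Pascals per mmHg.
PA_PER_MMHG = 133.322

#: Typical adult arm length, m (gives a hydrostatic swing of ~±45 mmHg).
DEFAULT_ARM_LENGTH_M = 0.577


def hydrostatic_swing_mmhg(arm_length_m: float) -> float:
    """Hydrostatic pressure offset (mmHg) of the hand one arm length below
    heart level: rho * g * L expressed in mmHg."""
    if arm_length_m <= 0:
        raise ValueError(f"arm_length_m must be positive, got {arm_length_m}")
    return RHO_BLOOD_KG_M3 * G_M_S2 * arm_length_m / PA_PER_MMHG
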