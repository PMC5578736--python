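"""Unit conversions.

All internal computation uses micrometres and seconds. Diffusion
coefficients from the physiology literature arrive in cm^2/s and
convective velocities in um/min; the converters below are exact
(1 cm^2/s = 1e8 um^2/s).
"""

CM2_PER_S_TO_UM2_PER_S = 1.0e8
UM2_PER_S_TO_CM2_PER_S = 1.0e-8


def cm2_per_s_to_um2_per_s(d: float) -> float:
    """Convert a diffusion coefficient from cm^2/s to um^2/s."""
    return d * CM2_PER_S_TO_UM2_PER_S


def um2_per_s_to_cm2_per_s(d: float) -> float:
    """Convert a diffusion coefficient from um^2/s to cm^2/s."""
    return d * UM2_PER_S_TO_CM2_PER_S


def um_per_min_to_um_per_s(v: float) -> float:
    """Convert a velocity from um/min to um/s."""
    return v / 60.0


def um_per_s_to_um_per_min(v: float) -> float:
    """Convert a velocity from um/s to um/min."""
    return v * 60.0


def minutes_to_seconds(t: float) -> float:
    return t * 60.0
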