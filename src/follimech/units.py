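"""Unit conversions used throughout the package.

All lengths are micrometres, pressures are pascals internally, and
cavity pressures are reported in mmHg (the convention of the pressure-
sensing literature this package follows).
"""

MMHG_TO_PA: float = 133.322
"""Pascals per mmHg (conventional value)."""

UM_TO_M: float = 1e-6


def mmhg_to_pa(p_mmhg: float) -> float:
    return p_mmhg * MMHG_TO_PA


def pa_to_mmhg(p_pa: float) -> float:
    return p_pa / MMHG_TO_PA
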