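"""Unit conversions.

All solver-internal arithmetic is SI (Pa, m, m^3/s, Pa.s/m^3).  Clinical
units — mmHg for pressure, mm for geometry, mL/s for flow, L/min for cardiac
output, mmHg.s/mL for lumped resistances — appear only at module boundaries.
Keeping the conversions in one place avoids mixed-unit resistance bugs.
"""

MMHG = 133.322387415  # Pa per mmHg


def mmhg_to_pa(p: float) -> float:
    return p * MMHG


def pa_to_mmhg(p: float) -> float:
    return p / MMHG


def mm_to_m(x: float) -> float:
    return x * 1e-3


def ml_s_to_m3_s(q: float) -> float:
    return q * 1e-6


def m3_s_to_ml_s(q: float) -> float:
    return q * 1e6


def l_min_to_ml_s(q: float) -> float:
    return q * 1000.0 / 60.0


def resistance_mmhg_ml_to_si(r: float) -> float:
    """mmHg.s/mL -> Pa.s/m^3."""
    return r * MMHG / 1e-6


def resistance_si_to_mmhg_ml(r: float) -> float:
    """Pa.s/m^3 -> mmHg.s/mL."""
    return r * 1e-6 / MMHG
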