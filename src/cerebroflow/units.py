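"""Unit conversions.

The public API speaks clinical units (mm, mL/min); all internal arithmetic
is SI (m, Pa, m³/s).  Conversions are centralised here so no other module
carries literal factors.
"""

MM_TO_M = 1e-3
M_TO_MM = 1e3

#: 1 m³/s in mL/min
M3S_TO_MLMIN = 6e7
MLMIN_TO_M3S = 1.0 / M3S_TO_MLMIN


def mm_to_m(x: float) -> float:
    return x * MM_TO_M


def mlmin_to_m3s(q: float) -> float:
    return q * MLMIN_TO_M3S


def m3s_to_mlmin(q: float) -> float:
    return q * M3S_TO_MLMIN
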