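"""Unit conversions.

Canonical internal units are micrometers (µm) for length and cubic
micrometers (µm³) for volume; everything else converts through the
constants below, which live only here.  Report helpers round the way the
source literature prints its numbers so that fixture comparisons are
well defined.
"""

from __future__ import annotations

UM_PER_MM = 1e3
UM_PER_CM = 1e4
UM_PER_M = 1e6
UM_PER_KM = 1e9

UM3_PER_MM3 = 1e9
UM3_PER_CM3 = 1e12

MM_PER_UM = 1.0 / UM_PER_MM

#: unit ladder for human-readable reporting, largest first
_LADDER = (("km", UM_PER_KM), ("m", UM_PER_M), ("cm", UM_PER_CM), ("mm", UM_PER_MM), ("um", 1.0))


def round_length_report(length_um: float) -> tuple[float, str]:
    """Round a length the way per-neuron axon lengths are conventionally
    printed: to the nearest centimeter below 2 m, to the nearest meter above.

    Returns ``(value, unit)`` with unit ``"cm"`` or ``"m"``.
    """
    meters = length_um / UM_PER_M
    if meters < 2.0:
        return float(round(length_um / UM_PER_CM)), "cm"
    return float(round(meters)), "m"


def to_human_unit(length_um: float) -> tuple[float, str]:
    """Express a length in the largest unit in which its value is >= 1.

    ``to_human_unit(3e5)`` -> ``(30.0, "cm")``.  Zero is reported in µm.
    """
    for unit, factor in _LADDER:
        value = length_um / factor
        if abs(value) >= 1.0:
            return value, unit
    return float(length_um), "um"


def round_to_sig(value: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if value == 0:
        return 0.0
    from math import floor, log10

    return round(value, -int(floor(log10(abs(value)))) + (sig - 1))
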