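"""Unit conversions used when comparing chamber geometries.

The chamber literature mixes imperial box dimensions (inches) with metric
volumes (litres); these helpers make the conversion explicit so volume
comparisons between rigs are reproducible.
"""

from __future__ import annotations

from .errors import ValidationError

#: Exact definition: 1 inch = 2.54 cm, so 1 in^3 = 2.54^3 cm^3 = 16.387064 mL.
LITERS_PER_CUBIC_INCH = 0.016387064


def cubic_inches_to_liters(volume_in3: float) -> float:
    """Convert a volume in cubic inches to litres."""
    if volume_in3 < 0:
        raise ValidationError("volume_in3", "volume must be non-negative")
    return volume_in3 * LITERS_PER_CUBIC_INCH


def box_volume_liters(length_in: float, width_in: float, height_in: float) -> float:
    """Volume of a rectangular box given in inches, returned in litres."""
    for name, v in (("length_in", length_in), ("width_in", width_in), ("height_in", height_in)):
        if v <= 0:
            raise ValidationError(name, "dimension must be positive")
    return cubic_inches_to_liters(length_in * width_in * height_in)
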