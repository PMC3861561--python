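"""Area and density arithmetic for calibrated microscope fields.

A ×40 field of 310.3 x 232.72 μm covers 0.072213 mm²; nuclear density is
reported in nuclei/mm² over that fixed area.  Only rectangular fields are
modelled — the circular high-power field used for mitosis counting plays no
role here because histological grade is consumed as an input.
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, Field

from .annotations import FieldGeometry

UM2_PER_MM2 = 1_000_000.0


class FieldArea(BaseModel):
    """Field area in mm²."""

    model_config = ConfigDict(frozen=True)

    area_mm2: float = Field(gt=0, allow_inf_nan=False)


def field_area_mm2(geometry: FieldGeometry) -> FieldArea:
    """Exact μm² → mm² product conversion of a field's dimensions."""
    return FieldArea(area_mm2=geometry.width_um * geometry.height_um / UM2_PER_MM2)


def nuclear_density(n_nuclei: int, area: FieldArea | float) -> float:
    """Nuclei per mm².

    Full precision is returned; the reporting layer rounds to the nearest
    integer for presentation.
    """
    if n_nuclei < 0:
        raise ValueError("n_nuclei must be non-negative")
    area_mm2 = area.area_mm2 if isinstance(area, FieldArea) else float(area)
    if area_mm2 <= 0:
        raise ValueError("area must be strictly positive")
    return n_nuclei / area_mm2
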