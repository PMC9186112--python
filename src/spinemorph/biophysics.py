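"""Passive spine-neck electrical resistance model.

For a neck of length l and radius r, the passive resistance scales as
R ~ l / (pi r^2); the cytosolic resistivity constant is deliberately left
out, so the index carries units of um^-1 and only ratios (or values scaled
to a measured reference) are physically meaningful.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class NeckGeometry:
    length_um: float
    radius_um: float

    def __post_init__(self):
        if not (self.length_um > 0 and self.radius_um > 0):
            raise ValueError("neck length and radius must be positive")

    @classmethod
    def from_median_columns(cls, neck_length_um: float, neck_diameter_nm: float
                            ) -> "NeckGeometry":
        """Build from morphometry-table units (length um, diameter nm),
        halving the diameter and rounding the radius to the nanometer."""
        radius_um = round(neck_diameter_nm / 2.0) / 1000.0
        return cls(length_um=float(neck_length_um), radius_um=radius_um)


def resistance_index(g: NeckGeometry) -> float:
    """l / (pi r^2) in um^-1."""
    return g.length_um / (np.pi * g.radius_um**2)


def resistance_ratio(a: NeckGeometry, b: NeckGeometry) -> float:
    """index(a) / index(b); invariant to a common unit rescaling."""
    return resistance_index(a) / resistance_index(b)


def absolute_resistance(g: NeckGeometry, reference_g: NeckGeometry,
                        reference_megohm: float) -> float:
    """Scale a measured reference resistance to geometry ``g`` (MOhm)."""
    if reference_megohm <= 0:
        raise ValueError("reference resistance must be positive")
    return reference_megohm * resistance_ratio(g, reference_g)


def group_median_geometry(table, group_mask) -> NeckGeometry:
    """Median neck geometry (length, diameter) of the selected rows."""
    import pandas as pd

    sel = table.loc[group_mask]
    lengths = pd.to_numeric(sel["neck_length_um"], errors="coerce").dropna()
    diams = pd.to_numeric(sel["neck_diameter_nm"], errors="coerce").dropna()
    if lengths.empty or diams.empty:
        raise ValueError("no neck measurements in selection")
    return NeckGeometry.from_median_columns(float(lengths.median()),
                                            float(diams.median()))
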