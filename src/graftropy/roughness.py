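"""Roughness metrics for heightfields: surface area, empirical fractal
dimension, and altitude statistics.

The empirical fractal dimension of an integer heightfield is
``D_F = ln(X) / ln(L)`` where ``X`` is the total exposed surface area (the
flat tops of all cells plus the side-wall panels between adjacent cells of
different altitude, in units of a**2) and ``L`` is the projected edge
length.  A flat surface has ``D_F = 2`` exactly; extremely rough fields tend
toward 3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .surfaces import HeightField


@dataclass
class RoughnessReport:
    """Summary of a heightfield's roughness."""

    area_total: float
    L: int
    D_F: float
    sigma_emp: float


def surface_area(field: HeightField) -> float:
    """Total exposed area: cell tops plus interior side walls (units a**2).

    Each of the ``L**2`` cells contributes a unit top face; every interior
    4-neighbour pair of cells contributes ``|Δz|`` unit wall panels.
    Boundary cells contribute no exterior walls (those are artifacts of the
    finite window) and no bottom faces.
    """
    if field.L < 2:
        raise ValueError("surface area needs at least a 2x2 grid")
    z = field.z.astype(np.int64)
    walls = np.abs(np.diff(z, axis=0)).sum() + np.abs(np.diff(z, axis=1)).sum()
    return float(field.L**2 + walls)


def fractal_dimension(field: HeightField) -> float:
    """Empirical fractal dimension ``ln(area) / ln(L)``."""
    if field.L < 2:
        raise ValueError("fractal dimension undefined for L < 2")
    return float(np.log(surface_area(field)) / np.log(field.L))


def altitude_std(field: HeightField) -> float:
    """Population standard deviation of the integer altitudes (units a)."""
    return float(field.z.std())


def characterize(field: HeightField) -> RoughnessReport:
    """Compute all roughness metrics of ``field`` in one pass."""
    return RoughnessReport(
        area_total=surface_area(field),
        L=field.L,
        D_F=fractal_dimension(field),
        sigma_emp=altitude_std(field),
    )
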