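"""Sectional contact areas, cutoff-series decomposition and ruggedness ratio.

The sectional (flattened) contact area at cutoff t is the physical area of
the distance-map pixels whose inter-surface gap is at most t: pixel count ×
unit area.  Computing it for an ascending series of cutoffs (1, 3, 5 Å by
default) and differencing gives partial areas per gap band — contour lines
of the interface — whose shares of the largest cumulative area sum to 100%.
Dividing an externally obtained buried 3-D surface area (e.g. from PISA) by
the 5 Å sectional area measures the ruggedness of the interface: ≈ 1 for a
flat contact, larger for convex/concave ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .depthmap import DistanceMap

__all__ = [
    "AreaSeries",
    "RuggednessReport",
    "contact_area",
    "area_series",
    "area_ratio",
    "series_table",
]

DEFAULT_CUTOFFS = (1.0, 3.0, 5.0)


@dataclass(frozen=True)
class AreaSeries:
    """Cumulative, partial and percentage contact areas over ascending cutoffs.

    ``partial_area[k]`` is the area of the gap band between consecutive
    cutoffs (the first band reaches from the minimum gap to the first
    cutoff); percentages are relative to the largest cumulative area.
    """

    cutoffs: tuple[float, ...]
    cumulative_area: tuple[float, ...]
    partial_area: tuple[float, ...]
    percentage: tuple[float, ...]

    @classmethod
    def from_cumulative(cls, cutoffs: Sequence[float],
                        cumulative: Sequence[float]) -> "AreaSeries":
        cutoffs = tuple(float(c) for c in cutoffs)
        cumulative = tuple(float(a) for a in cumulative)
        if len(cutoffs) != len(cumulative):
            raise ValueError("cutoffs and cumulative areas differ in length")
        if any(b <= a for a, b in zip(cutoffs, cutoffs[1:])):
            raise ValueError(f"cutoffs must be strictly ascending: {cutoffs}")
        if any(b < a - 1e-9 for a, b in zip(cumulative, cumulative[1:])):
            raise ValueError("cumulative areas must be non-decreasing")
        partial = (cumulative[0],) + tuple(
            b - a for a, b in zip(cumulative, cumulative[1:]))
        total = cumulative[-1]
        if total > 0:
            pct = tuple(100.0 * p / total for p in partial)
        else:
            pct = tuple(0.0 for _ in partial)
        return cls(cutoffs, cumulative, partial, pct)

    def to_dict(self) -> dict:
        return {
            "cutoffs": list(self.cutoffs),
            "cumulative_area": list(self.cumulative_area),
            "partial_area": list(self.partial_area),
            "percentage": list(self.percentage),
        }


@dataclass(frozen=True)
class RuggednessReport:
    """Buried 3-D surface area vs flattened sectional area.

    ``ratio`` = surface/sectional; near 1 for a flat interface, up to ~4 for
    a sphere-like contact (4πr² / πr², both hemispheres buried).
    """

    sectional_area: float
    surface_area: float

    @property
    def ratio(self) -> float:
        return area_ratio(self.surface_area, self.sectional_area)

    def to_dict(self) -> dict:
        return {
            "sectional_area": float(self.sectional_area),
            "surface_area": float(self.surface_area),
            "ratio": self.ratio,
            "ratio_1dp": round(self.ratio, 1),
        }


def contact_area(dist_map: DistanceMap, t: float) -> float:
    """Sectional contact area at cutoff t (Å): defined pixels with gap ≤ t × u.

    Negative gaps (interpenetration along the binding axis) satisfy any
    positive cutoff and are counted.
    """
    if not t > 0:
        raise ValueError("cutoff t must be positive")
    with np.errstate(invalid="ignore"):
        n = int(np.count_nonzero(dist_map.defined & (dist_map.values <= t)))
    return n * dist_map.unit_area


def area_series(dist_map: DistanceMap,
                cutoffs: Sequence[float] = DEFAULT_CUTOFFS) -> AreaSeries:
    """Cumulative contact areas for ascending cutoffs, with partials and shares."""
    cutoffs = tuple(float(c) for c in cutoffs)
    if any(c <= 0 for c in cutoffs):
        raise ValueError("cutoffs must be positive")
    if any(b <= a for a, b in zip(cutoffs, cutoffs[1:])):
        raise ValueError(f"cutoffs must be strictly ascending: {cutoffs}")
    cumulative = [contact_area(dist_map, t) for t in cutoffs]
    return AreaSeries.from_cumulative(cutoffs, cumulative)


def area_ratio(surface_area: float, sectional_area: float) -> float:
    """Ruggedness ratio: buried 3-D surface area over flattened sectional area."""
    if not surface_area > 0:
        raise ValueError(f"surface area must be positive, got {surface_area}")
    if not sectional_area > 0:
        raise ValueError(f"sectional area must be positive, got {sectional_area}")
    return surface_area / sectional_area


def series_table(label: str, series: AreaSeries,
                 surface_area: float | None = None) -> pd.DataFrame:
    """One-row report of a cutoff series (areas at 1 decimal as reported).

    Columns mirror the standard interface report: cumulative area per
    cutoff, partial area and percentage per band, and — when a buried
    surface area is supplied — the surface/sectional ruggedness ratio.
    """
    row: dict[str, float | str] = {"id": label}
    for c, a in zip(series.cutoffs, series.cumulative_area):
        row[f"area_{c:g}A"] = round(a, 1)
    bands = [f"<{series.cutoffs[0]:g}A"] + [
        f"{a:g}-{b:g}A" for a, b in zip(series.cutoffs, series.cutoffs[1:])]
    for band, p in zip(bands, series.partial_area):
        row[f"partial_{band}"] = round(p, 1)
    for band, p in zip(bands, series.percentage):
        row[f"pct_{band}"] = round(p, 1)
    if surface_area is not None:
        report = RuggednessReport(sectional_area=series.cumulative_area[-1],
                                  surface_area=surface_area)
        row["surface_area"] = round(surface_area, 1)
        row["area_ratio"] = round(report.ratio, 1)
    return pd.DataFrame([row])
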