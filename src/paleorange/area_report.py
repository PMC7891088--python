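"""Latitude-weighted area accounting, change tables and cross-tabulations.

Cell areas come from the spherical band formula on the authalic-radius
sphere, so per-category areas partition the land total exactly (same
floating-point sums) and a global grid sums to the sphere's surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import LatLonGrid
from .stratification import NODATA_ID
from .suitability_mapping import CATEGORY_NAMES, NODATA_CODE, CategoryMap

#: Authalic Earth radius, km.
EARTH_RADIUS_KM = 6371.0072


def cell_area(lat, resolution: float) -> np.ndarray:
    """Area in km^2 of a ``resolution x resolution`` degree cell centred
    at latitude ``lat`` (spherical band slice)."""
    lat = np.asarray(lat, dtype=float)
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude out of range")
    r = resolution / 2.0
    lat_hi = np.deg2rad(np.minimum(lat + r, 90.0))
    lat_lo = np.deg2rad(np.maximum(lat - r, -90.0))
    band = 2.0 * np.pi * EARTH_RADIUS_KM**2 * (np.sin(lat_hi) - np.sin(lat_lo))
    return band * (resolution / 360.0)


def cell_area_grid(grid: LatLonGrid) -> np.ndarray:
    """Per-cell area grid, km^2, shape ``grid.shape``."""
    per_row = cell_area(grid.lat_centers(), grid.resolution)
    return np.broadcast_to(per_row[:, None], grid.shape).copy()


@dataclass
class AreaReport:
    slice_label: str
    total_land_km2: float
    areas_km2: dict[int, float] = field(default_factory=dict)  # category code -> km^2

    def percentages(self) -> dict[int, float]:
        """Percent of slice land area per category, to 1 decimal."""
        if self.total_land_km2 <= 0:
            return {c: 0.0 for c in self.areas_km2}
        return {
            c: round(100.0 * a / self.total_land_km2, 1)
            for c, a in self.areas_km2.items()
        }

    def to_frame(self) -> pd.DataFrame:
        pct = self.percentages()
        return pd.DataFrame(
            {
                "slice": self.slice_label,
                "category": list(self.areas_km2),
                "category_name": [CATEGORY_NAMES.get(c, str(c)) for c in self.areas_km2],
                "area_km2": list(self.areas_km2.values()),
                "percent_of_land": [pct[c] for c in self.areas_km2],
            }
        )


def area_by_category(cmap: CategoryMap, slice_label: str = "") -> AreaReport:
    """Sum cell areas per category code over the land mask."""
    areas = cell_area_grid(cmap.grid)
    land = cmap.land_mask
    codes = cmap.codes
    out: dict[int, float] = {}
    for code in np.unique(codes[land]):
        out[int(code)] = float(areas[land & (codes == code)].sum())
    total = float(areas[land].sum())
    return AreaReport(slice_label=slice_label, total_land_km2=total, areas_km2=out)


def compare_time_slices(reports: list[AreaReport]) -> pd.DataFrame:
    """Per-category absolute and relative changes between consecutive
    report pairs, plus a total-land-area row per pair (flagging
    sea-level-driven extent differences)."""
    if len(reports) < 2:
        raise ValueError("need at least two reports to compare")
    rows = []
    for a, b in zip(reports[:-1], reports[1:]):
        cats = sorted(set(a.areas_km2) | set(b.areas_km2))
        for c in cats:
            av = a.areas_km2.get(c, 0.0)
            bv = b.areas_km2.get(c, 0.0)
            rows.append(
                {
                    "from_slice": a.slice_label,
                    "to_slice": b.slice_label,
                    "category": c,
                    "category_name": CATEGORY_NAMES.get(c, str(c)),
                    "area_from_km2": av,
                    "area_to_km2": bv,
                    "abs_change_km2": bv - av,
                    "rel_change": (bv - av) / av if av > 0 else np.nan,
                }
            )
        rows.append(
            {
                "from_slice": a.slice_label,
                "to_slice": b.slice_label,
                "category": NODATA_CODE,
                "category_name": "total land",
                "area_from_km2": a.total_land_km2,
                "area_to_km2": b.total_land_km2,
                "abs_change_km2": b.total_land_km2 - a.total_land_km2,
                "rel_change": (b.total_land_km2 - a.total_land_km2) / a.total_land_km2
                if a.total_land_km2 > 0
                else np.nan,
            }
        )
    return pd.DataFrame(rows)


def zone_area_within_range(
    zones: np.ndarray, range_mask: np.ndarray, grid: LatLonGrid
) -> pd.DataFrame:
    """Per-zone total area, area inside the range mask, and the
    within-range fraction (realized vs fundamental comparison)."""
    zones = np.asarray(zones)
    range_mask = np.asarray(range_mask, dtype=bool)
    if zones.shape != grid.shape or range_mask.shape != grid.shape:
        raise ValueError("zone map and range mask must be aligned with the grid")
    areas = cell_area_grid(grid)
    rows = []
    for z in np.unique(zones):
        if z == NODATA_ID:
            continue
        sel = zones == z
        total = float(areas[sel].sum())
        inside = float(areas[sel & range_mask].sum())
        rows.append(
            {
                "zone": int(z),
                "total_area_km2": total,
                "range_area_km2": inside,
                "range_fraction": inside / total if total > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["zone", "total_area_km2", "range_area_km2", "range_fraction"])


def crosstab_categories(
    labels: np.ndarray, landcover: np.ndarray, grid: LatLonGrid
) -> pd.DataFrame:
    """Area-weighted contingency table of two integer rasters (rows:
    strata/zones, columns: land-cover classes), with label 0 treated as
    nodata in both."""
    labels = np.asarray(labels)
    landcover = np.asarray(landcover)
    if labels.shape != grid.shape or landcover.shape != grid.shape:
        raise ValueError("rasters must be aligned with the grid")
    areas = cell_area_grid(grid)
    valid = (labels != NODATA_ID) & (landcover != NODATA_ID)
    df = pd.DataFrame(
        {
            "label": labels[valid],
            "cover": landcover[valid],
            "area": areas[valid],
        }
    )
    table = df.pivot_table(
        index="label", columns="cover", values="area", aggfunc="sum", fill_value=0.0
    )
    return table


def row_proportions(table: pd.DataFrame) -> pd.DataFrame:
    """Normalise a crosstab so every row sums to 1."""
    sums = table.sum(axis=1)
    return table.div(sums.replace(0.0, np.nan), axis=0)
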