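"""Per-stratum favourability categories and ensemble combination.

Five ordered base categories are assigned from the area share of each
stratum that the binary niche model marks suitable:

    [0, 10%)  unsuitable
    [10, 40%) low use
    [40, 60%) utilised
    [60, 80%) favoured
    [80, 100%] highly favoured

Boundaries are left-closed (the printed "<10%" upper bound of the
lowest class forces exactly 10% into "low use"); the top interval is
closed at 100%.

Category maps from a pseudo-GCM ensemble are combined cellwise: a
unique modal category wins; a two-way tie between ADJACENT categories
becomes a joint class; any other tie is "uncertain".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd

from .grids import LatLonGrid
from .stratification import NODATA_ID, StrataMap

logger = logging.getLogger(__name__)


class Category(IntEnum):
    UNSUITABLE = 0
    LOW_USE = 1
    UTILISED = 2
    FAVOURED = 3
    HIGHLY_FAVOURED = 4


#: Joint class code for the adjacent pair (c, c+1) is JOINT_BASE + c.
JOINT_BASE = 5
UNCERTAIN = 9
NODATA_CODE = -1

BASE_NAMES = {
    Category.UNSUITABLE: "unsuitable",
    Category.LOW_USE: "low use",
    Category.UTILISED: "utilised",
    Category.FAVOURED: "favoured",
    Category.HIGHLY_FAVOURED: "highly favoured",
}

CATEGORY_NAMES = {int(c): name for c, name in BASE_NAMES.items()}
for _c in range(4):
    CATEGORY_NAMES[JOINT_BASE + _c] = (
        f"{BASE_NAMES[Category(_c)]}/{BASE_NAMES[Category(_c + 1)]}"
    )
CATEGORY_NAMES[UNCERTAIN] = "uncertain"
CATEGORY_NAMES[NODATA_CODE] = "nodata"

#: Lower edges of categories 1..4 as fractions.
CATEGORY_BOUNDS = (0.10, 0.40, 0.60, 0.80)


def joint_code(a: int, b: int) -> int:
    """Code of the joint class for two adjacent base categories."""
    lo, hi = (a, b) if a < b else (b, a)
    if hi - lo != 1:
        raise ValueError(f"joint classes exist only for adjacent categories, got {a}, {b}")
    return JOINT_BASE + lo


def categorize(fraction: float) -> Category:
    """Base category for a suitable-area fraction in [0, 1]."""
    if not (0.0 <= fraction <= 1.0):
        raise ValueError(f"fraction must lie in [0, 1], got {fraction}")
    idx = 0
    for bound in CATEGORY_BOUNDS:
        if fraction >= bound:
            idx += 1
    return Category(idx)


@dataclass
class CategoryMap:
    """Per-cell category codes (base, joint or uncertain); -1 off-mask."""

    grid: LatLonGrid
    codes: np.ndarray  # (n_lat, n_lon) int16

    @property
    def land_mask(self) -> np.ndarray:
        return self.codes != NODATA_CODE

    def legend(self) -> dict[int, str]:
        present = np.unique(self.codes)
        return {int(c): CATEGORY_NAMES[int(c)] for c in present}


def suitable_fraction_by_stratum(
    binary: np.ndarray,
    strata: StrataMap,
    cell_areas: np.ndarray,
) -> pd.DataFrame:
    """Area-weighted suitable fraction and category per stratum.

    ``binary`` is the 1/0/NaN grid from the niche-model binarization,
    ``cell_areas`` the per-cell area grid in km^2. Strata with no land
    cells inside the extent are omitted (logged). Cells that are land
    in the strata map but NaN in the binary grid count as unsuitable
    area (the model made no positive claim there).
    """
    if binary.shape != strata.strata.shape or cell_areas.shape != binary.shape:
        raise ValueError("binary grid, strata map and cell areas must be aligned")
    rows = []
    suitable = np.nan_to_num(binary, nan=0.0)
    ids = np.unique(strata.strata)
    ids = ids[ids != NODATA_ID]
    for sid in ids:
        sel = strata.strata == sid
        total = float(cell_areas[sel].sum())
        if total <= 0:
            logger.info("stratum %d has zero area in extent; omitted", sid)
            continue
        suit = float((cell_areas[sel] * suitable[sel]).sum())
        frac = suit / total
        rows.append(
            {
                "stratum": int(sid),
                "zone": int(strata.zones[sel][0]),
                "suitable_area_km2": suit,
                "total_area_km2": total,
                "fraction": frac,
                "category": int(categorize(frac)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "stratum",
            "zone",
            "suitable_area_km2",
            "total_area_km2",
            "fraction",
            "category",
        ],
    )


def apply_categories(strata: StrataMap, table: pd.DataFrame) -> CategoryMap:
    """Paint each cell with its stratum's category; nodata preserved."""
    ids_present = np.unique(strata.strata)
    ids_present = ids_present[ids_present != NODATA_ID]
    lookup = dict(zip(table["stratum"].astype(int), table["category"].astype(int)))
    missing = sorted(set(ids_present.tolist()) - set(lookup))
    if missing:
        raise ValueError(f"strata missing from the category table: {missing}")
    max_id = int(ids_present.max()) if ids_present.size else 0
    lut = np.full(max_id + 1, NODATA_CODE, dtype=np.int16)
    for sid, cat in lookup.items():
        if sid <= max_id:
            lut[sid] = cat
    codes = np.full(strata.strata.shape, NODATA_CODE, dtype=np.int16)
    land = strata.strata != NODATA_ID
    codes[land] = lut[strata.strata[land]]
    return CategoryMap(grid=strata.grid, codes=codes)


def _combine_counts(counts: np.ndarray) -> int:
    """Combine a 5-vector of per-category votes into a single code."""
    top = counts.max()
    winners = np.nonzero(counts == top)[0]
    if winners.size == 1:
        return int(winners[0])
    if winners.size == 2 and winners[1] - winners[0] == 1:
        return joint_code(int(winners[0]), int(winners[1]))
    return UNCERTAIN


def combine_ensemble(maps: list[CategoryMap]) -> CategoryMap:
    """Cellwise modal combination of aligned base-category maps.

    Unique mode -> that category; top count tied between two adjacent
    categories -> joint class; any other tie -> uncertain. A cell is
    nodata in the result only where it is nodata in every member.
    """
    if not maps:
        raise ValueError("combine_ensemble needs at least one map")
    grid = maps[0].grid
    shape = maps[0].codes.shape
    for m in maps[1:]:
        if m.grid != grid or m.codes.shape != shape:
            raise ValueError("ensemble members are not aligned")
    stack = np.stack([m.codes for m in maps])
    if stack.max() > int(Category.HIGHLY_FAVOURED):
        raise ValueError("ensemble members must contain base categories only")
    counts = np.zeros((5,) + shape, dtype=np.int32)
    for c in range(5):
        counts[c] = (stack == c).sum(axis=0)
    total = counts.sum(axis=0)

    top = counts.max(axis=0)
    is_top = counts == top
    n_top = is_top.sum(axis=0)
    first = np.argmax(is_top, axis=0)
    last = 4 - np.argmax(is_top[::-1], axis=0)

    out = np.full(shape, NODATA_CODE, dtype=np.int16)
    voted = total > 0
    unique = voted & (n_top == 1)
    out[unique] = first[unique]
    adjacent = voted & (n_top == 2) & (last - first == 1)
    out[adjacent] = (JOINT_BASE + first[adjacent]).astype(np.int16)
    other_tie = voted & ~unique & ~adjacent
    out[other_tie] = UNCERTAIN
    return CategoryMap(grid=grid, codes=out)


#: The published collapse table for joint classes, keyed by label.
#: "unsuitable/utilised" cannot arise from combine_ensemble (that tie is
#: non-adjacent, hence uncertain) but the printed rule is kept verbatim.
PRINTED_COLLAPSE = {
    "highly favoured/favoured": "highly favoured",
    "favoured/highly favoured": "highly favoured",
    "favoured/utilised": "favoured",
    "utilised/favoured": "favoured",
    "low use/utilised": "utilised",
    "unsuitable/utilised": "low use",
    # not in the printed table; follows its adjacent-pair pattern
    "unsuitable/low use": "low use",
}

_NAME_TO_BASE = {name: int(cat) for cat, name in BASE_NAMES.items()}


def collapse_label(label: str) -> str:
    """Collapse a (possibly joint) class label to a base-category label."""
    if label in _NAME_TO_BASE or label == "uncertain":
        return label
    if label in PRINTED_COLLAPSE:
        return PRINTED_COLLAPSE[label]
    raise ValueError(f"unknown class label: {label!r}")


def collapse_classes(cmap: CategoryMap) -> CategoryMap:
    """Collapse joint classes to base categories using the printed
    mapping table; base categories and uncertain pass through.
    Idempotent."""
    codes = cmap.codes
    out = codes.copy()
    joints = (codes >= JOINT_BASE) & (codes < UNCERTAIN)
    for code in np.unique(codes[joints]):
        target = collapse_label(CATEGORY_NAMES[int(code)])
        out[codes == code] = _NAME_TO_BASE[target]
    known = (
        (codes == NODATA_CODE)
        | ((codes >= 0) & (codes <= int(Category.HIGHLY_FAVOURED)))
        | joints
        | (codes == UNCERTAIN)
    )
    if not np.all(known):
        bad = sorted(np.unique(codes[~known]).tolist())
        raise ValueError(f"unknown category codes: {bad}")
    return CategoryMap(grid=cmap.grid, codes=out)
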