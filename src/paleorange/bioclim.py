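"""The four bioclimatic variables driving stratification and niche models.

* growing degree-days on a 0 degC base (degC*days / year)
* temperature seasonality (population SD of monthly means x 100)
* aridity index (annual precipitation / annual PET, dimensionless)
* PET seasonality (coefficient of variation of monthly PET x 100)

PET uses the Hargreaves formulation with extraterrestrial radiation from
standard solar geometry (a fixed 365-day calendar; mid-month days of
year). The formula is pluggable via the ``pet_fn`` argument of
:func:`build_bioclim_stack`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .grids import LatLonGrid
from .synthetic_data import MonthlyClimate

DAYS_IN_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31], dtype=float)
#: Mid-month day of year on the 365-day calendar.
MID_MONTH_DOY = np.cumsum(DAYS_IN_MONTH) - DAYS_IN_MONTH / 2.0

#: Aridity index reported when annual PET is zero (hyper-humid cap).
HYPER_HUMID_CAP = 100.0

VARIABLE_NAMES = ("gdd0", "temp_seasonality", "aridity_index", "pet_seasonality")


@dataclass
class BioclimStack:
    """The four variables as 2-D grids (NaN off the land mask)."""

    grid: LatLonGrid
    gdd0: np.ndarray
    temp_seasonality: np.ndarray
    aridity_index: np.ndarray
    pet_seasonality: np.ndarray
    land_mask: np.ndarray

    def layers(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in VARIABLE_NAMES}

    def feature_matrix(self) -> np.ndarray:
        """Land-cell values as an (n_land, 4) matrix in VARIABLE_NAMES order."""
        return np.column_stack(
            [getattr(self, name)[self.land_mask] for name in VARIABLE_NAMES]
        )

    def values_at(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """(n, 4) matrix of variable values at the given cells."""
        return np.column_stack(
            [getattr(self, name)[rows, cols] for name in VARIABLE_NAMES]
        )


def extraterrestrial_radiation(lat, doy) -> np.ndarray:
    """Daily extraterrestrial radiation in mm-equivalent water per day.

    Standard solar-geometry formulation: solar constant 0.0820
    MJ m-2 min-1, inverse relative Earth-Sun distance and solar
    declination as sinusoids of the day of year, sunset hour angle
    clamped for polar day/night, and a 0.408 mm per MJ m-2 conversion.
    """
    lat = np.asarray(lat, dtype=float)
    doy = np.asarray(doy, dtype=float)
    phi = np.deg2rad(lat)
    dr = 1.0 + 0.033 * np.cos(2.0 * np.pi * doy / 365.0)
    delta = 0.409 * np.sin(2.0 * np.pi * doy / 365.0 - 1.39)
    x = -np.tan(phi) * np.tan(delta)
    ws = np.arccos(np.clip(x, -1.0, 1.0))
    gsc = 0.0820  # MJ m-2 min-1
    ra_mj = (
        (24.0 * 60.0 / np.pi)
        * gsc
        * dr
        * (ws * np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.sin(ws))
    )
    return 0.408 * np.maximum(ra_mj, 0.0)


def compute_pet_hargreaves(tmean, tmin, tmax, lat) -> np.ndarray:
    """Monthly Hargreaves PET (mm/month), clamped at zero.

    ``PET_m = 0.0023 * RA_m * (tmean_m + 17.8) * sqrt(tmax_m - tmin_m) * days_m``

    Parameters are 12-month arrays broadcastable against one another;
    ``lat`` broadcasts over the spatial axes.
    """
    tmean = np.asarray(tmean, dtype=float)
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    if tmean.shape[0] != 12:
        raise ValueError("expected 12 monthly grids on axis 0")
    if np.any(tmin > tmax + 1e-9):
        raise ValueError("tmin exceeds tmax in at least one cell")
    lat = np.asarray(lat, dtype=float)
    extra = (1,) * (tmean.ndim - 1)
    doy = MID_MONTH_DOY.reshape((12,) + extra)
    days = DAYS_IN_MONTH.reshape((12,) + extra)
    ra = extraterrestrial_radiation(lat[None, ...], doy)
    pet_daily = 0.0023 * ra * (tmean + 17.8) * np.sqrt(np.maximum(tmax - tmin, 0.0))
    return np.maximum(pet_daily, 0.0) * days


def compute_gdd0(tmean) -> np.ndarray:
    """Growing degree-days above 0 degC: sum of clamped monthly means
    weighted by month lengths (365-day calendar)."""
    tmean = np.asarray(tmean, dtype=float)
    if tmean.shape[0] != 12:
        raise ValueError("expected 12 monthly grids on axis 0")
    extra = (1,) * (tmean.ndim - 1)
    days = DAYS_IN_MONTH.reshape((12,) + extra)
    return np.sum(np.maximum(tmean, 0.0) * days, axis=0)


def compute_temp_seasonality(tmean) -> np.ndarray:
    """Population standard deviation of the 12 monthly means, x 100."""
    tmean = np.asarray(tmean, dtype=float)
    if tmean.shape[0] != 12:
        raise ValueError("expected 12 monthly grids on axis 0")
    return np.std(tmean, axis=0) * 100.0


def compute_aridity_index(prec, pet, hyper_humid_cap: float = HYPER_HUMID_CAP) -> np.ndarray:
    """Annual precipitation over annual PET; zero-PET cells get the cap."""
    prec = np.asarray(prec, dtype=float)
    pet = np.asarray(pet, dtype=float)
    if np.any(prec < 0):
        raise ValueError("precipitation must be non-negative")
    if np.any(pet < 0):
        raise ValueError("PET must be non-negative")
    p_ann = prec.sum(axis=0)
    pet_ann = pet.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(pet_ann > 0, p_ann / np.where(pet_ann > 0, pet_ann, 1.0), np.nan)
    return np.where(pet_ann > 0, out, np.where(p_ann > 0, hyper_humid_cap, 0.0))


def compute_pet_seasonality(pet) -> np.ndarray:
    """Coefficient of variation of monthly PET x 100 (0 where mean PET is 0)."""
    pet = np.asarray(pet, dtype=float)
    mean = pet.mean(axis=0)
    sd = pet.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, 100.0 * sd / np.where(mean > 0, mean, 1.0), 0.0)
    return cv


def build_bioclim_stack(
    climate: MonthlyClimate,
    pet_fn: Callable[..., np.ndarray] = compute_pet_hargreaves,
) -> BioclimStack:
    """Compose the four variables from a monthly climate; cells off the
    land mask become NaN."""
    lat = climate.grid.lat_grid()
    pet = pet_fn(climate.tmean, climate.tmin, climate.tmax, lat)
    layers = {
        "gdd0": compute_gdd0(climate.tmean),
        "temp_seasonality": compute_temp_seasonality(climate.tmean),
        "aridity_index": compute_aridity_index(climate.prec, pet),
        "pet_seasonality": compute_pet_seasonality(pet),
    }
    mask = climate.land_mask
    for name, arr in layers.items():
        out = np.where(mask, arr, np.nan)
        if not np.all(np.isfinite(out[mask])):
            raise ValueError(f"non-finite {name} values on the land mask")
        layers[name] = out
    return BioclimStack(grid=climate.grid, land_mask=mask.copy(), **layers)
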