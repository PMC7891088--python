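"""Seeded synthetic inputs: climate grids, pseudo-GCM ensembles, land
masks, occurrence records, range masks and land-cover rasters.

The generators are parametric stand-ins for the real gridded climate and
locality inputs of a continental niche-modelling study: temperature
follows a latitudinal lapse with a seasonal cycle, precipitation is a
background level plus a movable Gaussian "pluvial belt", pseudo-GCM
ensemble members are smooth random perturbations of a base climate, and
occurrences are drawn cell-wise from a supplied suitability surface.
Every generator is a pure function of its parameters and a seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage

from .grids import KM_PER_DEGREE, LatLonGrid

logger = logging.getLogger(__name__)

SLICE_LABELS = ("present", "mid-holocene", "lgm")


@dataclass(frozen=True)
class ScenarioSpec:
    """Knobs of the parametric climate generator.

    ``pluvial_center_lat`` / ``pluvial_width`` / ``pluvial_peak_precip``
    position a Gaussian belt of high precipitation, emulating pluvial
    versus interpluvial configurations. ``sea_level_offset`` widens the
    land mask by that many cells of coastal dilation (used for the
    low-sea-level glacial slice).
    """

    base_temp: float = 28.0  # deg C annual mean at the equator
    lat_lapse: float = 0.6  # deg C lost per degree of |latitude|
    seasonal_amp: float = 8.0  # deg C amplitude of the annual cycle
    diurnal_range: float = 10.0  # tmax - tmin, deg C
    pluvial_center_lat: float = 15.0
    pluvial_width: float = 10.0  # degrees latitude (Gaussian sd)
    pluvial_peak_precip: float = 180.0  # mm/month at belt centre
    background_precip: float = 15.0  # mm/month away from the belt
    noise_sd: float = 0.0  # deg C for temperature, mm for precipitation
    sea_level_offset: int = 0  # cells of extra coastal land

    def __post_init__(self) -> None:
        if self.pluvial_width <= 0:
            raise ValueError("pluvial_width must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.sea_level_offset < 0:
            raise ValueError("sea_level_offset must be non-negative")


@dataclass
class MonthlyClimate:
    """Twelve monthly grids per field plus a land mask on one grid."""

    grid: LatLonGrid
    tmean: np.ndarray  # (12, n_lat, n_lon), deg C
    tmin: np.ndarray
    tmax: np.ndarray
    prec: np.ndarray  # (12, n_lat, n_lon), mm/month
    land_mask: np.ndarray  # (n_lat, n_lon) bool
    slice_label: str = "present"

    def __post_init__(self) -> None:
        shape = (12,) + self.grid.shape
        for name in ("tmean", "tmin", "tmax", "prec"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
        if self.land_mask.shape != self.grid.shape:
            raise ValueError("land_mask shape does not match grid")
        if np.any(self.tmin > self.tmean + 1e-9) or np.any(self.tmean > self.tmax + 1e-9):
            raise ValueError("tmin <= tmean <= tmax violated")
        if np.any(self.prec < 0):
            raise ValueError("precipitation must be non-negative")


@dataclass(frozen=True)
class OccurrenceRecord:
    lon: float
    lat: float
    source: str
    error_km: float

    def __post_init__(self) -> None:
        if self.error_km < 0:
            raise ValueError("error_km must be non-negative")


@dataclass
class OccurrenceSet:
    """Ordered collection of occurrence records."""

    records: list[OccurrenceRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def lons(self) -> np.ndarray:
        return np.array([r.lon for r in self.records], dtype=float)

    def lats(self) -> np.ndarray:
        return np.array([r.lat for r in self.records], dtype=float)

    def errors_km(self) -> np.ndarray:
        return np.array([r.error_km for r in self.records], dtype=float)


def _seasonal_cycle(lat_grid: np.ndarray, spec: ScenarioSpec) -> np.ndarray:
    """Zero-annual-mean monthly temperature cycle, anti-phased between
    hemispheres and vanishing at the equator."""
    months = np.arange(12)
    phase = np.cos(2.0 * np.pi * months / 12.0)  # sums to 0 over the year
    hemi = np.sin(np.deg2rad(lat_grid))
    return spec.seasonal_amp * phase[:, None, None] * hemi[None, :, :]


def generate_climate(
    spec: ScenarioSpec,
    grid: LatLonGrid,
    seed: int,
    land_mask: np.ndarray | None = None,
    slice_label: str = "present",
) -> MonthlyClimate:
    """Generate a monthly climate with lapse-rate temperature and a
    Gaussian pluvial precipitation belt.

    With ``noise_sd == 0`` the annual-mean temperature at the equator is
    exactly ``spec.base_temp`` and the precipitation field is an exact
    function of latitude.
    """
    lat = grid.lat_grid()
    if land_mask is None:
        land_mask = np.ones(grid.shape, dtype=bool)

    rng = np.random.default_rng(seed)
    tmean = (
        spec.base_temp
        - spec.lat_lapse * np.abs(lat)[None, :, :]
        + _seasonal_cycle(lat, spec)
    )
    belt = spec.pluvial_peak_precip * np.exp(
        -0.5 * ((lat - spec.pluvial_center_lat) / spec.pluvial_width) ** 2
    )
    prec = np.broadcast_to(
        (spec.background_precip + belt)[None, :, :], (12,) + grid.shape
    ).astype(float).copy()

    if spec.noise_sd > 0:
        tmean = tmean + rng.normal(0.0, spec.noise_sd, size=tmean.shape)
        prec = np.maximum(prec + rng.normal(0.0, spec.noise_sd, size=prec.shape), 0.0)

    half = 0.5 * spec.diurnal_range
    return MonthlyClimate(
        grid=grid,
        tmean=tmean,
        tmin=tmean - half,
        tmax=tmean + half,
        prec=prec,
        land_mask=np.asarray(land_mask, dtype=bool),
        slice_label=slice_label,
    )


def generate_masks(
    grid: LatLonGrid, sea_level_offset: int, seed: int
) -> dict[str, np.ndarray]:
    """Land masks per time slice.

    A smooth random field is thresholded into a present-day land mask
    (shared with the mid-Holocene slice); the glacial mask is a coastal
    dilation of the present mask by ``sea_level_offset`` cells, so the
    glacial land area is a superset of (and with positive offset larger
    than) the present-day one.
    """
    if sea_level_offset < 0:
        raise ValueError("sea_level_offset must be non-negative")
    rng = np.random.default_rng(seed)
    n_lat, n_lon = grid.shape
    sigma = max(2.0, min(n_lat, n_lon) / 12.0)
    fld = ndimage.gaussian_filter(rng.standard_normal(grid.shape), sigma=sigma)
    present = fld > np.quantile(fld, 0.40)
    if sea_level_offset > 0:
        lgm = ndimage.binary_dilation(present, iterations=sea_level_offset)
    else:
        lgm = present.copy()
    return {"present": present, "mid-holocene": present.copy(), "lgm": lgm}


def _parse_perturb_sd(perturb_sd) -> tuple[float, float]:
    if isinstance(perturb_sd, Mapping):
        return float(perturb_sd.get("temp", 0.0)), float(perturb_sd.get("prec", 0.0))
    v = float(perturb_sd)
    return v, v


def generate_gcm_ensemble(
    base: MonthlyClimate,
    n_models: int,
    perturb_sd,
    seed: int,
) -> list[MonthlyClimate]:
    """Pseudo-GCM ensemble: each member is the base climate plus a
    smooth (spatially correlated) random perturbation.

    ``perturb_sd`` is either a scalar (deg C for temperature, mm for
    precipitation) or a mapping ``{"temp": sd_c, "prec": sd_mm}``. The
    same temperature offset is applied to tmean/tmin/tmax so the
    cellwise ordering is preserved. Member order is deterministic for a
    given seed.
    """
    if n_models < 1:
        raise ValueError(f"n_models must be >= 1, got {n_models}")
    temp_sd, prec_sd = _parse_perturb_sd(perturb_sd)
    rng = np.random.default_rng(seed)
    n_lat, n_lon = base.grid.shape
    sigma = max(1.0, min(n_lat, n_lon) / 10.0)
    members: list[MonthlyClimate] = []
    for _ in range(n_models):
        if temp_sd > 0:
            raw = ndimage.gaussian_filter(
                rng.standard_normal((12, n_lat, n_lon)), sigma=(0, sigma, sigma)
            )
            # renormalise to the requested cellwise sd after smoothing
            dt = raw * (temp_sd / max(raw.std(), 1e-12))
        else:
            dt = np.zeros((12, n_lat, n_lon))
        if prec_sd > 0:
            raw = ndimage.gaussian_filter(
                rng.standard_normal((12, n_lat, n_lon)), sigma=(0, sigma, sigma)
            )
            dp = raw * (prec_sd / max(raw.std(), 1e-12))
        else:
            dp = np.zeros((12, n_lat, n_lon))
        members.append(
            MonthlyClimate(
                grid=base.grid,
                tmean=base.tmean + dt,
                tmin=base.tmin + dt,
                tmax=base.tmax + dt,
                prec=np.maximum(base.prec + dp, 0.0),
                land_mask=base.land_mask.copy(),
                slice_label=base.slice_label,
            )
        )
    return members


def generate_occurrences(
    suitability,
    n: int,
    jitter_km: float,
    seed: int,
    source: str = "synthetic",
    grid: LatLonGrid | None = None,
) -> OccurrenceSet:
    """Sample occurrence points cell-wise with probability proportional
    to suitability, then jitter each point within ``jitter_km``.

    ``suitability`` is either an object with ``.values`` and ``.grid``
    attributes (a suitability map) or a plain 2-D array combined with
    the ``grid`` argument. NaN cells have zero sampling probability.
    Jitter is isotropic in km, converted to degrees at each point's
    latitude; the ``error_km`` field of every record is set to
    ``jitter_km``.
    """
    if hasattr(suitability, "values") and hasattr(suitability, "grid"):
        values = np.asarray(suitability.values, dtype=float)
        grid = suitability.grid
    else:
        values = np.asarray(suitability, dtype=float)
        if grid is None:
            raise ValueError("grid is required when suitability is a bare array")
    if n < 0:
        raise ValueError("n must be non-negative")
    if n == 0:
        return OccurrenceSet([])
    p = np.where(np.isfinite(values), values, 0.0).ravel()
    if np.any(p < 0):
        raise ValueError("suitability must be non-negative")
    total = p.sum()
    if total <= 0:
        raise ValueError("cannot sample occurrences from an all-zero suitability")
    p = p / total

    rng = np.random.default_rng(seed)
    flat = rng.choice(p.size, size=n, replace=True, p=p)
    rows, cols = np.unravel_index(flat, grid.shape)
    lats = grid.lat_centers()[rows]
    lons = grid.lon_centers()[cols]

    if jitter_km > 0:
        theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
        radius = jitter_km * np.sqrt(rng.uniform(0.0, 1.0, size=n))
        dlat = radius * np.sin(theta) / KM_PER_DEGREE
        coslat = np.cos(np.deg2rad(np.clip(lats, -89.0, 89.0)))
        dlon = radius * np.cos(theta) / (KM_PER_DEGREE * coslat)
        lats = np.clip(lats + dlat, grid.lat_min, grid.lat_max)
        lons = np.clip(lons + dlon, grid.lon_min, grid.lon_max)

    records = [
        OccurrenceRecord(lon=float(lo), lat=float(la), source=source, error_km=float(jitter_km))
        for lo, la in zip(lons, lats)
    ]
    return OccurrenceSet(records)


def filter_occurrences(occ: OccurrenceSet, max_error_km: float) -> OccurrenceSet:
    """Keep records whose positional error is at most ``max_error_km``
    (inclusive), preserving order."""
    if max_error_km < 0:
        raise ValueError("max_error_km must be non-negative")
    kept = [r for r in occ.records if r.error_km <= max_error_km]
    dropped = len(occ.records) - len(kept)
    if dropped:
        logger.info("filter_occurrences: dropped %d of %d records", dropped, len(occ))
    return OccurrenceSet(kept)


def generate_range_mask(
    suitability,
    grid: LatLonGrid | None = None,
    quantile: float = 0.8,
) -> np.ndarray:
    """Synthetic 'realized range' mask: the top ``1 - quantile`` share of
    suitable cells (stand-in for an observed extant-range raster)."""
    if hasattr(suitability, "values") and hasattr(suitability, "grid"):
        values = np.asarray(suitability.values, dtype=float)
    else:
        values = np.asarray(suitability, dtype=float)
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        raise ValueError("suitability has no finite cells")
    thr = np.quantile(finite, quantile)
    return np.isfinite(values) & (values >= thr)


def generate_landcover(
    climate: MonthlyClimate, n_classes: int = 5, seed: int = 0
) -> np.ndarray:
    """Integer land-cover raster driven by annual precipitation quantiles
    (plus a dash of noise), for cross-tabulation tests. 0 = nodata."""
    rng = np.random.default_rng(seed)
    annual = climate.prec.sum(axis=0)
    noisy = annual + rng.normal(0.0, max(annual.std(), 1.0) * 0.05, size=annual.shape)
    land = climate.land_mask
    out = np.zeros(climate.grid.shape, dtype=np.int32)
    if land.sum() == 0:
        return out
    qs = np.quantile(noisy[land], np.linspace(0, 1, n_classes + 1)[1:-1])
    out[land] = np.digitize(noisy[land], qs) + 1
    return out
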