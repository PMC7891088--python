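"""Environmental stratification: PCA + k-means strata, aggregated zones.

Fits on a present-day bioclimatic stack and classifies any other stack
(paleoclimate projections, perturbed ensemble members) into the same
strata by nearest centroid in standardized principal-component space.
Strata are relabelled after fitting so that ids are ordered by (zone,
descending warmth), which makes labels reproducible for a fixed seed.
Zone 1 is the warmest zone by centroid growing degree-days.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.decomposition import PCA

from .bioclim import VARIABLE_NAMES, BioclimStack
from .grids import LatLonGrid

#: Stratum/zone id used for cells off the land mask.
NODATA_ID = 0


class NotFittedError(RuntimeError):
    pass


@dataclass
class StratificationModel:
    means: np.ndarray  # (4,) per-variable standardisation mean
    sds: np.ndarray  # (4,)
    pca_components: np.ndarray  # (n_pc, 4) loadings (rows are components)
    explained_fractions: np.ndarray  # (n_pc,), sums to 1
    centroids_pc: np.ndarray  # (S, n_pc) in standardized PC space
    strata_to_zone: np.ndarray  # (S,) zone id in 1..Z for stratum id i+1
    n_strata: int = 0
    n_zones: int = 0
    fitted: bool = False
    training_labels: np.ndarray | None = field(default=None, repr=False)

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Raw 4-variable matrix -> standardized PC coordinates."""
        z = (X - self.means) / self.sds
        return z @ self.pca_components.T

    def centroids_original_units(self) -> np.ndarray:
        """Centroids back-projected to the raw variable scale, (S, 4)."""
        z = self.centroids_pc @ self.pca_components
        return z * self.sds + self.means

    def assign(self, X: np.ndarray) -> np.ndarray:
        """Nearest-centroid stratum ids (1..S) for a raw feature matrix.

        Ties go to the lowest stratum id (argmin picks the first
        minimum).
        """
        if not self.fitted:
            raise NotFittedError("stratification model is not fitted")
        pcs = self.transform(X)
        d = cdist(pcs, self.centroids_pc)
        return np.argmin(d, axis=1) + 1

    def zones_of(self, strata_ids: np.ndarray) -> np.ndarray:
        out = np.full(strata_ids.shape, NODATA_ID, dtype=np.int32)
        valid = strata_ids >= 1
        out[valid] = self.strata_to_zone[strata_ids[valid] - 1]
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "variables": list(VARIABLE_NAMES),
                "means": self.means.tolist(),
                "sds": self.sds.tolist(),
                "pca_components": self.pca_components.tolist(),
                "explained_fractions": self.explained_fractions.tolist(),
                "centroids_pc": self.centroids_pc.tolist(),
                "strata_to_zone": self.strata_to_zone.tolist(),
                "n_strata": self.n_strata,
                "n_zones": self.n_zones,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "StratificationModel":
        d = json.loads(text)
        return cls(
            means=np.asarray(d["means"], dtype=float),
            sds=np.asarray(d["sds"], dtype=float),
            pca_components=np.asarray(d["pca_components"], dtype=float),
            explained_fractions=np.asarray(d["explained_fractions"], dtype=float),
            centroids_pc=np.asarray(d["centroids_pc"], dtype=float),
            strata_to_zone=np.asarray(d["strata_to_zone"], dtype=np.int32),
            n_strata=int(d["n_strata"]),
            n_zones=int(d["n_zones"]),
            fitted=True,
        )


@dataclass
class StrataMap:
    """Per-cell stratum and zone ids; NODATA_ID (0) off the land mask."""

    grid: LatLonGrid
    strata: np.ndarray  # (n_lat, n_lon) int
    zones: np.ndarray  # (n_lat, n_lon) int

    @property
    def land_mask(self) -> np.ndarray:
        return self.strata != NODATA_ID


def fit_stratification(
    stack: BioclimStack,
    n_strata: int = 125,
    n_zones: int = 18,
    seed: int = 0,
    n_init: int = 10,
) -> StratificationModel:
    """Standardise, run PCA (all components retained), k-means the PC
    scores into ``n_strata`` strata, and agglomerate the stratum
    centroids into ``n_zones`` warmth-ordered zones."""
    if n_zones < 1 or n_strata < n_zones:
        raise ValueError("need n_strata >= n_zones >= 1")
    X = stack.feature_matrix()
    if X.shape[0] < n_strata:
        raise ValueError(
            f"{X.shape[0]} land cells cannot support {n_strata} strata"
        )
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    sds = np.where(sds > 0, sds, 1.0)
    z = (X - means) / sds

    pca = PCA(n_components=z.shape[1], svd_solver="full")
    pcs = pca.fit_transform(z)

    km = KMeans(n_clusters=n_strata, n_init=n_init, random_state=seed)
    raw_labels = km.fit_predict(pcs)
    centroids = km.cluster_centers_

    # zones: group stratum centroids, then order zones warmest-first
    if n_strata == 1:
        zone_of_raw = np.zeros(1, dtype=int)
    elif n_zones == 1:
        zone_of_raw = np.zeros(n_strata, dtype=int)
    else:
        agg = AgglomerativeClustering(n_clusters=n_zones, linkage="ward")
        zone_of_raw = agg.fit_predict(centroids)

    gdd_idx = VARIABLE_NAMES.index("gdd0")
    centroids_raw_units = (centroids @ pca.components_) * sds + means
    centroid_gdd = centroids_raw_units[:, gdd_idx]
    zone_warmth = np.array(
        [centroid_gdd[zone_of_raw == g].mean() for g in range(n_zones)]
    )
    zone_rank = {g: r + 1 for r, g in enumerate(np.argsort(-zone_warmth))}
    zone_id_of_raw = np.array([zone_rank[g] for g in zone_of_raw])

    # relabel strata by (zone id, descending centroid warmth) for
    # deterministic, interpretable ids
    order = np.lexsort((-centroid_gdd, zone_id_of_raw))
    new_id_of_raw = np.empty(n_strata, dtype=int)
    new_id_of_raw[order] = np.arange(1, n_strata + 1)

    model = StratificationModel(
        means=means,
        sds=sds,
        pca_components=pca.components_,
        explained_fractions=pca.explained_variance_ratio_,
        centroids_pc=centroids[order],
        strata_to_zone=zone_id_of_raw[order].astype(np.int32),
        n_strata=n_strata,
        n_zones=n_zones,
        fitted=True,
    )
    model.training_labels = new_id_of_raw[raw_labels]
    return model


def classify_grid(model: StratificationModel, stack: BioclimStack) -> StrataMap:
    """Label every land cell of ``stack`` with its nearest-centroid
    stratum and the stratum's zone; off-mask cells get NODATA_ID."""
    if not model.fitted:
        raise NotFittedError("stratification model is not fitted")
    strata = np.full(stack.grid.shape, NODATA_ID, dtype=np.int32)
    mask = stack.land_mask
    if mask.any():
        strata[mask] = model.assign(stack.feature_matrix())
    return StrataMap(grid=stack.grid, strata=strata, zones=model.zones_of(strata))


def explained_variance(model: StratificationModel) -> np.ndarray:
    """Per-component explained-variance fractions (non-increasing, sum 1)."""
    if not model.fitted:
        raise NotFittedError("stratification model is not fitted")
    return model.explained_fractions.copy()
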