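"""Spatial weight matrices over city centroids.

Cities are points (lon/lat), so the default neighborhood scheme is
k-nearest-neighbor under great-circle distance; a fixed distance band and
polygon contiguity are also available.  Weights are held dense (the study
scale is a few hundred units) with GAL-format round-tripping for
interoperability with other spatial-analysis software.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpatialWeights",
    "build_weights",
    "great_circle_km",
]

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088


def great_circle_km(coords_a: np.ndarray, coords_b: np.ndarray | None = None) -> np.ndarray:
    """Pairwise great-circle distances (haversine), in km.

    Parameters
    ----------
    coords_a : array (n, 2) of (lon, lat) in degrees.
    coords_b : array (m, 2) or None (self-distances).
    """
    a = np.radians(np.asarray(coords_a, dtype=float))
    b = a if coords_b is None else np.radians(np.asarray(coords_b, dtype=float))
    lon1, lat1 = a[:, 0][:, None], a[:, 1][:, None]
    lon2, lat2 = b[:, 0][None, :], b[:, 1][None, :]
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


@dataclass
class SpatialWeights:
    """Pairwise spatial weights w_ij over an ordered set of units.

    Invariants: all weights nonnegative and finite; the diagonal is zero
    unless `includes_self`; if `row_standardized`, every non-isolated row
    sums to 1 (to within 1e-12).
    """

    ids: list
    matrix: np.ndarray
    row_standardized: bool = False
    includes_self: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError(f"weights matrix shape {self.matrix.shape} != ({n}, {n})")
        if not np.all(np.isfinite(self.matrix)) or np.any(self.matrix < 0):
            raise ValueError("weights must be finite and nonnegative")
        if not self.includes_self and np.any(np.diag(self.matrix) != 0):
            raise ValueError("diagonal weights present but includes_self is False")
        if self.row_standardized:
            sums = self.matrix.sum(axis=1)
            bad = (sums > 0) & (np.abs(sums - 1.0) > 1e-12)
            if np.any(bad):
                raise ValueError("row_standardized flag set but rows do not sum to 1")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def isolates(self) -> list:
        """Units with no neighbors (zero row off the diagonal)."""
        off = self.matrix.copy()
        np.fill_diagonal(off, 0.0)
        return [self.ids[i] for i in np.flatnonzero(off.sum(axis=1) == 0)]

    def neighbors(self, unit) -> dict:
        i = self.ids.index(unit)
        row = self.matrix[i]
        return {self.ids[j]: row[j] for j in np.flatnonzero(row) if j != i or self.includes_self}

    def standardized(self) -> "SpatialWeights":
        """Return a row-standardized copy (isolate rows stay zero)."""
        sums = self.matrix.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            m = np.where(sums > 0, self.matrix / sums, 0.0)
        return SpatialWeights(self.ids, m, row_standardized=True,
                              includes_self=self.includes_self, meta=dict(self.meta))

    def with_self(self, weight: float = 1.0) -> "SpatialWeights":
        """Return a copy with self-weights set (for Gi*-style statistics)."""
        m = self.matrix.copy()
        np.fill_diagonal(m, weight)
        return SpatialWeights(self.ids, m, row_standardized=False,
                              includes_self=True, meta=dict(self.meta))

    # --- GAL interchange -------------------------------------------------
    def to_gal(self, path) -> None:
        """Write binary adjacency in GAL format (weights are dropped: GAL
        carries topology only, as in other spatial packages)."""
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for i, uid in enumerate(self.ids):
                nbrs = [self.ids[j] for j in np.flatnonzero(self.matrix[i]) if j != i]
                fh.write(f"{uid} {len(nbrs)}\n")
                fh.write(" ".join(str(x) for x in nbrs) + "\n")

    @classmethod
    def from_gal(cls, path) -> "SpatialWeights":
        with open(path) as fh:
            tokens = fh.read().split("\n")
        header = tokens[0].split()
        n = int(header[-1]) if len(header) > 1 else int(header[0])
        ids, adj = [], {}
        line = 1
        for _ in range(n):
            uid, deg = tokens[line].split()
            nbrs = tokens[line + 1].split() if int(deg) > 0 else []
            if int(deg) > 0:
                line += 2
            else:
                # tolerate both "id 0" followed by empty line or not
                line += 2 if tokens[line + 1].strip() == "" else 1
            ids.append(uid)
            adj[uid] = nbrs
        index = {u: i for i, u in enumerate(ids)}
        m = np.zeros((n, n))
        for u, nbrs in adj.items():
            for v in nbrs:
                m[index[u], index[v]] = 1.0
        return cls(ids, m)


def _knn_matrix(dist: np.ndarray, k: int) -> np.ndarray:
    n = dist.shape[0]
    m = np.zeros((n, n))
    for i in range(n):
        order = np.lexsort((np.arange(n), dist[i]))  # distance, then unit order
        nbrs = [j for j in order if j != i][:k]
        m[i, nbrs] = 1.0
    return m


def build_weights(
    coords,
    scheme: str = "knn",
    k: int = 5,
    threshold: float | None = None,
    row_standardize: bool = True,
    symmetric: bool = False,
    ids=None,
    polygons=None,
) -> SpatialWeights:
    """Build a spatial weights object from point coordinates.

    Parameters
    ----------
    coords : (n, 2) array of (lon, lat) degrees.
    scheme : 'knn' (default), 'distance_band', or 'contiguity_from_polygons'.
    k : neighbor count for knn; must satisfy k < n.
    threshold : band radius in km for 'distance_band'.
    symmetric : for knn, force w_ij = max(w_ij, w_ji) before standardization.
    polygons : shapely geometries, required for contiguity.

    Duplicate coordinates are legal; exact-tie neighbor choices fall back to
    unit-id order and are logged.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n < 2:
        raise ValueError("at least 2 units are required to build weights")
    if ids is None:
        ids = list(range(n))
    if len(ids) != n:
        raise ValueError("ids length does not match coords")

    if scheme == "knn":
        if k >= n:
            raise ValueError(f"k={k} must be smaller than the number of units n={n}")
        dist = great_circle_km(coords)
        uniq = {tuple(c) for c in coords.round(12).tolist()}
        if len(uniq) < n:
            logger.warning("duplicate coordinates detected; knn ties broken by unit order")
        m = _knn_matrix(dist, k)
        if symmetric:
            m = np.maximum(m, m.T)
    elif scheme == "distance_band":
        if threshold is None or threshold <= 0:
            raise ValueError("distance_band requires a positive threshold (km)")
        dist = great_circle_km(coords)
        m = ((dist > 0) & (dist <= threshold)).astype(float)
        np.fill_diagonal(m, 0.0)
    elif scheme == "contiguity_from_polygons":
        if polygons is None:
            raise ValueError("contiguity scheme requires polygons")
        m = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                if polygons[i].intersects(polygons[j]):
                    m[i, j] = m[j, i] = 1.0
    else:
        raise ValueError(f"unknown weights scheme: {scheme!r}")

    w = SpatialWeights(list(ids), m, meta={"scheme": scheme, "k": k, "threshold": threshold})
    if w.isolates:
        logger.warning("weights have %d isolate(s): %s", len(w.isolates), w.isolates[:10])
    return w.standardized() if row_standardize else w
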