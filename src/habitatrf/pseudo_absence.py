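"""Pseudo-absence generation by environmental dissimilarity.

With presence-only records, "absences" must be manufactured. The
approach here clusters the harmonized predictor stack with k-means on
z-scored cell vectors, identifies the clusters that contain presence
records (the species' coarse environmental envelope), and draws random
points uniformly from cells of the remaining — environmentally
dissimilar — clusters. An alternative policy based on a direct
environmental-distance threshold to the nearest presence is provided,
since "dissimilar pixels" admits either reading.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .points import PSEUDO_ABSENCE, OccurrenceSet
from .raster import EnvironmentalStack, RasterGrid

__all__ = [
    "ClusterMap",
    "cluster_environment",
    "presence_clusters",
    "sample_pseudo_absences",
    "dissimilar_cells_by_distance",
]


def _standardized_matrix(stack: EnvironmentalStack) -> tuple[np.ndarray, np.ndarray]:
    """Z-score each layer over valid cells; zero-variance layers -> 0.

    Standardization keeps Euclidean k-means from being dominated by
    large-range layers (precipitation in mm vs fractional covers).
    """
    X, idx = stack.to_matrix()
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd, idx


@dataclass
class ClusterMap:
    """K-means partition of the landscape in standardized predictor space."""

    labels: RasterGrid  # integer cluster id per cell; nodata where unlabelled
    k: int
    centroids: np.ndarray  # (k, n_layers) in standardized space
    inertia: float

    def __post_init__(self) -> None:
        if self.centroids.shape[0] != self.k:
            raise ValueError("centroid count must equal k")
        lab = self.labels.valid_values
        if lab.size and (lab.min() < 0 or lab.max() >= self.k):
            raise ValueError("cluster labels must lie in [0, k)")

    def label_at(self, occ: OccurrenceSet) -> np.ndarray:
        """Cluster id under each point; error if any point is unlabelled."""
        vals = self.labels.sample(occ.lon, occ.lat)
        bad = vals == self.labels.nodata
        if np.any(bad):
            pts = list(zip(occ.lon[bad][:5], occ.lat[bad][:5]))
            raise ValueError(
                f"{int(bad.sum())} point(s) fall on unlabelled (nodata) cells, e.g. {pts}"
            )
        return vals.astype(int)


def cluster_environment(stack: EnvironmentalStack, k: int, seed: int) -> ClusterMap:
    """Partition valid cells into ``k`` environmental clusters.

    Layers are z-scored, then k-means (Euclidean) runs on the cell
    vectors. Deterministic for a given seed. Nodata cells stay
    unlabelled.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    geom = stack.require_harmonized()
    X, idx = _standardized_matrix(stack)
    if X.shape[0] < k:
        raise ValueError(f"k={k} exceeds the {X.shape[0]} valid cells")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(X)
    grid = np.full(geom.nrows * geom.ncols, -1.0)
    grid[idx] = labels
    label_grid = RasterGrid(grid.reshape(geom.shape), geom, nodata=-1.0, name="clusters")
    return ClusterMap(labels=label_grid, k=k, centroids=km.cluster_centers_, inertia=float(km.inertia_))


def presence_clusters(cmap: ClusterMap, presences: OccurrenceSet) -> set[int]:
    """Ids of clusters containing at least one presence point."""
    if len(presences) == 0:
        return set()
    return set(int(c) for c in cmap.label_at(presences))


def sample_pseudo_absences(
    cmap: ClusterMap,
    excluded: set[int],
    n: int,
    seed: int,
    presence_cells: set[tuple[int, int]] | None = None,
) -> OccurrenceSet:
    """Draw ``n`` distinct pseudo-absence cells uniformly at random.

    Eligible cells are labelled, not in an excluded cluster and not
    occupied by a presence point (``presence_cells`` as (row, col)
    pairs). Points are placed at cell centres.
    """
    geom = cmap.labels.geometry
    lab = cmap.labels.values.ravel()
    eligible = cmap.labels.valid_mask.ravel().copy()
    for c in excluded:
        eligible &= lab != c
    if presence_cells:
        rows, cols = zip(*presence_cells)
        flat = np.asarray(rows) * geom.ncols + np.asarray(cols)
        eligible[flat] = False
    idx = np.flatnonzero(eligible)
    if idx.size < n:
        raise ValueError(
            f"only {idx.size} eligible cells for {n} pseudo-absences "
            f"(short by {n - idx.size})"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(idx, size=n, replace=False)
    row, col = np.divmod(chosen, geom.ncols)
    x, y = geom.cell_center(row, col)
    return OccurrenceSet.from_arrays(x, y, PSEUDO_ABSENCE)


def dissimilar_cells_by_distance(
    stack: EnvironmentalStack, presences: OccurrenceSet, quantile: float = 0.75
) -> np.ndarray:
    """Alternative dissimilarity policy: distance threshold in predictor space.

    Marks cells whose standardized Euclidean distance to the *nearest*
    presence exceeds the given quantile of that distance over all valid
    cells. Returns a boolean mask (grid shape) of dissimilar cells.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    geom = stack.require_harmonized()
    X, idx = _standardized_matrix(stack)
    row, col = geom.cell_index(presences.lon, presences.lat)
    flat = row * geom.ncols + col
    pos = np.searchsorted(idx, flat)
    if np.any((pos >= idx.size) | (idx[np.minimum(pos, idx.size - 1)] != flat)):
        raise ValueError("presence point(s) fall on nodata cells")
    P = X[pos]
    # nearest-presence distance per cell; chunked to bound memory
    dmin = np.full(X.shape[0], np.inf)
    step = 100_000 // max(len(P), 1) + 1
    for i in range(0, X.shape[0], step):
        d = np.linalg.norm(X[i : i + step, None, :] - P[None, :, :], axis=2)
        dmin[i : i + step] = d.min(axis=1)
    thr = np.quantile(dmin, quantile)
    mask = np.zeros(geom.nrows * geom.ncols, dtype=bool)
    mask[idx[dmin > thr]] = True
    return mask.reshape(geom.shape)
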