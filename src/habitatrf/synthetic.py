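"""Synthetic multi-resolution landscapes with known ground truth.

The generator emulates the statistical structure the habitat-suitability
analysis assumes, without any downloads: spatially smooth environmental
fields on three native grids (coarse climate-, medium vegetation- and
fine terrain-resolution analogues), a known logistic true-suitability
surface over the harmonized stack, and presence points sampled from it.
Because the truth is known, downstream stages (clustering, tuning,
importance ranking, mapping) can be tested for parameter recovery.

Fields are smoothed Gaussian noise rescaled exactly to a configured
range; only the range and a smoothness length-scale are emulated, not
the covariance structure of real climate or satellite products.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .points import PRESENCE, OccurrenceSet
from .raster import DEFAULT_NODATA, EnvironmentalStack, GridGeometry, RasterGrid
from . import raster_ops

__all__ = [
    "LayerSpec",
    "LandscapeConfig",
    "default_layer_specs",
    "generate_environment",
    "true_suitability",
    "sample_presences",
]


@dataclass(frozen=True)
class LayerSpec:
    """Value range, native grid group and smoothness of one synthetic layer."""

    group: str  # key into LandscapeConfig.resolutions
    vmin: float
    vmax: float
    length_scale: float = 0.1  # smoothness length-scale, map units

    def __post_init__(self) -> None:
        if self.vmax < self.vmin:
            raise ValueError(f"vmax {self.vmax} < vmin {self.vmin}")
        if self.length_scale < 0:
            raise ValueError("length_scale must be >= 0")


# Ranges for the default 26-predictor set: 19 bioclim analogues, three
# vegetation fractions, elevation and its three terrain derivatives.
# Ranges follow the study-area summary ([min, max] per layer); bio14 is
# constant and percent_nonvegetated saturates high, so the default set
# exercises the degenerate cases the model stage must tolerate.
_BIOCLIM_RANGES: dict[str, tuple[float, float]] = {
    "bio01": (9.4, 27.0),
    "bio02": (7.3, 18.1),
    "bio03": (36.0, 53.0),
    "bio04": (37.13, 67.65),
    "bio05": (23.4, 42.4),
    "bio06": (-4.7, 15.7),
    "bio07": (19.5, 35.5),
    "bio08": (2.4, 32.6),
    "bio09": (12.0, 31.4),
    "bio10": (16.4, 34.2),
    "bio11": (1.5, 21.6),
    "bio12": (1.0, 227.0),
    "bio13": (1.0, 55.0),
    "bio14": (1.0, 1.0),
    "bio15": (28.0, 205.0),
    "bio16": (1.0, 145.0),
    "bio17": (1.0, 10.0),
    "bio18": (1.0, 26.0),
    "bio19": (1.0, 141.0),
}
_VEGETATION_RANGES: dict[str, tuple[float, float]] = {
    "percent_tree_cover": (1.0, 38.0),
    "percent_nontree_vegetation": (1.0, 87.0),
    "percent_nonvegetated": (4.0, 100.0),
}


def default_layer_specs() -> dict[str, LayerSpec]:
    specs = {
        name: LayerSpec("climate", lo, hi) for name, (lo, hi) in _BIOCLIM_RANGES.items()
    }
    specs.update(
        {
            name: LayerSpec("vegetation", lo, hi, length_scale=0.05)
            for name, (lo, hi) in _VEGETATION_RANGES.items()
        }
    )
    specs["elevation"] = LayerSpec("terrain", 1.0, 2467.0, length_scale=0.05)
    return specs


@dataclass
class LandscapeConfig:
    """Everything needed to synthesize one landscape deterministically.

    ``resolutions`` maps a layer group to its native cell size; the
    defaults keep the coarse : medium : fine ratio of the real climate /
    vegetation / terrain products (1 : 4 : 8 here) at a size a laptop
    resolves in seconds. ``suitability_coefficients`` weight the named
    layers (after per-layer standardization) in the logistic linear
    predictor of the true suitability surface.
    """

    extent: tuple[float, float, float, float] = (30.0, 26.0, 31.0, 27.0)
    resolutions: dict[str, float] = field(
        default_factory=lambda: {"climate": 0.02, "vegetation": 0.005, "terrain": 0.0025}
    )
    layer_specs: dict[str, LayerSpec] = field(default_factory=default_layer_specs)
    suitability_coefficients: dict[str, float] = field(
        default_factory=lambda: {"bio01": 1.0, "bio12": 1.0, "percent_nontree_vegetation": 1.0}
    )
    intercept: float = -1.0
    n_presence: int = 56
    seed: int = 0
    derive_terrain: bool = True  # add slope/aspect/hillshade computed from elevation

    def validate(self) -> None:
        xmin, ymin, xmax, ymax = self.extent
        if xmax <= xmin or ymax <= ymin:
            raise ValueError("degenerate extent")
        for group, cell in self.resolutions.items():
            if cell <= 0:
                raise ValueError(f"cell size for group {group!r} must be positive")
        for name, spec in self.layer_specs.items():
            if spec.group not in self.resolutions:
                raise ValueError(f"layer {name!r} references unknown group {spec.group!r}")
        known = set(self.layer_specs)
        if self.derive_terrain and "elevation" in known:
            known |= {"slope", "aspect", "hillshade"}
        missing = set(self.suitability_coefficients) - known
        if missing:
            raise ValueError(
                f"suitability_coefficients reference unknown layer(s): {sorted(missing)}"
            )
        if self.n_presence < 1:
            raise ValueError("n_presence must be >= 1")


def _layer_rng(seed: int, name: str) -> np.random.Generator:
    # stable per-layer stream: master seed + CRC32 of the layer name
    return np.random.default_rng([seed, zlib.crc32(name.encode())])


def _smooth_field(
    geom: GridGeometry, spec: LayerSpec, rng: np.random.Generator
) -> np.ndarray:
    noise = rng.standard_normal(geom.shape)
    sigma_cells = spec.length_scale / geom.dx
    f = gaussian_filter(noise, sigma=sigma_cells, mode="reflect") if sigma_cells > 0 else noise
    if spec.vmax == spec.vmin:
        return np.full(geom.shape, spec.vmin)
    lo, hi = f.min(), f.max()
    if hi == lo:  # smoothing collapsed the field; centre of range
        return np.full(geom.shape, 0.5 * (spec.vmin + spec.vmax))
    return spec.vmin + (f - lo) * (spec.vmax - spec.vmin) / (hi - lo)


def generate_environment(config: LandscapeConfig) -> EnvironmentalStack:
    """Synthesize every configured layer on its group's native grid.

    Each layer is an independent smoothed-Gaussian-noise field rescaled
    exactly to its configured range, drawn from a per-layer stream of
    the master seed, so the output is bit-identical across runs of the
    same config. When ``derive_terrain`` is set and an ``elevation``
    layer exists, slope, aspect and hillshade are computed from it on
    the terrain grid and appended.
    """
    config.validate()
    xmin, ymin, xmax, ymax = config.extent
    geoms = {
        group: GridGeometry.from_extent(xmin, ymin, xmax, ymax, cell)
        for group, cell in config.resolutions.items()
    }
    stack = EnvironmentalStack()
    for name, spec in config.layer_specs.items():
        geom = geoms[spec.group]
        values = _smooth_field(geom, spec, _layer_rng(config.seed, name))
        stack.add(name, RasterGrid(values, geom, name=name))
    if config.derive_terrain and "elevation" in stack:
        dem = stack["elevation"]
        stack.add("slope", raster_ops.slope(dem))
        asp = raster_ops.aspect(dem)
        # smooth fields are never flat, but guard the nodata convention
        stack.add("aspect", asp)
        stack.add("hillshade", raster_ops.hillshade(dem))
    return stack


def true_suitability(stack: EnvironmentalStack, config: LandscapeConfig) -> RasterGrid:
    """Known ground-truth suitability: logistic in standardized layers.

    Per cell: ``expit(intercept + sum_k coeff_k * z_k)`` where ``z_k`` is
    the k-th weighted layer standardized (z-scored) over its valid
    cells. Requires a harmonized stack; a coefficient naming a missing
    layer raises with that name.
    """
    geom = stack.require_harmonized()
    eta = np.full(geom.shape, float(config.intercept))
    mask = np.ones(geom.shape, dtype=bool)
    for name, coeff in config.suitability_coefficients.items():
        if name not in stack:
            raise KeyError(f"suitability coefficient references missing layer {name!r}")
        grid = stack[name]
        mask &= grid.valid_mask
        v = grid.values
        mu = grid.valid_values.mean()
        sd = grid.valid_values.std()
        z = (v - mu) / sd if sd > 0 else np.zeros_like(v)
        eta = eta + coeff * z
    out = np.where(mask, expit(eta), DEFAULT_NODATA)
    return RasterGrid(out, geom, name="true_suitability")


def sample_presences(suitability: RasterGrid, n: int, seed: int) -> OccurrenceSet:
    """Draw ``n`` distinct presence cells with probability ∝ suitability.

    Points are placed at cell centres. Cells that are nodata are never
    sampled; asking for more points than there are valid cells is an
    error.
    """
    mask = suitability.valid_mask
    idx = np.flatnonzero(mask.ravel())
    if n > idx.size:
        raise ValueError(f"requested {n} presences but only {idx.size} valid cells")
    w = suitability.values.ravel()[idx].astype(float)
    if np.any(w < 0):
        raise ValueError("suitability values must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("suitability is zero everywhere; cannot sample presences")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(idx, size=n, replace=False, p=w / total)
    row, col = np.divmod(chosen, suitability.geometry.ncols)
    x, y = suitability.geometry.cell_center(row, col)
    return OccurrenceSet.from_arrays(x, y, PRESENCE)
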