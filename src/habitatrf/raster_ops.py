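"""Grid harmonization, terrain derivatives and layer summaries.

Predictor layers arrive on different native grids (climate-, vegetation-
and terrain-resolution analogues). Everything downstream of the model
needs one common grid, so layers are resampled — by default with
bilinear interpolation (weighted average of the four nearest source
cell centres), with block-mean aggregation available as an alternative
when coarsening.

Terrain derivatives (slope, aspect, hillshade) use Horn's 8-neighbour
stencil, the de-facto GIS standard.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .raster import EnvironmentalStack, GridGeometry, RasterGrid

#: metres per degree of latitude (spherical approximation) used to put
#: degree-based grids and metre-based elevations on common footing.
METRES_PER_DEGREE = 111_320.0

__all__ = [
    "METRES_PER_DEGREE",
    "resample_bilinear",
    "aggregate_block_mean",
    "harmonize",
    "slope",
    "aspect",
    "hillshade",
    "layer_summary",
]


def _check_overlap(src: GridGeometry, target: GridGeometry) -> None:
    sxmin, symin, sxmax, symax = src.bounds
    txmin, tymin, txmax, tymax = target.bounds
    if txmin >= sxmax or txmax <= sxmin or tymin >= symax or tymax <= symin:
        raise ValueError(
            f"source bounds {src.bounds} and target bounds {target.bounds} are disjoint"
        )


def resample_bilinear(src: RasterGrid, target: GridGeometry) -> RasterGrid:
    """Resample onto ``target`` by bilinear interpolation.

    Each target cell takes the distance-weighted average of the four
    source cell centres nearest to its own centre. Target centres beyond
    the outermost source centres are clamped to the edge of the centre
    lattice, so output values never overshoot the source range. Where
    part of the 2x2 stencil is nodata the weights are renormalized over
    the valid corners; an entirely-nodata stencil yields nodata.
    """
    g = src.geometry
    if g.nrows < 2 or g.ncols < 2:
        raise ValueError("bilinear resampling needs a source of at least 2x2 cells")
    _check_overlap(g, target)

    jj, ii = np.meshgrid(np.arange(target.ncols), np.arange(target.nrows))
    tx, ty = target.cell_center(ii.ravel(), jj.ravel())

    # fractional position in the source cell-centre lattice
    fx = np.clip((tx - (g.x0 + 0.5 * g.dx)) / g.dx, 0.0, g.ncols - 1.0)
    fy = np.clip(((g.y0 - 0.5 * g.dy) - ty) / g.dy, 0.0, g.nrows - 1.0)
    j0 = np.minimum(np.floor(fx).astype(int), g.ncols - 2)
    i0 = np.minimum(np.floor(fy).astype(int), g.nrows - 2)
    wx = fx - j0
    wy = fy - i0

    vals = src.values
    valid = src.valid_mask
    corners = [
        (vals[i0, j0], valid[i0, j0], (1 - wx) * (1 - wy)),
        (vals[i0, j0 + 1], valid[i0, j0 + 1], wx * (1 - wy)),
        (vals[i0 + 1, j0], valid[i0 + 1, j0], (1 - wx) * wy),
        (vals[i0 + 1, j0 + 1], valid[i0 + 1, j0 + 1], wx * wy),
    ]
    num = np.zeros(tx.shape)
    den = np.zeros(tx.shape)
    for v, ok, w in corners:
        w = np.where(ok, w, 0.0)
        num += w * np.where(ok, v, 0.0)
        den += w
    out = np.where(den > 0, num / np.where(den > 0, den, 1.0), src.nodata)
    return RasterGrid(out.reshape(target.shape), target, nodata=src.nodata, name=src.name)


def aggregate_block_mean(src: RasterGrid, target: GridGeometry) -> RasterGrid:
    """Coarsen by averaging all source cell centres inside each target cell.

    Alternative to point-sampling bilinear interpolation when the target
    grid is much coarser than the source; nodata source cells are
    ignored, and target cells containing no valid source centre become
    nodata.
    """
    g = src.geometry
    _check_overlap(g, target)
    jj, ii = np.meshgrid(np.arange(g.ncols), np.arange(g.nrows))
    sx, sy = g.cell_center(ii.ravel(), jj.ravel())
    inside = (
        (sx >= target.x0)
        & (sx < target.x0 + target.ncols * target.dx)
        & (sy <= target.y0)
        & (sy > target.y0 - target.nrows * target.dy)
    )
    valid = src.valid_mask.ravel() & inside
    row, col = target.cell_index(sx[valid], sy[valid])
    flat = row * target.ncols + col
    n = target.nrows * target.ncols
    sums = np.bincount(flat, weights=src.values.ravel()[valid], minlength=n)
    counts = np.bincount(flat, minlength=n)
    out = np.where(counts > 0, sums / np.maximum(counts, 1), src.nodata)
    return RasterGrid(out.reshape(target.shape), target, nodata=src.nodata, name=src.name)


def harmonize(
    stack: EnvironmentalStack,
    target: GridGeometry | None = None,
    method: str = "bilinear",
) -> EnvironmentalStack:
    """Bring every layer of a mixed-resolution stack onto one grid.

    By default the target is the grid of the coarsest layer (largest
    cell size), mirroring alignment to the lowest-resolution climate
    grid. ``method`` is ``"bilinear"`` (default) or ``"block_mean"``.
    """
    if len(stack) == 0:
        raise ValueError("cannot harmonize an empty stack")
    if target is None:
        target = max((g.geometry for _, g in stack.items()), key=lambda g: g.dx * g.dy)
    resampler = {"bilinear": resample_bilinear, "block_mean": aggregate_block_mean}
    if method not in resampler:
        raise ValueError(f"unknown resampling method {method!r}")
    out = EnvironmentalStack()
    for name, grid in stack.items():
        if grid.geometry == target:
            out.add(name, grid)
        else:
            out.add(name, resampler[method](grid, target))
    return out


# ---------------------------------------------------------------------------
# Terrain derivatives (Horn 1981 stencil)
# ---------------------------------------------------------------------------

def _horn_gradients(
    dem: RasterGrid, geographic: bool, edge_policy: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (dz/dx east, dz/dy north, valid-output mask).

    Nodata neighbours fall back to the centre value; edge cells use the
    replicated-edge stencil when ``edge_policy="replicate"`` (default),
    or are masked out when ``edge_policy="nodata"``.
    """
    if dem.geometry.nrows < 3 or dem.geometry.ncols < 3:
        raise ValueError("terrain derivatives need a DEM of at least 3x3 cells")
    if edge_policy not in ("replicate", "nodata"):
        raise ValueError(f"edge_policy must be 'replicate' or 'nodata', got {edge_policy!r}")
    g = dem.geometry
    z = np.where(dem.valid_mask, dem.values, np.nan)
    zp = np.pad(z, 1, mode="edge")

    def nb(di: int, dj: int) -> np.ndarray:
        block = zp[1 + di : 1 + di + g.nrows, 1 + dj : 1 + dj + g.ncols]
        return np.where(np.isnan(block), z, block)  # nodata neighbour -> centre value

    a, b, c = nb(-1, -1), nb(-1, 0), nb(-1, 1)
    d, f = nb(0, -1), nb(0, 1)
    gg, h, i = nb(1, -1), nb(1, 0), nb(1, 1)

    if geographic:
        yres = np.full((g.nrows, 1), g.dy * METRES_PER_DEGREE)
        lat = g.row_center_latitudes()[:, None]
        xres = g.dx * METRES_PER_DEGREE * np.cos(np.radians(lat))
    else:
        xres = np.full((g.nrows, 1), g.dx)
        yres = np.full((g.nrows, 1), g.dy)

    dzdx = ((c + 2 * f + i) - (a + 2 * d + gg)) / (8.0 * xres)
    # row index grows southward, so the "down the array" difference is -north
    dzdy = ((a + 2 * b + c) - (gg + 2 * h + i)) / (8.0 * yres)

    mask = dem.valid_mask.copy()
    if edge_policy == "nodata":
        mask[0, :] = mask[-1, :] = False
        mask[:, 0] = mask[:, -1] = False
    return dzdx, dzdy, mask


def slope(
    dem: RasterGrid, geographic: bool = True, edge_policy: str = "replicate"
) -> RasterGrid:
    """Slope in degrees [0, 90] from Horn's 8-neighbour stencil.

    ``geographic=True`` treats the grid spacing as degrees and converts
    it to metres (cos-latitude corrected in x) so the ratio against
    metre-valued elevations is dimensionless.
    """
    dzdx, dzdy, mask = _horn_gradients(dem, geographic, edge_policy)
    s = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    return dem.with_values(np.where(mask, s, dem.nodata), name="slope")


def aspect(
    dem: RasterGrid, geographic: bool = True, edge_policy: str = "replicate"
) -> RasterGrid:
    """Downslope direction in degrees [0, 360) clockwise from north.

    Flat cells (zero gradient) have no defined direction and are set to
    nodata; an exactly north-facing slope reports 0, never 360.
    """
    dzdx, dzdy, mask = _horn_gradients(dem, geographic, edge_policy)
    flat = (dzdx == 0) & (dzdy == 0)
    az = np.degrees(np.arctan2(-dzdx, -dzdy)) % 360.0
    az = np.where(az >= 360.0, 0.0, az)
    out = np.where(mask & ~flat, az, dem.nodata)
    return dem.with_values(out, name="aspect")


def hillshade(
    dem: RasterGrid,
    sun_azimuth: float = 315.0,
    sun_altitude: float = 45.0,
    geographic: bool = True,
    edge_policy: str = "replicate",
) -> RasterGrid:
    """Simulated illumination, integer [0, 255] (GIS-standard formula).

    Defaults: sun from the northwest (azimuth 315 deg) at 45 deg above the
    horizon. A flat surface under a zenith sun (altitude 90) scores 255.
    """
    dzdx, dzdy, mask = _horn_gradients(dem, geographic, edge_policy)
    zenith = np.radians(90.0 - sun_altitude)
    slope_r = np.arctan(np.hypot(dzdx, dzdy))
    aspect_r = np.arctan2(-dzdx, -dzdy)  # flat -> 0, harmless: sin(slope)=0
    az_r = np.radians(sun_azimuth)
    shade = 255.0 * (
        np.cos(zenith) * np.cos(slope_r)
        + np.sin(zenith) * np.sin(slope_r) * np.cos(az_r - aspect_r)
    )
    shade = np.round(np.clip(shade, 0.0, 255.0))
    return dem.with_values(np.where(mask, shade, dem.nodata), name="hillshade")


# ---------------------------------------------------------------------------
# Layer summaries
# ---------------------------------------------------------------------------

def layer_summary(stack: EnvironmentalStack) -> pd.DataFrame:
    """Per-layer min / Q1 / median / Q3 / max / mean over valid cells.

    Quartiles use linear interpolation between order statistics. A layer
    with no valid cell is an error (a summary of nothing is meaningless).
    """
    rows = {}
    for name, grid in stack.items():
        v = grid.valid_values
        if v.size == 0:
            raise ValueError(f"layer {name!r} has zero valid cells")
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        rows[name] = {
            "min": float(v.min()),
            "q1": float(q1),
            "median": float(med),
            "q3": float(q3),
            "max": float(v.max()),
            "mean": float(v.mean()),
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "layer"
    return df[["min", "q1", "median", "q3", "max", "mean"]]
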