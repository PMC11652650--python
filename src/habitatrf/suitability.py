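"""HSI surface post-processing: class binning and area bookkeeping in km².

The Habitat Suitability Index is binned into fixed-width classes
(default 0.1 over [0, 1]); each bin's area is totalled in km², with a
cos-latitude cell-area correction when the grid is geographic. A
configurable "suitable" range (default HSI 0.6–0.9: everything below
0.6 reads as poor habitat) is summed from the bins, and the binary
majority-vote map gets presence/absence areas and percentages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import RasterGrid

KM_PER_DEGREE = 111.32

__all__ = [
    "KM_PER_DEGREE",
    "ClassAreaTable",
    "cell_areas_km2",
    "classify_hsi",
    "binary_area",
    "suitable_area",
    "area_percentages",
]


def cell_areas_km2(grid: RasterGrid, mode: str = "geographic") -> np.ndarray:
    """Per-row cell area in km², shaped (nrows, 1).

    ``geographic``: cell sizes are degrees; area = dx·dy·(111.32 km/deg)²
    scaled by cos(latitude of the row's cell centres).
    ``planar``: cell sizes are already kilometres.
    """
    g = grid.geometry
    if mode == "geographic":
        lat = g.row_center_latitudes()[:, None]
        return g.dx * g.dy * KM_PER_DEGREE**2 * np.cos(np.radians(lat))
    if mode == "planar":
        return np.full((g.nrows, 1), g.dx * g.dy)
    raise ValueError(f"area mode must be 'geographic' or 'planar', got {mode!r}")


@dataclass
class ClassAreaTable:
    """Area per HSI bin plus the configurable suitable-range total."""

    bins: pd.DataFrame  # columns: bin_lo, bin_hi, area_km2
    total_km2: float
    suitable_range: tuple[float, float] = (0.6, 0.9)

    def __post_init__(self) -> None:
        if (self.bins["area_km2"] < 0).any():
            raise ValueError("bin areas must be >= 0")
        s = float(self.bins["area_km2"].sum())
        if self.total_km2 > 0 and abs(s - self.total_km2) > 1e-6 * self.total_km2:
            raise ValueError(f"bin areas sum to {s}, not the total {self.total_km2}")

    @property
    def suitable_km2(self) -> float:
        return suitable_area(self, *self.suitable_range)

    def to_csv(self, path) -> None:
        self.bins.to_csv(path, index=False)


def classify_hsi(
    hsi: RasterGrid,
    bin_width: float = 0.1,
    area_mode: str = "geographic",
    suitable_range: tuple[float, float] = (0.6, 0.9),
) -> ClassAreaTable:
    """Bin the HSI surface and total each bin's area in km².

    Bins are half-open ``[lo, hi)`` except the last, which closes at 1
    so an HSI of exactly 1 is counted. ``bin_width`` must divide 1
    evenly. Every valid cell lands in exactly one bin, so the bin areas
    sum to the total valid area by construction.
    """
    n_bins = 1.0 / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError(f"bin width {bin_width} does not divide [0, 1] evenly")
    n_bins = int(round(n_bins))
    mask = hsi.valid_mask
    v = hsi.values
    if ((v[mask] < 0) | (v[mask] > 1)).any():
        raise ValueError("HSI values must lie in [0, 1]")
    # a value within 1e-9 of a bin edge counts as on the edge (0.3 -> [0.3, 0.4))
    idx = np.minimum(np.floor(v / bin_width + 1e-9).astype(int), n_bins - 1)  # last bin closed
    areas = np.broadcast_to(cell_areas_km2(hsi, area_mode), v.shape)
    bin_area = np.bincount(idx[mask], weights=areas[mask], minlength=n_bins)
    edges = np.round(np.arange(n_bins + 1) * bin_width, 10)
    df = pd.DataFrame(
        {"bin_lo": edges[:-1], "bin_hi": edges[1:], "area_km2": bin_area}
    )
    return ClassAreaTable(df, total_km2=float(bin_area.sum()), suitable_range=suitable_range)


def suitable_area(table: ClassAreaTable, lo: float = 0.6, hi: float = 0.9) -> float:
    """Sum of bin areas whose interval lies inside [lo, hi).

    ``lo`` and ``hi`` must coincide with bin edges; a bound cutting
    through a bin (e.g. 0.65 on 0.1-wide bins) is an error rather than
    a silently prorated area.
    """
    edges = np.concatenate([table.bins["bin_lo"].to_numpy(), [table.bins["bin_hi"].iloc[-1]]])
    for bound in (lo, hi):
        if not np.isclose(edges, bound, atol=1e-9).any():
            raise ValueError(f"bound {bound} does not align with bin edges {np.round(edges, 6)}")
    sel = (table.bins["bin_lo"] >= lo - 1e-9) & (table.bins["bin_hi"] <= hi + 1e-9)
    return float(table.bins.loc[sel, "area_km2"].sum())


def area_percentages(presence_km2: float, absence_km2: float) -> tuple[float, float]:
    """Presence/absence shares (%) of the mapped territory; they sum to 100."""
    total = presence_km2 + absence_km2
    if total <= 0:
        raise ValueError("total mapped area must be positive")
    return 100.0 * presence_km2 / total, 100.0 * absence_km2 / total


def binary_area(
    class_map: RasterGrid, area_mode: str = "geographic"
) -> tuple[float, float, float, float]:
    """(presence_km2, absence_km2, presence_pct, absence_pct) of a binary map."""
    mask = class_map.valid_mask
    if not mask.any():
        raise ValueError("binary map has no valid cells")
    v = class_map.values
    vals = set(np.unique(v[mask]))
    if not vals <= {0.0, 1.0}:
        raise ValueError(f"binary map must contain only 0/1, got values {sorted(vals)[:5]}")
    areas = np.broadcast_to(cell_areas_km2(class_map, area_mode), v.shape)
    presence = float(areas[mask & (v == 1)].sum())
    absence = float(areas[mask & (v == 0)].sum())
    p_pct, a_pct = area_percentages(presence, absence)
    return presence, absence, p_pct, a_pct
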