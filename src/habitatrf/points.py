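"""Labelled occurrence records (presence / pseudo-absence points)."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

PRESENCE = "presence"
PSEUDO_ABSENCE = "pseudo_absence"
_VALID_LABELS = frozenset({PRESENCE, PSEUDO_ABSENCE})

__all__ = ["PRESENCE", "PSEUDO_ABSENCE", "OccurrenceSet"]


@dataclass
class OccurrenceSet:
    """Point records with coordinates and a presence / pseudo-absence label.

    Backed by a DataFrame with columns ``lon, lat, label``; coordinates
    are cell centres throughout this package, which removes any
    point-in-pixel ambiguity downstream.
    """

    records: pd.DataFrame
    crs_tag: str = "EPSG:4326"

    def __post_init__(self) -> None:
        required = {"lon", "lat", "label"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"occurrence table missing column(s): {sorted(missing)}")
        bad = set(self.records["label"].unique()) - _VALID_LABELS
        if bad:
            raise ValueError(
                f"labels must be in {sorted(_VALID_LABELS)}, got extra {sorted(bad)}"
            )
        self.records = self.records.reset_index(drop=True)

    @classmethod
    def from_arrays(
        cls, lon: np.ndarray, lat: np.ndarray, label: str | np.ndarray, crs_tag: str = "EPSG:4326"
    ) -> "OccurrenceSet":
        lon = np.asarray(lon, dtype=float)
        if np.isscalar(label) or isinstance(label, str):
            label = np.full(lon.shape, label, dtype=object)
        return cls(
            pd.DataFrame({"lon": lon, "lat": np.asarray(lat, dtype=float), "label": label}),
            crs_tag=crs_tag,
        )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def lon(self) -> np.ndarray:
        return self.records["lon"].to_numpy()

    @property
    def lat(self) -> np.ndarray:
        return self.records["lat"].to_numpy()

    @property
    def labels(self) -> np.ndarray:
        return self.records["label"].to_numpy()

    def presences(self) -> "OccurrenceSet":
        return OccurrenceSet(self.records[self.records["label"] == PRESENCE], self.crs_tag)

    def pseudo_absences(self) -> "OccurrenceSet":
        return OccurrenceSet(self.records[self.records["label"] == PSEUDO_ABSENCE], self.crs_tag)

    def concat(self, other: "OccurrenceSet") -> "OccurrenceSet":
        return OccurrenceSet(
            pd.concat([self.records, other.records], ignore_index=True), self.crs_tag
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.records.to_csv(path, index=False)
        return path

    @classmethod
    def read_csv(cls, path: str | Path, crs_tag: str = "EPSG:4326") -> "OccurrenceSet":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"occurrence file not found: {path}")
        return cls(pd.read_csv(path), crs_tag=crs_tag)
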