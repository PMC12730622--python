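"""Occurrence and background point sets (projected coordinates, metres)."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class OccurrenceSet:
    """Presence points: one row per site, projected x/y in metres."""

    data: pd.DataFrame  # columns: site_id, x, y

    def __post_init__(self) -> None:
        missing = {"site_id", "x", "y"} - set(self.data.columns)
        if missing:
            raise ValueError(f"occurrence table missing columns: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def xy(self) -> np.ndarray:
        return self.data[["x", "y"]].to_numpy(float)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "OccurrenceSet":
        return cls(pd.read_csv(path))

    def to_geojson(self, path: str | Path, crs_id: str = "local-metres") -> None:
        features = [
            {
                "type": "Feature",
                "properties": {"site_id": row.site_id},
                "geometry": {"type": "Point", "coordinates": [row.x, row.y]},
            }
            for row in self.data.itertuples()
        ]
        doc = {"type": "FeatureCollection", "crs_id": crs_id, "features": features}
        Path(path).write_text(json.dumps(doc, indent=1))


@dataclass
class BackgroundSet:
    """Background (pseudo-absence) points with their sampling stratum.

    ``stratum`` is ``"buffer"`` (within the survey buffer around occurrences)
    or ``"mask"`` (anywhere on the analysis mask).
    """

    data: pd.DataFrame  # columns: x, y, stratum
    seed: int | None = None

    def __post_init__(self) -> None:
        missing = {"x", "y", "stratum"} - set(self.data.columns)
        if missing:
            raise ValueError(f"background table missing columns: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def xy(self) -> np.ndarray:
        return self.data[["x", "y"]].to_numpy(float)

    def stratum_counts(self) -> dict[str, int]:
        return self.data["stratum"].value_counts().to_dict()

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "BackgroundSet":
        return cls(pd.read_csv(path))
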