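"""Field-survey site records and their summary statistics.

The package ships the six published survey records of the Korean
*Cotoneaster integerrimus* population (one calcareous scree site, five
deciduous broad-leaved forest sites) as a CSV fixture; :func:`load_survey_sites`
reads it.  Summaries report min/max/mean/median per numeric field and an
8-sector compass tally of aspects; the field-recorded 16-sector labels are
stored verbatim.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

LIGHT_CONDITIONS = ("full-sun", "partial-shade")

SECTORS_8 = ("N", "NE", "E", "SE", "S", "SW", "W", "NW")

NUMERIC_FIELDS = ("altitude_m", "n_individuals", "area_m2", "slope_deg")


@dataclass(frozen=True)
class SiteRecord:
    site_id: int
    habitat_type: str
    altitude_m: float
    n_individuals: int
    area_m2: float
    aspect_deg: float
    slope_deg: float
    light_condition: str
    aspect_label: str = ""

    def __post_init__(self) -> None:
        if self.altitude_m <= 0:
            raise ValueError("altitude must be positive")
        if not 0 <= self.slope_deg <= 90:
            raise ValueError("slope must lie in [0, 90] degrees")
        if not 0 <= self.aspect_deg < 360:
            raise ValueError("aspect must lie in [0, 360) degrees")
        if self.light_condition not in LIGHT_CONDITIONS:
            raise ValueError(f"unknown light condition {self.light_condition!r}")


def aspect_sector(aspect_deg: float) -> str:
    """8-sector compass class; N spans [337.5, 360) and [0, 22.5)."""
    return SECTORS_8[int(((aspect_deg + 22.5) % 360) // 45)]


@dataclass
class SiteSummary:
    """Per-field min/max/mean/median plus aspect and categorical tallies."""

    numeric: dict[str, dict[str, float]]
    aspect_sectors: dict[str, int]
    habitat_types: dict[str, int]
    light_conditions: dict[str, int]
    n_sites: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1))

    def to_text(self) -> str:
        lines = [f"Survey summary over {self.n_sites} sites", "-" * 46]
        lines.append(f"{'field':<16s}{'min':>7s}{'max':>7s}{'mean':>8s}{'median':>8s}")
        for name, s in self.numeric.items():
            lines.append(
                f"{name:<16s}{s['min']:>7.1f}{s['max']:>7.1f}{s['mean']:>8.1f}{s['median']:>8.1f}"
            )
        lines.append("aspect sectors: " + ", ".join(f"{k}={v}" for k, v in self.aspect_sectors.items()))
        lines.append("habitat types:  " + ", ".join(f"{k}={v}" for k, v in self.habitat_types.items()))
        lines.append("light:          " + ", ".join(f"{k}={v}" for k, v in self.light_conditions.items()))
        return "\n".join(lines)


def summarize_sites(records: list[SiteRecord]) -> SiteSummary:
    """Summary statistics of the survey records (order-invariant)."""
    if not records:
        raise ValueError("no site records to summarize")
    numeric = {}
    for name in NUMERIC_FIELDS:
        v = np.array([getattr(r, name) for r in records], float)
        numeric[name] = {
            "min": float(v.min()),
            "max": float(v.max()),
            "mean": float(v.mean()),
            "median": float(np.median(v)),
        }
    sectors = {s: 0 for s in SECTORS_8}
    habitats: dict[str, int] = {}
    light: dict[str, int] = {}
    for r in records:
        sectors[aspect_sector(r.aspect_deg)] += 1
        habitats[r.habitat_type] = habitats.get(r.habitat_type, 0) + 1
        light[r.light_condition] = light.get(r.light_condition, 0) + 1
    return SiteSummary(
        numeric=numeric,
        aspect_sectors={k: v for k, v in sectors.items() if v},
        habitat_types=habitats,
        light_conditions=light,
        n_sites=len(records),
    )


def records_from_frame(df: pd.DataFrame) -> list[SiteRecord]:
    return [
        SiteRecord(
            site_id=int(row.site_id),
            habitat_type=str(row.habitat_type),
            altitude_m=float(row.altitude_m),
            n_individuals=int(row.n_individuals),
            area_m2=float(row.area_m2),
            aspect_deg=float(row.aspect_deg),
            slope_deg=float(row.slope_deg),
            light_condition=str(row.light_condition),
            aspect_label=str(getattr(row, "aspect_label", "")),
        )
        for row in df.itertuples()
    ]


def load_sites_csv(path: str | Path) -> list[SiteRecord]:
    return records_from_frame(pd.read_csv(path))


def load_survey_sites() -> list[SiteRecord]:
    """The six bundled Korean survey records."""
    with resources.files("karstsdm.data").joinpath("survey_sites.csv").open() as fh:
        return records_from_frame(pd.read_csv(fh))
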