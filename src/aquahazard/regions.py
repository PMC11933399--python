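"""District polygons, climate zones and point-to-district assignment.

Districts are the aggregation unit for the water-quality index, the
hazard index and population exposure.  Coordinates are planar kilometres
throughout the synthetic world; real-data users may carry a CRS string
opaquely through the I/O layer.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon, box


class ClimateZone(str, enum.Enum):
    """Sri Lanka's agro-climatic zones by mean annual rainfall:
    dry (< 1,750 mm), intermediate (1,750-2,500 mm), wet (> 2,500 mm)."""

    DRY = "dry"
    INTERMEDIATE = "intermediate"
    WET = "wet"


@dataclass
class District:
    id: str
    polygon: Polygon
    climate_zone: ClimateZone
    population: int

    def __post_init__(self) -> None:
        if self.population < 0:
            raise ValueError(f"district {self.id}: negative population")


@dataclass
class DistrictMap:
    """Non-overlapping district polygons partitioning a study rectangle."""

    districts: list[District]
    bounds: tuple[float, float, float, float]  # x_min, y_min, x_max, y_max
    crs: str | None = None
    _order: list[District] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._order = sorted(self.districts, key=lambda d: d.id)

    def __len__(self) -> int:
        return len(self.districts)

    @property
    def ids(self) -> list[str]:
        return [d.id for d in self._order]

    @property
    def total_population(self) -> int:
        return int(sum(d.population for d in self.districts))

    def __getitem__(self, district_id: str) -> District:
        for d in self.districts:
            if d.id == district_id:
                return d
        raise KeyError(district_id)

    @property
    def rectangle(self) -> Polygon:
        return box(*self.bounds)

    def assign_points(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """District id for each point, or ``""`` for points outside all
        districts.  Boundary points belong to exactly one district: the
        one with the lowest id (districts are scanned in id order)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        out = np.full(x.shape, "", dtype=object)
        unassigned = np.ones(x.shape, dtype=bool)
        for d in self._order:
            if not unassigned.any():
                break
            hit = unassigned & shapely.intersects_xy(d.polygon, x, y)
            out[hit] = d.id
            unassigned &= ~hit
        return out

    def zone_of(self, district_id: str) -> ClimateZone:
        return self[district_id].climate_zone
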