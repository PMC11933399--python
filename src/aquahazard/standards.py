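"""Drinking-water standards and exceedance screening.

The hazard index screens ten chemical parameters of groundwater against
drinking-water limits (WHO / US EPA by default, Sri Lankan national
standards as an alternative).  Every parameter is hazardous when it
*exceeds* its limit, with one deliberate reversal: low iron in drinking
water provides no nutritional benefit and is linked to anemia in children
and pregnant women, so iron is flagged when it falls *below* the limit.

Limits ship as a packaged, human-editable CSV
(``aquahazard/data/standards.csv``); callers may load an override file
with the same columns.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "INDEX_PARAMETERS",
    "Source",
    "Direction",
    "StandardsEntry",
    "load_standards",
    "violates",
    "MissingValueError",
]

#: The ten chemical parameters entering the hazard index and the WQI,
#: in canonical order.  pH is screened in descriptive statistics only and
#: never enters the index.
INDEX_PARAMETERS: tuple[str, ...] = (
    "Chloride",
    "Alkalinity",
    "Nitrate",
    "Nitrite",
    "Fluoride",
    "Phosphate",
    "TDS",
    "Hardness",
    "Iron",
    "Sulphate",
)


class Source(str, enum.Enum):
    """Which body's drinking-water limits to screen against."""

    WHO_EPA = "WHO_EPA"
    SriLanka = "SriLanka"


class Direction(str, enum.Enum):
    ABOVE_IS_HAZARD = "above_is_hazard"
    BELOW_IS_HAZARD = "below_is_hazard"


class MissingValueError(ValueError):
    """A missing concentration reached a screening step; impute or drop first."""


@dataclass(frozen=True)
class StandardsEntry:
    """A single parameter's limit and hazard direction.

    Attributes
    ----------
    parameter : str
        One of :data:`INDEX_PARAMETERS`.
    limit : float
        The screening limit in ``unit`` (mg/L throughout).
    source : Source
    direction : Direction
        ``above_is_hazard`` for every parameter except iron, where
        deficiency below the limit is the health concern.
    unit : str
    """

    parameter: str
    limit: float
    source: Source
    direction: Direction
    unit: str = "mg/L"

    def __post_init__(self) -> None:
        if self.limit <= 0:
            raise ValueError(f"limit must be positive, got {self.limit}")
        below = self.direction == Direction.BELOW_IS_HAZARD
        if below != (self.parameter == "Iron"):
            raise ValueError(
                "below_is_hazard applies to Iron and only to Iron "
                f"(got {self.parameter} / {self.direction.value})"
            )


def load_standards(
    source: Source | str = Source.WHO_EPA, path: str | Path | None = None
) -> list[StandardsEntry]:
    """Load the screening limits for one standards body.

    Parameters
    ----------
    source : Source or str
        ``WHO_EPA`` (default; these are the limits the hazard index uses)
        or ``SriLanka``.  Where the Sri Lankan standard is a
        desirable-to-permissible range, the lower (most protective) bound
        is stored.
    path : optional
        Override CSV with columns ``parameter, limit, unit, source,
        direction``; defaults to the packaged table.

    Returns
    -------
    list of StandardsEntry, one per index parameter, in canonical order.
    """
    source = Source(source)
    if path is None:
        with resources.files("aquahazard.data").joinpath("standards.csv").open() as fh:
            table = pd.read_csv(fh)
    else:
        table = pd.read_csv(path)
    sub = table[table["source"] == source.value].set_index("parameter")
    missing = [p for p in INDEX_PARAMETERS if p not in sub.index]
    if missing:
        raise ValueError(f"standards table lacks {source.value} limits for {missing}")
    return [
        StandardsEntry(
            parameter=p,
            limit=float(sub.loc[p, "limit"]),
            source=source,
            direction=Direction(sub.loc[p, "direction"]),
            unit=str(sub.loc[p, "unit"]),
        )
        for p in INDEX_PARAMETERS
    ]


def violates(value: float, entry: StandardsEntry) -> bool:
    """True iff ``value`` is on the hazardous side of the limit.

    Strict inequality: a concentration exactly at the limit is compliant
    in both directions.  Missing values are rejected — callers must
    impute or drop them first.
    """
    if value is None or pd.isna(value):
        raise MissingValueError(
            f"missing {entry.parameter} value cannot be screened; impute or drop first"
        )
    if value < 0:
        raise ValueError(f"negative concentration {value} for {entry.parameter}")
    if entry.direction == Direction.ABOVE_IS_HAZARD:
        return value > entry.limit
    return value < entry.limit


def standards_by_parameter(
    source: Source | str = Source.WHO_EPA, path: str | Path | None = None
) -> dict[str, StandardsEntry]:
    """Convenience mapping parameter name -> entry."""
    return {e.parameter: e for e in load_standards(source, path)}
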