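"""Weighted Arithmetic Water Quality Index (WAWQI).

The WAWQI condenses a multi-parameter water sample into one score.
Each parameter i gets a unit weight inversely proportional to its
standard S_i,

    K = 1 / sum_i (1 / S_i),        W_i = K / S_i   (sum W_i = 1),

and a quality rating relative to an ideal concentration V_o
(0 for every chemical parameter here; 7.0 would be used for pH),

    Q_i = 100 * (V_i - V_o) / (S_i - V_o),

so Q_i = 100 exactly at the standard and can exceed 100 above it.  The
score is sum W_i Q_i / sum W_i, and classification follows the usual
bands: [0, 25) excellent, [25, 50) good, [50, 75) poor, [75, 100) very
poor, >= 100 unsuitable for drinking.

District scores are the mean of per-well scores (preserving hotspot
wells), not the score of mean concentrations; the alternative is
available via ``aggregate="score_of_means"``.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import pandas as pd

from .regions import DistrictMap
from .standards import StandardsEntry

__all__ = [
    "WqiClass",
    "WqiResult",
    "unit_weights",
    "quality_rating",
    "wawqi_score",
    "classify_wqi",
    "well_wqi",
    "district_wqi",
]


class WqiClass(str, enum.Enum):
    EXCELLENT = "excellent"
    GOOD = "good"
    POOR = "poor"
    VERY_POOR = "very_poor"
    UNSUITABLE = "unsuitable"


@dataclass(frozen=True)
class WqiResult:
    unit: str  # "well" or "district"
    id: str
    score: float
    class_label: WqiClass
    standards_source: str
    n_wells: int = 1


def unit_weights(standards: list[StandardsEntry]) -> dict[str, float]:
    """W_i = K / S_i with K = 1 / sum(1/S_i); the weights sum to 1."""
    if not standards:
        raise ValueError("empty standards list")
    for e in standards:
        if e.limit <= 0:
            raise ValueError(f"non-positive standard for {e.parameter}")
    k = 1.0 / sum(1.0 / e.limit for e in standards)
    return {e.parameter: k / e.limit for e in standards}


def quality_rating(value: float, entry: StandardsEntry, ideal: float = 0.0) -> float:
    """Q_i = 100 (V_i - V_o) / (S_i - V_o); unbounded above 100."""
    if entry.limit == ideal:
        raise ValueError(f"standard equals ideal for {entry.parameter}; rating undefined")
    return 100.0 * (value - ideal) / (entry.limit - ideal)


def wawqi_score(
    values: dict[str, float],
    standards: list[StandardsEntry],
    ideals: dict[str, float] | None = None,
) -> float:
    """Aggregate score over the parameters present in both ``values`` and
    ``standards``; weights are renormalized over that subset."""
    ideals = ideals or {}
    used = [e for e in standards if e.parameter in values]
    if not used:
        raise ValueError("no overlapping parameters between values and standards")
    for e in used:
        if pd.isna(values[e.parameter]):
            raise ValueError(f"missing {e.parameter} value; complete the table first")
    w = unit_weights(used)
    num = sum(
        w[e.parameter] * quality_rating(values[e.parameter], e, ideals.get(e.parameter, 0.0))
        for e in used
    )
    return num / sum(w.values())


def classify_wqi(score: float) -> WqiClass:
    if score < 0:
        raise ValueError(f"negative WQI score {score}")
    if score < 25:
        return WqiClass.EXCELLENT
    if score < 50:
        return WqiClass.GOOD
    if score < 75:
        return WqiClass.POOR
    if score < 100:
        return WqiClass.VERY_POOR
    return WqiClass.UNSUITABLE


def well_wqi(
    wells: pd.DataFrame,
    standards: list[StandardsEntry],
    ideals: dict[str, float] | None = None,
) -> pd.Series:
    """Per-well WAWQI scores (the table must be complete)."""
    params = [e.parameter for e in standards if e.parameter in wells.columns]
    if not params:
        raise ValueError("well table has no index-parameter columns")
    sub = wells[params]
    if sub.isna().any().any():
        raise ValueError("well table has missing index values; impute or drop first")
    w = unit_weights([e for e in standards if e.parameter in params])
    ideals = ideals or {}
    total = sum(w.values())
    score = sum(
        w[e.parameter]
        * (100.0 * (sub[e.parameter] - ideals.get(e.parameter, 0.0))
           / (e.limit - ideals.get(e.parameter, 0.0)))
        for e in standards
        if e.parameter in params
    ) / total
    return pd.Series(score.to_numpy(), index=wells["well_id"], name="wqi")


def district_wqi(
    wells: pd.DataFrame,
    districts: DistrictMap,
    standards: list[StandardsEntry],
    ideals: dict[str, float] | None = None,
    aggregate: str = "mean_of_scores",
) -> list[WqiResult]:
    """District-level WAWQI: mean of per-well scores by default.

    Districts with no wells are excluded with a warning.
    """
    if len(wells) == 0:
        raise ValueError("empty well table")
    source = standards[0].source.value
    results: list[WqiResult] = []
    for did in districts.ids:
        sub = wells[wells["district_id"] == did]
        if len(sub) == 0:
            warnings.warn(f"district {did} has no wells; excluded from WQI")
            continue
        if aggregate == "mean_of_scores":
            score = float(well_wqi(sub, standards, ideals).mean())
        elif aggregate == "score_of_means":
            params = [e.parameter for e in standards if e.parameter in sub.columns]
            score = wawqi_score(sub[params].mean().to_dict(), standards, ideals)
        else:
            raise ValueError(f"unknown aggregate {aggregate!r}")
        results.append(
            WqiResult(
                unit="district",
                id=did,
                score=score,
                class_label=classify_wqi(score),
                standards_source=source,
                n_wells=len(sub),
            )
        )
    return results
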