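"""Multi-parameter groundwater hazard index and population exposure.

For each district the hazard index is the mean, over the ten index
parameters, of the within-district proportion of evaluation units whose
concentration violates the drinking-water standard:

    index = (1/n) * sum_par  (# units violating) / (# units),

with n = 10.  The evaluation units are either interpolated grid cells
("interpolated" method) or completed well records ("imputed" method);
both pathways are always reported side by side.  The index lives in
[0, 1]; national-scale studies place district values roughly between
0.09 (best) and 0.37 (worst).

Population exposure is all-or-nothing at district resolution: a
district's entire population counts as exposed when its index exceeds a
caller-supplied threshold.  The threshold defining "exposed to poor
groundwater quality" is a modelling choice, so it is a required,
explicit argument — never a silent default.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import ParameterGrid
from .impute import ImputationResult
from .interpolate import grid_to_district_values
from .regions import DistrictMap
from .standards import Direction, StandardsEntry

__all__ = [
    "HazardClass",
    "HazardResult",
    "ExposureResult",
    "DEFAULT_HAZARD_BREAKS",
    "exceedance_fraction",
    "hazard_index",
    "hazard_by_interpolation",
    "hazard_by_imputation",
    "exceedance_table",
    "classify_hazard",
    "population_exposure",
]

#: Default class breaks chosen so the observed national extremes
#: (~0.09 and 0.37) land in the lowest and highest classes.
DEFAULT_HAZARD_BREAKS: tuple[float, float, float] = (0.10, 0.20, 0.30)

#: Districts with fewer well observations than this are flagged.
MIN_WELLS_UNFLAGGED = 5


class HazardClass(str, enum.Enum):
    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"
    VERY_HIGH = "very_high"


@dataclass(frozen=True)
class HazardResult:
    district_id: str
    method: str  # "interpolated" | "imputed"
    exceedance: dict[str, float]  # parameter -> violation fraction
    index: float
    hazard_class: HazardClass
    n_units: int
    flagged_small_n: bool = False


@dataclass(frozen=True)
class ExposureResult:
    district_id: str
    population: int
    exposed: int
    index: float


def exceedance_fraction(values: np.ndarray | list[float], entry: StandardsEntry) -> float:
    """Fraction of values on the hazardous side of the limit."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError(f"no values to screen for {entry.parameter}")
    if np.isnan(values).any():
        raise ValueError(f"missing {entry.parameter} values; impute or drop first")
    if entry.direction == Direction.ABOVE_IS_HAZARD:
        return float((values > entry.limit).mean())
    return float((values < entry.limit).mean())


def hazard_index(exceedances: dict[str, float], parameters: list[str] | tuple[str, ...]) -> float:
    """Arithmetic mean of the per-parameter violation proportions."""
    missing = [p for p in parameters if p not in exceedances]
    if missing:
        raise ValueError(f"missing exceedance fractions for {missing}")
    return float(np.mean([exceedances[p] for p in parameters]))


def _result(
    district_id: str,
    method: str,
    exc: dict[str, float],
    n_units: int,
    breaks: tuple[float, float, float],
    flagged: bool = False,
) -> HazardResult:
    idx = hazard_index(exc, list(exc))
    return HazardResult(
        district_id=district_id,
        method=method,
        exceedance=exc,
        index=idx,
        hazard_class=classify_hazard(idx, breaks),
        n_units=n_units,
        flagged_small_n=flagged,
    )


def hazard_by_interpolation(
    grids: list[ParameterGrid],
    districts: DistrictMap,
    standards: list[StandardsEntry],
    breaks: tuple[float, float, float] = DEFAULT_HAZARD_BREAKS,
) -> list[HazardResult]:
    """Grid-cell pathway: pool each parameter grid's cells by district
    and screen them.  All grids must share one GridSpec."""
    by_param = {e.parameter: e for e in standards}
    specs = {id(g.spec) for g in grids}
    if len({(g.spec.x_min, g.spec.y_min, g.spec.cell_size, g.spec.shape) for g in grids}) > 1:
        raise ValueError("all parameter grids must share one GridSpec")
    del specs
    pooled = {g.parameter: grid_to_district_values(g, districts) for g in grids}
    results: list[HazardResult] = []
    for did in districts.ids:
        exc: dict[str, float] = {}
        n_units = 0
        skip = False
        for g in grids:
            vals = pooled[g.parameter].get(did)
            if vals is None:
                skip = True  # no cell centres in this district
                break
            exc[g.parameter] = exceedance_fraction(vals, by_param[g.parameter])
            n_units = len(vals)
        if skip:
            continue
        results.append(_result(did, "interpolated", exc, n_units, breaks))
    return results


def hazard_by_imputation(
    imputed: ImputationResult | pd.DataFrame,
    districts: DistrictMap,
    standards: list[StandardsEntry],
    breaks: tuple[float, float, float] = DEFAULT_HAZARD_BREAKS,
) -> list[HazardResult]:
    """Point-observation pathway: screen the completed well values per
    district.  Districts with zero wells are excluded with a warning;
    districts with < 5 wells are flagged in the result metadata."""
    table = imputed.completed if isinstance(imputed, ImputationResult) else imputed
    if len(table) == 0:
        raise ValueError("empty well table")
    params = [e.parameter for e in standards if e.parameter in table.columns]
    by_param = {e.parameter: e for e in standards}
    results: list[HazardResult] = []
    for did in districts.ids:
        sub = table[table["district_id"] == did]
        if len(sub) == 0:
            warnings.warn(f"district {did} has no wells; excluded from hazard index")
            continue
        exc = {p: exceedance_fraction(sub[p].to_numpy(), by_param[p]) for p in params}
        results.append(
            _result(did, "imputed", exc, len(sub), breaks,
                    flagged=len(sub) < MIN_WELLS_UNFLAGGED)
        )
    return results


def exceedance_table(results: list[HazardResult]) -> pd.DataFrame:
    """District x parameter matrix of violation percentages (fraction x
    100), rows sorted by descending hazard index.  Row sums carry no
    meaning and are not normalized."""
    if not results:
        raise ValueError("no hazard results")
    rows = sorted(results, key=lambda r: (-r.index, r.district_id))
    data = {r.district_id: {p: 100.0 * f for p, f in r.exceedance.items()} for r in rows}
    out = pd.DataFrame.from_dict(data, orient="index")
    out.index.name = "district_id"
    return out


def classify_hazard(
    index: float, breaks: tuple[float, float, float] = DEFAULT_HAZARD_BREAKS
) -> HazardClass:
    """Ordinal class from ascending breaks; a boundary value belongs to
    the upper class (0.10 with default breaks is already moderate)."""
    if not (0.0 <= index <= 1.0):
        raise ValueError(f"hazard index {index} outside [0, 1]")
    b1, b2, b3 = breaks
    if not (b1 < b2 < b3):
        raise ValueError(f"breaks must be strictly ascending, got {breaks}")
    if index < b1:
        return HazardClass.LOW
    if index < b2:
        return HazardClass.MODERATE
    if index < b3:
        return HazardClass.HIGH
    return HazardClass.VERY_HIGH


def population_exposure(
    results: list[HazardResult],
    districts: DistrictMap,
    exposure_threshold: float,
) -> tuple[list[ExposureResult], dict[str, float]]:
    """District and national exposure at the given index threshold.

    A district's whole population is exposed iff its hazard index
    exceeds ``exposure_threshold`` (total population regardless of
    actual drinking-water source).  Returns the per-district rows and a
    national summary with keys ``national_total``, ``national_exposed``
    and ``national_percent`` (= 100 * exposed / total).
    """
    if not (0.0 <= exposure_threshold <= 1.0):
        raise ValueError("exposure_threshold must be in [0, 1]")
    rows: list[ExposureResult] = []
    for r in results:
        pop = districts[r.district_id].population
        rows.append(
            ExposureResult(
                district_id=r.district_id,
                population=pop,
                exposed=pop if r.index > exposure_threshold else 0,
                index=r.index,
            )
        )
    total = districts.total_population
    exposed = int(sum(r.exposed for r in rows))
    summary = {
        "national_total": float(total),
        "national_exposed": float(exposed),
        "national_percent": 100.0 * exposed / total if total else float("nan"),
    }
    return rows, summary
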