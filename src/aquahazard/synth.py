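"""Synthetic national well networks for end-to-end pipeline testing.

The real agency datasets behind this kind of national groundwater survey
are typically not redistributable, so this module builds a fully
synthetic stand-in with the same statistical anatomy: 25 Voronoi
"districts" over a 250 x 420 km rectangle (roughly a Sri Lanka-sized
study area), three spatially contiguous climate zones, lognormal
spatially autocorrelated "true" concentration fields calibrated to
published climate-zone means, 688 sampled wells with realistic
per-parameter missingness (4%-71%), and a district population surface
totalling 22 million people.

Everything is deterministic given a seed, and the dense true fields are
retained so that estimator output can be scored against exhaustive
ground truth (:func:`true_district_exceedance`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import Voronoi, cKDTree
from shapely.geometry import Polygon, box

from .grids import GridSpec, ParameterGrid
from .regions import ClimateZone, District, DistrictMap
from .standards import INDEX_PARAMETERS, StandardsEntry

__all__ = [
    "STUDY_BOUNDS",
    "N_WELLS_DEFAULT",
    "TOTAL_POPULATION_DEFAULT",
    "OBSERVED_COUNTS",
    "ZONE_MEANS",
    "DEFAULT_CLUSTERS",
    "TrueField",
    "default_missing_rates",
    "generate_districts",
    "generate_true_fields",
    "sample_wells",
    "apply_missingness",
    "true_district_exceedance",
]

#: Study rectangle in planar km, roughly Sri Lanka's extent.
STUDY_BOUNDS: tuple[float, float, float, float] = (0.0, 0.0, 250.0, 420.0)

N_WELLS_DEFAULT = 688
TOTAL_POPULATION_DEFAULT = 22_000_000

#: Number of wells with an observed value per parameter, out of 688
#: (the survey's bookkeeping table); missingness rates derive from these.
OBSERVED_COUNTS: dict[str, int] = {
    "Chloride": 598,
    "Alkalinity": 613,
    "Nitrate": 316,
    "Nitrite": 208,
    "Fluoride": 613,
    "Phosphate": 199,
    "TDS": 348,
    "Hardness": 659,
    "Iron": 620,
    "Sulphate": 437,
}

#: Mean concentration (mg/L) of each parameter within each climate zone;
#: the calibration targets of the true-field generator.
ZONE_MEANS: dict[str, dict[ClimateZone, float]] = {
    "Chloride": {ClimateZone.DRY: 279.2, ClimateZone.INTERMEDIATE: 129.0, ClimateZone.WET: 60.20},
    "Alkalinity": {ClimateZone.DRY: 262.9, ClimateZone.INTERMEDIATE: 193.2, ClimateZone.WET: 104.9},
    "Nitrate": {ClimateZone.DRY: 2.5, ClimateZone.INTERMEDIATE: 2.9, ClimateZone.WET: 2.8},
    "Nitrite": {ClimateZone.DRY: 0.1, ClimateZone.INTERMEDIATE: 0.5, ClimateZone.WET: 1.3},
    "Fluoride": {ClimateZone.DRY: 1.0, ClimateZone.INTERMEDIATE: 0.7, ClimateZone.WET: 0.5},
    "Phosphate": {ClimateZone.DRY: 0.7, ClimateZone.INTERMEDIATE: 0.6, ClimateZone.WET: 0.4},
    "TDS": {ClimateZone.DRY: 875.3, ClimateZone.INTERMEDIATE: 436.2, ClimateZone.WET: 178.7},
    "Hardness": {ClimateZone.DRY: 343.2, ClimateZone.INTERMEDIATE: 234.4, ClimateZone.WET: 127.3},
    "Iron": {ClimateZone.DRY: 2.3, ClimateZone.INTERMEDIATE: 3.3, ClimateZone.WET: 2.6},
    "Sulphate": {ClimateZone.DRY: 54.4, ClimateZone.INTERMEDIATE: 32.0, ClimateZone.WET: 18.4},
}

#: Parameters sharing a latent spatial field, so that imputation has
#: cross-parameter signal to exploit: a salinity/mineralisation cluster,
#: a nutrient cluster, and two geogenic singletons.
DEFAULT_CLUSTERS: dict[str, tuple[str, ...]] = {
    "salinity": ("Chloride", "TDS", "Hardness", "Sulphate", "Alkalinity"),
    "nutrients": ("Nitrate", "Nitrite", "Phosphate"),
    "fluoride": ("Fluoride",),
    "iron": ("Iron",),
}

DEFAULT_CORRELATION_LENGTH_KM = 40.0
DEFAULT_FIELD_CV = 0.8
DEFAULT_BOUNDARY_SMOOTHING_KM = 15.0
DEFAULT_CLUSTER_WEIGHT = 0.7
DEFAULT_MEASUREMENT_CV = 0.05
DEFAULT_TRUE_CELL_KM = 2.0

# Domain tags mixed into each generator's SeedSequence so that passing
# one integer seed to several stages yields independent random streams
# (identical raw streams would, e.g., correlate a deletion mask with the
# well coordinates drawn from the same generator state).
_SEED_DOMAIN = {"districts": 1, "fields": 2, "wells": 3, "missingness": 4}


def _rng(seed: int, domain: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _SEED_DOMAIN[domain]]))


@dataclass
class TrueField:
    """A dense 'ground truth' raster of one parameter's concentrations."""

    parameter: str
    grid: ParameterGrid
    zone_means: dict[ClimateZone, float]
    correlation_length: float
    cv: float


def default_missing_rates() -> dict[str, float]:
    """Per-parameter missingness fractions implied by the observed counts
    (e.g. Phosphate 1 - 199/688 = 71%, Hardness 1 - 659/688 = 4%)."""
    return {p: 1.0 - OBSERVED_COUNTS[p] / N_WELLS_DEFAULT for p in INDEX_PARAMETERS}


# ---------------------------------------------------------------------------
# districts


def _clipped_voronoi(points: np.ndarray, bounds: tuple[float, float, float, float]) -> list[Polygon]:
    """Voronoi cells of ``points`` clipped to the bounding rectangle.

    Seeds are mirrored across all four edges so every original cell is
    finite; the mirrored construction tessellates the rectangle exactly.
    """
    x0, y0, x1, y1 = bounds
    mirrored = [points]
    for refl in (
        lambda p: np.column_stack([2 * x0 - p[:, 0], p[:, 1]]),
        lambda p: np.column_stack([2 * x1 - p[:, 0], p[:, 1]]),
        lambda p: np.column_stack([p[:, 0], 2 * y0 - p[:, 1]]),
        lambda p: np.column_stack([p[:, 0], 2 * y1 - p[:, 1]]),
    ):
        mirrored.append(refl(points))
    vor = Voronoi(np.vstack(mirrored))
    rect = box(*bounds)
    polys: list[Polygon] = []
    for i in range(len(points)):
        region = vor.regions[vor.point_region[i]]
        poly = Polygon(vor.vertices[region]).intersection(rect)
        polys.append(poly)
    return polys


def generate_districts(
    n_districts: int = 25,
    seed: int = 0,
    bounds: tuple[float, float, float, float] = STUDY_BOUNDS,
    total_population: int = TOTAL_POPULATION_DEFAULT,
    zone_fractions: tuple[float, float, float] = (0.5, 0.3, 0.2),
) -> DistrictMap:
    """Random Voronoi districts with contiguous climate zones.

    Climate zones follow a smooth northeast gradient in lieu of real
    orography: districts whose centroids score highest on
    ``0.75 * northness + 0.25 * eastness`` become dry, the lowest become
    wet — mimicking a dry north/east and a wet southwest.  District
    populations are lognormal weights scaled to ``total_population``
    exactly (a few very populous districts, many small ones).

    ``zone_fractions`` are the (dry, intermediate, wet) shares of
    districts, applied by rank.
    """
    if n_districts < 2:
        raise ValueError("need at least 2 districts")
    rng = _rng(seed, "districts")
    x0, y0, x1, y1 = bounds
    pts = np.column_stack(
        [rng.uniform(x0, x1, n_districts), rng.uniform(y0, y1, n_districts)]
    )
    polys = _clipped_voronoi(pts, bounds)

    cent = np.array([[p.centroid.x, p.centroid.y] for p in polys])
    score = 0.75 * (cent[:, 1] - y0) / (y1 - y0) + 0.25 * (cent[:, 0] - x0) / (x1 - x0)
    order = np.argsort(score)  # ascending: wet first, dry last
    n_wet = max(1, round(zone_fractions[2] * n_districts)) if n_districts >= 3 else 1
    n_dry = max(1, round(zone_fractions[0] * n_districts))
    zones = np.empty(n_districts, dtype=object)
    zones[order[:n_wet]] = ClimateZone.WET
    zones[order[n_wet:]] = ClimateZone.INTERMEDIATE
    zones[order[n_districts - n_dry:]] = ClimateZone.DRY

    w = rng.lognormal(mean=0.0, sigma=1.0, size=n_districts)
    frac = total_population * w / w.sum()
    pops = np.floor(frac).astype(int)
    # hand out the rounding remainder to the largest fractional parts
    short = int(total_population - pops.sum())
    for i in np.argsort(-(frac - pops))[:short]:
        pops[i] += 1

    districts = [
        District(
            id=f"D{i + 1:02d}",
            polygon=polys[i],
            climate_zone=zones[i],
            population=int(pops[i]),
        )
        for i in range(n_districts)
    ]
    return DistrictMap(districts=districts, bounds=bounds)


# ---------------------------------------------------------------------------
# true fields


def _standardized_grf(shape: tuple[int, int], sigma_cells: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian random field: smoothed white noise,
    re-standardized empirically (periodic boundary for stationarity)."""
    white = rng.standard_normal(shape)
    f = gaussian_filter(white, sigma=sigma_cells, mode="wrap")
    sd = f.std()
    if sd == 0:  # degenerate tiny grid
        return np.zeros(shape)
    return (f - f.mean()) / sd


def _cell_zone_masks(
    spec: GridSpec, districts: DistrictMap
) -> tuple[np.ndarray, dict[ClimateZone, np.ndarray]]:
    """District id per cell (grid-shaped) and boolean mask per zone.

    The rare cell centre falling exactly on a district boundary sliver is
    filled from its nearest assigned neighbour.
    """
    gx, gy = spec.center_points()
    ids = districts.assign_points(gx, gy)
    missing = ids == ""
    if missing.any():
        assigned = ~missing
        tree = cKDTree(np.column_stack([gx[assigned], gy[assigned]]))
        _, nearest = tree.query(np.column_stack([gx[missing], gy[missing]]))
        ids[missing] = ids[assigned][nearest]
    ids = ids.reshape(spec.shape)
    masks = {}
    for z in ClimateZone:
        members = {d.id for d in districts.districts if d.climate_zone == z}
        masks[z] = np.isin(ids, list(members)) if members else np.zeros(spec.shape, bool)
    return ids, masks


def generate_true_fields(
    districts: DistrictMap,
    zone_means: dict[str, dict[ClimateZone, float]] | None = None,
    correlation_length: float = DEFAULT_CORRELATION_LENGTH_KM,
    cv: float = DEFAULT_FIELD_CV,
    cell_size: float = DEFAULT_TRUE_CELL_KM,
    clusters: dict[str, tuple[str, ...]] | None = None,
    cluster_weight: float = DEFAULT_CLUSTER_WEIGHT,
    boundary_smoothing: float = DEFAULT_BOUNDARY_SMOOTHING_KM,
    seed: int = 0,
) -> list[TrueField]:
    """Lognormal spatially autocorrelated true fields, one per parameter.

    Each parameter's field is ``M(x, y) * exp(s * Z)`` with
    ``s = sqrt(log(1 + cv^2))``, ``Z`` a unit Gaussian random field of
    the given correlation length, and ``M`` the zone-mean surface
    blurred across climate-zone boundaries over ``boundary_smoothing``
    km — concentrations transition gradually between zones rather than
    jumping at an administrative line.  The field is then renormalized
    within each climate zone so realized zone-wise spatial means hit the
    ``zone_means`` targets exactly (the generator's calibration
    contract).  Parameters in the same cluster share
    ``sqrt(cluster_weight)`` of their latent field, giving the
    cross-parameter correlation that imputation exploits.
    """
    if cv < 0:
        raise ValueError("cv must be non-negative")
    zone_means = zone_means if zone_means is not None else ZONE_MEANS
    clusters = clusters if clusters is not None else DEFAULT_CLUSTERS
    parameters = [p for ps in clusters.values() for p in ps]
    for p in parameters:
        if p not in zone_means:
            raise ValueError(f"no zone means configured for parameter {p}")
        for z in ClimateZone:
            if z not in zone_means[p]:
                raise ValueError(f"no {z.value}-zone mean configured for {p}")

    x0, y0, x1, y1 = districts.bounds
    spec = GridSpec(x0, y0, x1, y1, cell_size)
    _, zone_masks = _cell_zone_masks(spec, districts)
    sigma_cells = correlation_length / cell_size
    rng = _rng(seed, "fields")

    cluster_latent = {
        name: _standardized_grf(spec.shape, sigma_cells, rng) for name in clusters
    }
    s = float(np.sqrt(np.log1p(cv**2)))
    w = float(np.sqrt(cluster_weight))

    fields: list[TrueField] = []
    for name, members in clusters.items():
        for p in members:
            if len(members) == 1:
                z_lat = cluster_latent[name]
            else:
                own = _standardized_grf(spec.shape, sigma_cells, rng)
                z_lat = w * cluster_latent[name] + np.sqrt(1.0 - cluster_weight) * own
            factor = np.exp(s * z_lat)
            mean_map = np.zeros(spec.shape)
            for zone, mask in zone_masks.items():
                mean_map[mask] = zone_means[p][zone]
            if boundary_smoothing > 0:
                mean_map = gaussian_filter(
                    mean_map, sigma=boundary_smoothing / cell_size, mode="nearest"
                )
            values = mean_map * factor
            for zone, mask in zone_masks.items():
                if not mask.any():
                    continue
                values[mask] *= zone_means[p][zone] / values[mask].mean()
            fields.append(
                TrueField(
                    parameter=p,
                    grid=ParameterGrid(parameter=p, spec=spec, values=values),
                    zone_means=dict(zone_means[p]),
                    correlation_length=correlation_length,
                    cv=cv,
                )
            )
    # keep canonical parameter order when the default set is used
    order = {p: i for i, p in enumerate(INDEX_PARAMETERS)}
    fields.sort(key=lambda f: order.get(f.parameter, len(order)))
    return fields


# ---------------------------------------------------------------------------
# wells


def _field_values_at(field: TrueField, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Read the true field at arbitrary points (nearest-cell lookup)."""
    spec = field.grid.spec
    j = np.clip(((x - spec.x_min) / spec.cell_size).astype(int), 0, spec.n_cols - 1)
    i = np.clip(((y - spec.y_min) / spec.cell_size).astype(int), 0, spec.n_rows - 1)
    return field.grid.values[i, j]


def sample_wells(
    fields: list[TrueField],
    districts: DistrictMap,
    n_wells: int = N_WELLS_DEFAULT,
    measurement_cv: float = DEFAULT_MEASUREMENT_CV,
    seed: int = 0,
) -> pd.DataFrame:
    """Place wells uniformly at random and read off all true fields.

    Returns a complete well table (no missingness yet) with columns
    ``well_id, x, y, district_id, climate_zone, depth`` plus one column
    per parameter.  Concentrations carry small multiplicative lognormal
    measurement noise (default 5% cv).  Well depths are lognormal around
    a 40 m median, clipped to the 4-105 m range of drilled supply wells.
    """
    if n_wells < 1:
        raise ValueError("n_wells must be >= 1")
    rng = _rng(seed, "wells")
    x0, y0, x1, y1 = districts.bounds
    xs = rng.uniform(x0, x1, n_wells)
    ys = rng.uniform(y0, y1, n_wells)
    ids = districts.assign_points(xs, ys)
    # points on boundary slivers outside every polygon: re-draw
    bad = ids == ""
    while bad.any():
        xs[bad] = rng.uniform(x0, x1, bad.sum())
        ys[bad] = rng.uniform(y0, y1, bad.sum())
        ids[bad] = districts.assign_points(xs[bad], ys[bad])
        bad = ids == ""

    zone_by_id = {d.id: d.climate_zone.value for d in districts.districts}
    depth = np.clip(rng.lognormal(np.log(40.0), 0.44, n_wells), 4.0, 105.0)
    table = pd.DataFrame(
        {
            "well_id": [f"W{i + 1:04d}" for i in range(n_wells)],
            "x": xs,
            "y": ys,
            "district_id": ids.astype(str),
            "climate_zone": [zone_by_id[i] for i in ids],
            "depth": depth,
        }
    )
    s = float(np.sqrt(np.log1p(measurement_cv**2))) if measurement_cv > 0 else 0.0
    for field in fields:
        true_vals = _field_values_at(field, xs, ys)
        noise = np.exp(s * rng.standard_normal(n_wells) - s**2 / 2) if s else 1.0
        table[field.parameter] = true_vals * noise
    return table


def apply_missingness(
    wells: pd.DataFrame,
    rates: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Delete parameter values completely at random (MCAR), per column.

    Pure function: the input table is untouched.  Default rates come
    from the survey bookkeeping counts (4% hardness ... 71% phosphate).
    """
    rates = rates if rates is not None else default_missing_rates()
    for p, r in rates.items():
        if not (0.0 <= r < 1.0):
            raise ValueError(f"missingness rate for {p} must be in [0, 1), got {r}")
    rng = _rng(seed, "missingness")
    out = wells.copy()
    for p, r in rates.items():
        if p not in out.columns:
            continue
        mask = rng.random(len(out)) < r
        out.loc[mask, p] = np.nan
    return out


# ---------------------------------------------------------------------------
# ground truth


def true_district_exceedance(
    fields: list[TrueField],
    districts: DistrictMap,
    standards: list[StandardsEntry],
) -> pd.DataFrame:
    """Exact per-district, per-parameter violation fractions from the
    dense true fields — the ground truth both estimation pathways must
    recover.  Rows are district ids, columns parameter names."""
    by_param = {e.parameter: e for e in standards}
    spec = fields[0].grid.spec
    ids, _ = _cell_zone_masks(spec, districts)
    flat_ids = ids.ravel()
    out = pd.DataFrame(index=districts.ids, columns=[f.parameter for f in fields], dtype=float)
    for field in fields:
        entry = by_param[field.parameter]
        vals = field.grid.values.ravel()
        if entry.direction.value == "above_is_hazard":
            viol = vals > entry.limit
        else:
            viol = vals < entry.limit
        for did in districts.ids:
            cell = flat_ids == did
            out.loc[did, field.parameter] = viol[cell].mean() if cell.any() else np.nan
    return out
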