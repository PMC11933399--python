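"""End-to-end orchestration: simulate -> impute -> interpolate -> WQI ->
hazard -> exposure, with a manifest for reproducibility.

Every stochastic stage consumes a sub-seed derived deterministically
from the run seed as

    stage_seed = (seed * 1_000_003 + crc32(stage_name)) mod 2^31,

so a single ``seed`` reproduces the whole run bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as ahio
from .grids import GridSpec
from .hazard import (
    DEFAULT_HAZARD_BREAKS,
    hazard_by_imputation,
    hazard_by_interpolation,
    exceedance_table,
    population_exposure,
)
from .impute import rf_impute
from .interpolate import (
    IDW_PARAMETERS,
    fit_variogram,
    interpolate_parameter,
    loo_standardized_rmse,
)
from .standards import INDEX_PARAMETERS, Source, load_standards
from .synth import (
    N_WELLS_DEFAULT,
    apply_missingness,
    generate_districts,
    generate_true_fields,
    sample_wells,
    true_district_exceedance,
)
from .wqi import district_wqi

__all__ = ["RunConfig", "stage_seed", "run_pipeline"]


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed (documented derivation)."""
    return (seed * 1_000_003 + zlib.crc32(stage.encode())) % 2**31


@dataclass
class RunConfig:
    """Knobs of a full pipeline run; CLI flags override config-file keys."""

    seed: int = 0
    standards_source: str = "WHO_EPA"
    n_districts: int = 25
    n_wells: int = N_WELLS_DEFAULT
    grid_cell_km: float = 2.0
    idw_power: float = 2.0
    ok_variogram: str | None = None  # None = automatic model selection
    log_krige: bool = True
    impute_n_trees: int = 100
    impute_max_iter: int = 10
    exposure_threshold: float = 0.2
    hazard_breaks: tuple[float, float, float] = DEFAULT_HAZARD_BREAKS
    wells_path: str | None = None  # when set, simulation is skipped
    districts_path: str | None = None
    out_dir: str = "run"
    simulate: bool = True
    write_grids: bool = False
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        doc.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in doc.items() if k in known}
        kwargs["extra"] = {k: v for k, v in doc.items() if k not in known}
        if "hazard_breaks" in kwargs:
            kwargs["hazard_breaks"] = tuple(kwargs["hazard_breaks"])
        return cls(**kwargs)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages in order and write a self-describing run
    directory; rerunning with the same config reproduces identical
    outputs.  Returns the run directory path."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    # --- inputs: simulate or load -----------------------------------------
    truth = None
    fields = None
    if config.simulate:
        districts = generate_districts(config.n_districts, seed=stage_seed(config.seed, "districts"))
        fields = generate_true_fields(districts, seed=stage_seed(config.seed, "fields"))
        complete = sample_wells(fields, districts, config.n_wells,
                                seed=stage_seed(config.seed, "wells"))
        wells = apply_missingness(complete, seed=stage_seed(config.seed, "missingness"))
        standards = load_standards(config.standards_source)
        truth = true_district_exceedance(fields, districts, standards)
        ahio.write_districts(districts, out / "districts.geojson")
        ahio.write_wells(wells, out / "wells.csv")
        truth.to_csv(out / "truth_exceedance.csv")
        written += [out / "districts.geojson", out / "wells.csv", out / "truth_exceedance.csv"]
    else:
        if not config.wells_path or not config.districts_path:
            raise ValueError("simulate=False requires wells_path and districts_path")
        wells = ahio.read_wells(config.wells_path)
        districts = ahio.read_districts(config.districts_path)
        standards = load_standards(config.standards_source)

    # --- imputation --------------------------------------------------------
    imp = rf_impute(
        wells,
        n_trees=config.impute_n_trees,
        max_iter=config.impute_max_iter,
        seed=stage_seed(config.seed, "impute"),
    )
    ahio.write_wells(imp.completed, out / "imputed.csv")
    (out / "imputation_report.json").write_text(json.dumps({
        "per_variable_oob": imp.per_variable_oob,
        "n_iterations": imp.n_iterations,
        "converged": imp.converged,
    }, indent=2))
    written += [out / "imputed.csv", out / "imputation_report.json"]

    # --- interpolation -----------------------------------------------------
    x0, y0, x1, y1 = districts.bounds
    spec = GridSpec(x0, y0, x1, y1, config.grid_cell_km)
    grids = []
    diag_rows = []
    params = [p for p in INDEX_PARAMETERS if p in wells.columns]
    for p in params:
        g = interpolate_parameter(
            wells, p, spec,
            variogram_model=config.ok_variogram,
            log_transform=config.log_krige,
            idw_power=config.idw_power,
        )
        grids.append(g)
        row = {"parameter": p, "method": g.method.value}
        if p not in IDW_PARAMETERS:
            work = wells[["x", "y", p]].copy()
            if config.log_krige:
                work[p] = np.log(work[p])
            vm = fit_variogram(work, p, config.ok_variogram)
            row.update(nugget=vm.nugget, sill=vm.sill, range_km=vm.range,
                       loo_std_rmse=(np.nan if vm.degenerate
                                     else loo_standardized_rmse(work, p, vm)))
        diag_rows.append(row)
        if config.write_grids:
            ahio.write_grid_ascii(g, out / "grids" / f"{p}.asc")
            written.append(out / "grids" / f"{p}.asc")
    pd.DataFrame(diag_rows).to_csv(out / "interpolation_diagnostics.csv", index=False)
    written.append(out / "interpolation_diagnostics.csv")

    # --- WQI (both standards bodies) ---------------------------------------
    wqi_rows = []
    for src in (Source.WHO_EPA, Source.SriLanka):
        for r in district_wqi(imp.completed, districts, load_standards(src)):
            wqi_rows.append({
                "district_id": r.id, "n_wells": r.n_wells, "score": r.score,
                "class": r.class_label.value, "standards_source": r.standards_source,
            })
    pd.DataFrame(wqi_rows).to_csv(out / "wqi.csv", index=False)
    written.append(out / "wqi.csv")

    # --- hazard index, both pathways ---------------------------------------
    interp_results = hazard_by_interpolation(grids, districts, standards, config.hazard_breaks)
    imput_results = hazard_by_imputation(imp, districts, standards, config.hazard_breaks)
    hz_rows = []
    for r in interp_results + imput_results:
        row = {"district_id": r.district_id, "method": r.method,
               "index": r.index, "class": r.hazard_class.value, "n_units": r.n_units}
        row.update({f"{p}_pct": 100.0 * f for p, f in r.exceedance.items()})
        hz_rows.append(row)
    pd.DataFrame(hz_rows).to_csv(out / "hazard.csv", index=False)
    exceedance_table(interp_results).to_csv(out / "exceedance_interpolated.csv")
    written += [out / "hazard.csv", out / "exceedance_interpolated.csv"]

    # --- exposure -----------------------------------------------------------
    exposure = {}
    exp_rows = []
    for name, res in (("interpolated", interp_results), ("imputed", imput_results)):
        rows, summary = population_exposure(res, districts, config.exposure_threshold)
        exposure[name] = summary
        for r in rows:
            exp_rows.append({"district_id": r.district_id, "method": name,
                             "population": r.population, "exposed": r.exposed,
                             "index": r.index})
    pd.DataFrame(exp_rows).to_csv(out / "exposure.csv", index=False)
    written.append(out / "exposure.csv")

    # --- summary + manifest -------------------------------------------------
    summary = {
        "seed": config.seed,
        "n_wells": int(len(wells)),
        "n_districts": len(districts),
        "hazard_index": {
            "interpolated": {r.district_id: r.index for r in interp_results},
            "imputed": {r.district_id: r.index for r in imput_results},
        },
        "exposure_threshold": config.exposure_threshold,
        "exposure": exposure,
        "imputation": {"n_iterations": imp.n_iterations,
                       "per_variable_oob": imp.per_variable_oob},
    }
    if truth is not None:
        truth_idx = truth.mean(axis=1)
        summary["truth_hazard_index"] = {d: float(v) for d, v in truth_idx.items()}
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    written.append(out / "summary.json")

    cfg = asdict(config)
    manifest = {
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "stage_seeds": {s: stage_seed(config.seed, s)
                        for s in ("districts", "fields", "wells", "missingness", "impute")},
        "outputs": {str(p.relative_to(out)): _checksum(p) for p in written},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
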