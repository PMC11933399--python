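"""Iterative random-forest imputation of missing well-record values.

National well databases typically have very uneven per-parameter
coverage (here 4%-71% missing), so the point-observation ("imputed")
hazard pathway first completes the table.  The imputer is the standard
chained random-forest scheme: initialize missing cells with column
medians, then repeatedly re-fit a random-forest regression for each
parameter (in order of increasing missingness) on all other columns and
re-predict its missing cells, until the normalized change in the imputed
values first increases or ``max_iter`` is reached.  Imputation quality
is tracked without a held-out set via each forest's out-of-bag (OOB)
predictions, and — in synthetic settings where the pre-deletion truth is
known — via the normalized root-mean-square error

    NRMSE = sqrt( mean((X_true - X_imp)^2) / var(X_true) )

taken over the missing cells only: 0 is perfect recovery, ~1 is no
better than imputing the mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .standards import INDEX_PARAMETERS

__all__ = ["ImputationResult", "rf_impute", "impute_baseline", "nrmse"]

#: Non-imputed columns used as extra predictors when present.
AUXILIARY_PREDICTORS = ("x", "y", "depth")
CATEGORICAL_PREDICTORS = ("district_id", "climate_zone")


@dataclass
class ImputationResult:
    """Completed table plus imputation diagnostics.

    ``per_variable_oob`` maps each imputed parameter to the OOB-based
    NRMSE of its final forest (error of predicting *observed* values
    from out-of-bag trees, normalized by the observed variance).
    """

    completed: pd.DataFrame
    per_variable_oob: dict[str, float]
    n_iterations: int
    converged: bool
    overall_nrmse: float | None = None
    parameters: tuple[str, ...] = field(default=INDEX_PARAMETERS)


def _design_matrix(
    table: pd.DataFrame, parameters: list[str], target: str, use_categoricals: bool
) -> np.ndarray:
    cols = [p for p in parameters if p != target]
    X = [table[cols].to_numpy(dtype=float)]
    aux = [c for c in AUXILIARY_PREDICTORS if c in table.columns]
    if aux:
        X.append(table[aux].to_numpy(dtype=float))
    if use_categoricals:
        for c in CATEGORICAL_PREDICTORS:
            if c in table.columns:
                X.append(pd.get_dummies(table[c]).to_numpy(dtype=float))
    return np.hstack(X)


def rf_impute(
    wells: pd.DataFrame,
    n_trees: int = 100,
    max_iter: int = 10,
    seed: int = 0,
    parameters: list[str] | None = None,
    use_categoricals: bool = True,
    max_features: float | str = "sqrt",
) -> ImputationResult:
    """Complete the well table by chained random-forest regression.

    Only the index parameters are imputed; coordinates, depth and (by
    default) the district / climate-zone categories serve as auxiliary
    predictors.  Observed cells pass through unchanged.  Deterministic
    given ``seed``.

    Raises ``ValueError`` if any parameter column has no observed value.
    """
    parameters = list(parameters) if parameters is not None else [
        p for p in INDEX_PARAMETERS if p in wells.columns
    ]
    if not parameters:
        raise ValueError("no index-parameter columns in the table")
    table = wells.copy()
    obs_mask = {p: table[p].notna().to_numpy() for p in parameters}
    for p in parameters:
        if not obs_mask[p].any():
            raise ValueError(f"parameter {p} has no observed values; cannot impute")

    miss_counts = {p: int((~obs_mask[p]).sum()) for p in parameters}
    to_impute = [p for p in parameters if miss_counts[p] > 0]
    if not to_impute:
        return ImputationResult(
            completed=table, per_variable_oob={}, n_iterations=0, converged=True,
            parameters=tuple(parameters),
        )
    visit_order = sorted(to_impute, key=lambda p: (miss_counts[p], p))

    # column-median initialization
    for p in to_impute:
        table.loc[~obs_mask[p], p] = table.loc[obs_mask[p], p].median()

    ss = np.random.SeedSequence(seed)
    oob: dict[str, float] = {}
    prev_imputed = {p: table.loc[~obs_mask[p], p].to_numpy(copy=True) for p in to_impute}
    best_imputed = {p: v.copy() for p, v in prev_imputed.items()}
    best_oob = dict(oob)
    prev_delta = np.inf
    n_iter = 0
    converged = False
    for _ in range(max_iter):
        n_iter += 1
        child_seeds = ss.spawn(len(visit_order))
        for p, cs in zip(visit_order, child_seeds):
            X = _design_matrix(table, parameters, p, use_categoricals)
            obs = obs_mask[p]
            rf = RandomForestRegressor(
                n_estimators=n_trees,
                max_features=max_features,  # mtry; "sqrt" is the usual imputation default
                oob_score=True,
                bootstrap=True,
                random_state=np.random.default_rng(cs).integers(2**31),
                n_jobs=1,
            )
            y_obs = table.loc[obs, p].to_numpy(dtype=float)
            rf.fit(X[obs], y_obs)
            table.loc[~obs, p] = rf.predict(X[~obs])
            var = y_obs.var()
            oob_pred = rf.oob_prediction_
            oob[p] = float(np.sqrt(np.mean((y_obs - oob_pred) ** 2) / var)) if var > 0 else 0.0
        cur = {p: table.loc[~obs_mask[p], p].to_numpy(copy=True) for p in to_impute}
        num = sum(((cur[p] - prev_imputed[p]) ** 2).sum() for p in to_impute)
        den = sum((cur[p] ** 2).sum() for p in to_impute)
        delta = num / den if den > 0 else 0.0
        if delta >= prev_delta:
            # change grew: keep the previous iteration's values (standard
            # chained-RF stopping rule)
            for p in to_impute:
                table.loc[~obs_mask[p], p] = best_imputed[p]
            oob = best_oob
            converged = True
            break
        best_imputed = {p: v.copy() for p, v in cur.items()}
        best_oob = dict(oob)
        prev_imputed = cur
        prev_delta = delta

    return ImputationResult(
        completed=table,
        per_variable_oob=oob,
        n_iterations=n_iter,
        converged=converged,
        parameters=tuple(parameters),
    )


def impute_baseline(wells: pd.DataFrame, parameters: list[str] | None = None) -> pd.DataFrame:
    """Mean imputation: every missing cell gets its column's observed mean.

    The comparison baseline — by construction its NRMSE tends to 1 under
    MCAR missingness.
    """
    parameters = list(parameters) if parameters is not None else [
        p for p in INDEX_PARAMETERS if p in wells.columns
    ]
    out = wells.copy()
    for p in parameters:
        obs = out[p].notna()
        if not obs.any():
            raise ValueError(f"parameter {p} has no observed values")
        out.loc[~obs, p] = out.loc[obs, p].mean()
    return out


def nrmse(
    true_table: pd.DataFrame,
    imputed_table: pd.DataFrame,
    mask: pd.DataFrame,
    parameters: list[str] | None = None,
) -> float:
    """Pooled normalized RMSE of the imputation over the masked cells.

    ``mask`` is a boolean frame (same row order) marking the cells that
    were deleted.  Within each parameter, squared errors are divided by
    the population variance of that parameter's true masked values —
    standardizing before pooling so high-magnitude parameters (TDS)
    cannot drown out low-magnitude ones (fluoride) — and the pooled mean
    of the standardized squared errors is rooted.  For one parameter this
    reduces to sqrt(MSE / var(true)).

    Raises ``ValueError`` when the mask is empty or a parameter's true
    masked values have zero variance (the ratio is undefined).
    """
    parameters = list(parameters) if parameters is not None else [
        p for p in INDEX_PARAMETERS if p in true_table.columns and p in mask.columns
    ]
    sq: list[np.ndarray] = []
    any_masked = False
    for p in parameters:
        m = mask[p].to_numpy(dtype=bool)
        if not m.any():
            continue
        any_masked = True
        t = true_table[p].to_numpy(dtype=float)[m]
        i = imputed_table[p].to_numpy(dtype=float)[m]
        var = t.var()  # population variance, matching the error normalization
        if var == 0:
            raise ValueError(f"zero variance of true masked {p} values; NRMSE undefined")
        sq.append((t - i) ** 2 / var)
    if not any_masked:
        raise ValueError("mask marks no missing cells")
    return float(np.sqrt(np.concatenate(sq).mean()))
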