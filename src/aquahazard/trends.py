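"""Monitoring-station time-series analysis for surface-water parameters.

River water quality (e.g. chemical oxygen demand along a monitored
river) is sampled fortnightly to monthly at fixed stations.  Analysis
runs at monthly cadence: raw observations are averaged per calendar
month (months without data stay missing, never zero), per-station
linear trends are reported in units per year, a 12-month climatology
summarizes seasonality, and the station x month matrix — rows ordered
by descending station mean, the heatmap convention — lines the stations
up for display.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "StationSeries",
    "TrendFit",
    "to_monthly",
    "linear_trend",
    "seasonal_climatology",
    "station_matrix",
]


@dataclass
class StationSeries:
    """One station's record of one parameter.

    ``observations`` maps timestamps to values; construct from a tidy
    frame with :meth:`from_frame`.  ``unit`` is carried as metadata and
    echoed in outputs.
    """

    station_id: str
    parameter: str
    observations: pd.Series
    unit: str = "mg/L"
    monthly: bool = field(default=False)

    def __post_init__(self) -> None:
        obs = self.observations
        if len(obs) == 0:
            raise ValueError(f"station {self.station_id}: empty series")
        obs = obs.sort_index()
        if not isinstance(obs.index, pd.PeriodIndex):
            obs.index = pd.DatetimeIndex(obs.index)
        self.observations = obs

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, station_id: str, parameter: str,
                   unit: str = "mg/L") -> "StationSeries":
        sub = frame[(frame["station"] == station_id) & (frame["parameter"] == parameter)]
        obs = pd.Series(sub["value"].to_numpy(), index=pd.to_datetime(sub["date"]))
        return cls(station_id=station_id, parameter=parameter, observations=obs, unit=unit)


@dataclass(frozen=True)
class TrendFit:
    slope_per_year: float
    intercept: float
    stderr: float
    n_months: int


def to_monthly(series: StationSeries) -> StationSeries:
    """Calendar-month means; months with no observation are absent (they
    reappear as gaps in the station matrix).  Idempotent."""
    if series.monthly:
        return series
    obs = series.observations
    monthly = obs.groupby(obs.index.to_period("M")).mean()
    return StationSeries(
        station_id=series.station_id,
        parameter=series.parameter,
        observations=monthly,
        unit=series.unit,
        monthly=True,
    )


def _decimal_years(index: pd.PeriodIndex) -> np.ndarray:
    # mid-month decimal time so slopes come out per calendar year
    return index.year + (index.month - 0.5) / 12.0


def linear_trend(series: StationSeries, robust: bool = False) -> TrendFit:
    """Linear trend of the monthly means in units per year.

    Ordinary least squares on decimal time by default; ``robust=True``
    switches to the Theil-Sen estimator.  Requires >= 24 monthly values
    (two years) — anything shorter cannot support a yearly trend.
    """
    m = to_monthly(series).observations.dropna()
    if len(m) < 24:
        raise ValueError(
            f"station {series.station_id}: {len(m)} monthly values < 24 required for a trend"
        )
    t = _decimal_years(m.index)
    y = m.to_numpy(dtype=float)
    if robust:
        slope, intercept, *_ = stats.theilslopes(y, t)
        stderr = float("nan")
    else:
        fit = sm.OLS(y, sm.add_constant(t)).fit()
        intercept, slope = fit.params
        stderr = float(fit.bse[1])
    return TrendFit(
        slope_per_year=float(slope), intercept=float(intercept),
        stderr=stderr, n_months=len(m),
    )


def seasonal_climatology(series: StationSeries) -> pd.Series:
    """Mean per calendar month across years (missing-aware); indexed
    1..12, with NaN for calendar months never observed."""
    m = to_monthly(series).observations.dropna()
    if len(m) < 12:
        raise ValueError(f"station {series.station_id}: need >= 12 monthly values")
    clim = m.groupby(m.index.month).mean()
    return clim.reindex(range(1, 13))


def station_matrix(series_set: list[StationSeries]) -> pd.DataFrame:
    """Station x month matrix with rows sorted by descending station
    mean (ties broken lexicographically by station id); columns span the
    union of the stations' monthly ranges, gaps preserved as NaN."""
    if len(series_set) < 2:
        raise ValueError("need at least 2 stations")
    params = {s.parameter for s in series_set}
    if len(params) > 1:
        raise ValueError(f"mixed parameters in one matrix: {sorted(params)}")
    monthly = {s.station_id: to_monthly(s).observations for s in series_set}
    lo = min(m.index.min() for m in monthly.values())
    hi = max(m.index.max() for m in monthly.values())
    cols = pd.period_range(lo, hi, freq="M")
    rows = {sid: m.reindex(cols) for sid, m in monthly.items()}
    out = pd.DataFrame(rows).T
    means = out.mean(axis=1)
    order = sorted(out.index, key=lambda sid: (-means[sid], sid))
    return out.loc[order]
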