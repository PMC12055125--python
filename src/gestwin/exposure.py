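"""Weekly exposure assignment by inverse-distance-squared interpolation.

Station weekly pollutant series are interpolated to each residence with the
standard air-quality assignment rules: if any monitoring station lies within
5 km of the residence, only stations within 5 km are used; otherwise the up
to four nearest stations within 50 km contribute; weights are inverse
squared great-circle distance. Weekly values are laid out on a unified week
axis (weeks 1-13 = the 13 complete preconception weeks, week 14 = pregnancy
week 1, ...), and period averages (preconception, pregnancy, trimesters) are
computed as arithmetic means of weekly values, reported only when at most
10% of the period's weeks are missing.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import N_LAG_WEEKS, PRECONCEPTION_WEEKS

EARTH_RADIUS_KM = 6371.0088
#: Distances below this floor (km) are clamped before inverse-square
#: weighting, so a collocated station dominates without dividing by zero.
MIN_DISTANCE_KM = 0.001
NEAR_RADIUS_KM = 5.0
MAX_RADIUS_KM = 50.0
MAX_STATIONS = 4
MISSING_FRACTION_LIMIT = 0.10

PERIODS = ("preconception", "pregnancy", "trimester1", "trimester2", "trimester3")


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km between points in decimal degrees."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))


def select_stations(residence: tuple[float, float], stations: pd.DataFrame,
                    max_n: int = MAX_STATIONS) -> pd.DataFrame:
    """Choose the stations eligible to interpolate at a residence.

    If one or more stations lie within 5 km, all (and only) those are used;
    otherwise the ``max_n`` nearest stations within 50 km; otherwise none.
    Returns the station rows with a ``distance_km`` column, sorted by
    distance with ties broken by station_id.
    """
    lon, lat = residence
    if not (-180.0 <= lon <= 180.0 and -90.0 <= lat <= 90.0):
        raise ValueError(f"invalid residence coordinates {residence}")
    st = stations.copy()
    st["distance_km"] = haversine_km(lon, lat, st["longitude"].to_numpy(),
                                     st["latitude"].to_numpy())
    st = st.sort_values(["distance_km", "station_id"], kind="mergesort")
    near = st[st["distance_km"] <= NEAR_RADIUS_KM]
    if len(near):
        return near.reset_index(drop=True)
    in_range = st[st["distance_km"] <= MAX_RADIUS_KM]
    return in_range.head(max_n).reset_index(drop=True)


def idw_interpolate(values: np.ndarray, distances_km: np.ndarray) -> float:
    """Inverse-distance-squared weighted mean; NaN for empty inputs."""
    values = np.asarray(values, dtype=float)
    distances_km = np.asarray(distances_km, dtype=float)
    if values.shape != distances_km.shape:
        raise ValueError("values and distances must have the same length")
    if values.size == 0:
        return float("nan")
    d = np.maximum(distances_km, MIN_DISTANCE_KM)
    w = 1.0 / (d * d)
    return float(np.sum(w * values) / np.sum(w))


def unified_axis(ga_weeks: float) -> np.ndarray:
    """Unified week indices for a pregnancy: 13 preconception weeks then
    pregnancy weeks 1..ceil(GA)."""
    if ga_weeks < 20:
        raise ValueError(f"implausible gestational age at birth: {ga_weeks}")
    return np.arange(1, PRECONCEPTION_WEEKS + math.ceil(ga_weeks) + 1)


def assign_weekly_exposures(participant: pd.Series, stations: pd.DataFrame,
                            weekly: pd.DataFrame, pollutant: str
                            ) -> pd.Series:
    """Interpolate one participant's weekly series on the unified axis.

    ``weekly`` is long format (station_id, pollutant, week_start_date,
    value). Unified week w covers the 7 days starting conception - 91 days
    + 7*(w-1); the station week containing that window's midpoint supplies
    the values. A station missing that week simply drops out of the
    interpolation; a week with no eligible station data is NaN.
    """
    ga = float(participant["ga_weeks"])
    axis = unified_axis(ga)
    conc = participant["conception_date"]
    if isinstance(conc, str):
        conc = dt.date.fromisoformat(conc)
    elif isinstance(conc, pd.Timestamp):
        conc = conc.date()

    sel = select_stations((participant["longitude"], participant["latitude"]),
                          stations)
    if len(sel) == 0:
        return pd.Series(np.nan, index=axis, name=pollutant)

    sub = weekly[(weekly["pollutant"] == pollutant)
                 & (weekly["station_id"].isin(sel["station_id"]))]
    wide = sub.pivot_table(index="week_start_date", columns="station_id",
                           values="value", aggfunc="first")
    wide = wide.reindex(columns=sel["station_id"])
    starts = [d.date() if isinstance(d, pd.Timestamp)
              else (dt.date.fromisoformat(d) if isinstance(d, str) else d)
              for d in wide.index]
    start_arr = np.array([(s - conc).days for s in starts])
    dists = sel["distance_km"].to_numpy()
    vals_matrix = wide.to_numpy(dtype=float)

    out = np.full(len(axis), np.nan)
    for k, w in enumerate(axis):
        mid_offset = -91 + 7 * (int(w) - 1) + 3
        hit = np.flatnonzero((start_arr <= mid_offset) & (mid_offset < start_arr + 7))
        if hit.size == 0:
            continue
        row = vals_matrix[hit[0]]
        ok = ~np.isnan(row)
        if ok.any():
            out[k] = idw_interpolate(row[ok], dists[ok])
    return pd.Series(out, index=axis, name=pollutant)


def assign_cohort_exposures(participants: pd.DataFrame, stations: pd.DataFrame,
                            weekly: pd.DataFrame, pollutant: str) -> pd.DataFrame:
    """Long-format weekly exposure table for a cohort."""
    rows = []
    for _, p in participants.iterrows():
        s = assign_weekly_exposures(p, stations, weekly, pollutant)
        rows.append(pd.DataFrame({
            "participant_id": p["participant_id"],
            "pollutant": pollutant,
            "unified_week": s.index,
            "value": s.to_numpy(),
        }))
    return pd.concat(rows, ignore_index=True)


def weekly_lag_matrix(exposures: pd.DataFrame, pollutant: str) -> pd.DataFrame:
    """Participant x 48 matrix of weekly exposures for distributed-lag
    models (unified weeks 1..48; later weeks are not part of the lag axis)."""
    sub = exposures[(exposures["pollutant"] == pollutant)
                    & (exposures["unified_week"] <= N_LAG_WEEKS)]
    wide = sub.pivot_table(index="participant_id", columns="unified_week",
                           values="value", aggfunc="first")
    return wide.reindex(columns=np.arange(1, N_LAG_WEEKS + 1))


def period_weeks(period: str, ga_weeks: float) -> np.ndarray:
    """Unified-week set belonging to an exposure period.

    Trimesters follow the day bounds 1-90 / 91-180 / 181-birth; pregnancy
    week w covers days 7(w-1)+1..7w and a trimester owns the weeks whose
    majority of days fall in its range (boundary weeks 13 and 26 belong to
    trimesters 1 and 2).
    """
    last = PRECONCEPTION_WEEKS + math.ceil(ga_weeks)
    if period == "preconception":
        return np.arange(1, PRECONCEPTION_WEEKS + 1)
    if period == "pregnancy":
        return np.arange(PRECONCEPTION_WEEKS + 1, last + 1)
    if period == "trimester1":
        return np.arange(PRECONCEPTION_WEEKS + 1, PRECONCEPTION_WEEKS + 14)
    if period == "trimester2":
        return np.arange(PRECONCEPTION_WEEKS + 14, PRECONCEPTION_WEEKS + 27)
    if period == "trimester3":
        return np.arange(PRECONCEPTION_WEEKS + 27, last + 1)
    raise ValueError(f"unknown period {period!r}; expected one of {PERIODS}")


@dataclass
class PeriodAverage:
    participant_id: str
    pollutant: str
    period: str
    mean: float             # NaN when the missingness rule is violated
    missing_fraction: float
    n_weeks: int


def compute_period_average(series: pd.Series, period: str, ga_weeks: float,
                           participant_id: str = "", pollutant: str = ""
                           ) -> PeriodAverage:
    """Arithmetic mean of a period's weekly values under the 10% rule.

    The mean is reported iff the fraction of missing weeks in the period is
    <= 0.10 (strictly more than 10% missing invalidates the period); it is
    then the mean over the non-missing weeks.
    """
    weeks = period_weeks(period, ga_weeks)
    vals = series.reindex(weeks).to_numpy(dtype=float)
    n_missing = int(np.isnan(vals).sum())
    frac = n_missing / len(weeks)
    mean = float(np.nanmean(vals)) if (frac <= MISSING_FRACTION_LIMIT
                                       and n_missing < len(weeks)) else float("nan")
    return PeriodAverage(participant_id, pollutant, period, mean, frac, len(weeks))


def cohort_period_averages(exposures: pd.DataFrame, participants: pd.DataFrame,
                           periods: tuple[str, ...] = PERIODS) -> pd.DataFrame:
    """Period-average table for a cohort from long-format weekly exposures."""
    ga = participants.set_index("participant_id")["ga_weeks"]
    rows = []
    for (pid, pol), grp in exposures.groupby(["participant_id", "pollutant"]):
        series = grp.set_index("unified_week")["value"]
        for period in periods:
            pa = compute_period_average(series, period, float(ga[pid]), pid, pol)
            rows.append(vars(pa))
    return pd.DataFrame(rows)
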