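"""Time-integrated weighted mean foraging locations.

Each individual's plasma value integrates roughly the week of prey before
blood sampling, so its spatial sample unit is a single location: foraging-
labelled fixes from trips inside the 7-day window are gridded, each cell
weighted by the share of foraging time spent in it, and the weighted mean
of the occupied cell centres is the individual's mean foraging location.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, NoForagingError, UnsupportedExtentError
from .geo import KM_PER_DEGREE, haversine_km
from .grids import GridSpec
from .tracks import Trip

log = logging.getLogger(__name__)

__all__ = ["GridSpec", "grid_cell_size", "select_trips_within_window",
           "time_spent_per_cell", "weighted_mean_location",
           "mean_foraging_location"]


def grid_cell_size(trips: list[Trip], horizon_h: float = 2.0) -> float:
    """Cell size as the mean 2-hour along-track distance, rounded up to 0.05 deg.

    Each trip is cut into consecutive complete ``horizon_h`` windows; the
    along-track (summed segment) distance per window is averaged over all
    windows of all trips, converted at 111.19 km/degree and rounded *up* to
    the next multiple of 0.05 degrees (an exact multiple stays itself).
    """
    dists = []
    for trip in trips:
        t = trip.times_s
        lon = trip.df["lon"].to_numpy(float)
        lat = trip.df["lat"].to_numpy(float)
        if t[-1] - t[0] < horizon_h * 3600.0:
            continue
        seg = np.atleast_1d(haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:]))
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        start = t[0]
        while start + horizon_h * 3600.0 <= t[-1] + 1e-6:
            end = start + horizon_h * 3600.0
            d0 = np.interp(start, t, cum)
            d1 = np.interp(end, t, cum)
            dists.append(d1 - d0)
            start = end
    if not dists:
        raise InsufficientDataError("no trip spans the 2-h horizon")
    deg = float(np.mean(dists)) / KM_PER_DEGREE
    return float(np.ceil(deg / 0.05 - 1e-9) * 0.05)


def select_trips_within_window(trips: list[Trip], blood_time,
                               window_days: float = 7.0) -> list[Trip]:
    """Trips whose final fix lies within the window before blood sampling.

    Trips straddling the window start are trimmed to it rather than
    excluded; fixes after the blood time are dropped. An empty selection is
    returned as an empty list (the caller drops the individual, logged).
    """
    blood_time = pd.Timestamp(blood_time)
    start = blood_time - pd.Timedelta(days=window_days)
    out = []
    for trip in trips:
        t = trip.df["time"]
        if t.iloc[-1] < start or t.iloc[-1] > blood_time:
            continue
        body = trip.df[(t >= start) & (t <= blood_time)]
        if len(body) >= 1:
            out.append(trip.with_df(body))
    if not out and trips:
        log.info("%s: no trips within %g d of blood sampling",
                 trips[0].individual_id, window_days)
    return out


def time_spent_per_cell(trips: list[Trip], grid: GridSpec,
                        foraging_only: bool = True) -> dict:
    """Normalised share of (foraging) time per grid cell.

    Each retained fix contributes its nominal sampling interval to its
    containing half-open cell; weights are normalised to sum to one.
    """
    acc: dict[tuple, float] = {}
    total = 0.0
    for trip in trips:
        df = trip.df
        if foraging_only:
            if "foraging" not in df.columns:
                raise NoForagingError(
                    f"{trip.individual_id}: fixes carry no foraging labels")
            df = df[df["foraging"].astype(bool)]
        if len(df) == 0:
            continue
        ix, iy = grid.cell_of(df["lon"].to_numpy(float), df["lat"].to_numpy(float))
        for i, j in zip(np.atleast_1d(ix), np.atleast_1d(iy)):
            acc[(int(i), int(j))] = acc.get((int(i), int(j)), 0.0) + trip.interval_s
            total += trip.interval_s
    if total == 0.0:
        raise NoForagingError("no foraging fixes in window")
    return {cell: w / total for cell, w in acc.items()}


def weighted_mean_location(weights: dict, grid: GridSpec) -> tuple[float, float]:
    """Arithmetic mean of cell-centre coordinates weighted by time share."""
    if grid.west < 180.0 < grid.east:
        raise UnsupportedExtentError("antimeridian-spanning grids unsupported")
    wsum = sum(weights.values())
    if abs(wsum - 1.0) > 1e-9:
        raise ValueError(f"weights sum to {wsum}, expected 1")
    lon = lat = 0.0
    for (ix, iy), w in weights.items():
        clon, clat = grid.center_of(ix, iy)
        lon += w * clon
        lat += w * clat
    return float(lon), float(lat)


def mean_foraging_location(trips: list[Trip], blood_time, grid: GridSpec,
                           window_days: float = 7.0) -> dict:
    """One individual's weighted mean foraging location and bookkeeping.

    Returns a dict with ``lon``, ``lat``, ``n_trips`` and the per-cell
    ``weights`` used (for audit); raises :class:`NoForagingError` if the
    individual has no foraging fixes within the window.
    """
    within = select_trips_within_window(trips, blood_time, window_days)
    if not within:
        raise NoForagingError("no trips within the sampling window")
    weights = time_spent_per_cell(within, grid, foraging_only=True)
    lon, lat = weighted_mean_location(weights, grid)
    return {"lon": lon, "lat": lat, "n_trips": len(within), "weights": weights}
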