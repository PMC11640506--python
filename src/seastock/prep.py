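"""Nominal CPUE on the analysis grid and the season labelling.

Nominal CPUE in a grid cell-month is total catch divided by total fishing
days over every record that fell in the cell, in kg per vessel per day.
Season labels follow the fishery's calendar: spring (March-May), summer
(June-August), autumn (September-November); months outside March-November
are outside the study window and rejected.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SEASON_OF_MONTH = {
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
}

GRIDDED_COLUMNS = [
    "cell_lon", "cell_lat", "year", "month", "season",
    "total_catch_kg", "total_effort_days", "cpue",
]


def assign_season(month: int) -> str:
    """Season label for a month inside the March-November study window."""
    try:
        return SEASON_OF_MONTH[int(month)]
    except (KeyError, ValueError):
        raise ValueError(
            f"month {month!r} outside the study window (3-11)"
        ) from None


def _cell_center(coord: np.ndarray, origin: float, cell_deg: float) -> np.ndarray:
    # half-open cells [edge, edge + cell_deg): each point maps to one cell
    idx = np.floor((coord - origin) / cell_deg)
    return origin + (idx + 0.5) * cell_deg


def nominal_cpue(
    records: pd.DataFrame,
    cell_size_deg: float,
    lon_origin: float | None = None,
    lat_origin: float | None = None,
) -> pd.DataFrame:
    """Grid records into cell-month nominal CPUE rows.

    Cell edges are anchored at ``lon_origin``/``lat_origin`` (defaults: the
    floor of the observed minimum, so cells align with whole-degree edges
    scaled by the cell size).  Only occupied cell-months are emitted.
    """
    if records.empty:
        raise ValueError("no records to grid")
    if cell_size_deg <= 0:
        raise ValueError("cell_size_deg must be positive")
    lon = records["lon"].to_numpy(dtype=float)
    lat = records["lat"].to_numpy(dtype=float)
    if lon_origin is None:
        lon_origin = np.floor(lon.min() / cell_size_deg) * cell_size_deg
    if lat_origin is None:
        lat_origin = np.floor(lat.min() / cell_size_deg) * cell_size_deg

    df = pd.DataFrame(
        {
            "cell_lon": _cell_center(lon, lon_origin, cell_size_deg),
            "cell_lat": _cell_center(lat, lat_origin, cell_size_deg),
            "year": records["year"].to_numpy(),
            "month": records["month"].to_numpy(),
            "catch": records["catch_kg"].to_numpy(dtype=float),
            "effort": records["effort_days"].to_numpy(dtype=float),
        }
    )
    out = (
        df.groupby(["cell_lon", "cell_lat", "year", "month"], as_index=False)
        .agg(total_catch_kg=("catch", "sum"), total_effort_days=("effort", "sum"))
        .sort_values(["year", "month", "cell_lat", "cell_lon"])
        .reset_index(drop=True)
    )
    out["season"] = out["month"].map(assign_season)
    out["cpue"] = out["total_catch_kg"] / out["total_effort_days"]
    return out[GRIDDED_COLUMNS]
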