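"""Geometry helpers and the knot mesh used by the spatio-temporal model.

All distances are desk-scale planar approximations: longitude/latitude are
projected to km with a local equirectangular scaling (111.32 km per degree
of latitude, scaled by cos of a reference latitude for longitude).  At the
scale of a regional fishing ground the error relative to great-circle
distances is far below the decorrelation range of the fields, so nothing
downstream is sensitive to the projection choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

KM_PER_DEG = 111.32


def lonlat_to_km(
    lon: np.ndarray,
    lat: np.ndarray,
    origin: tuple[float, float],
    ref_lat: float,
) -> np.ndarray:
    """Project lon/lat (degrees) to planar (easting, northing) km.

    Parameters
    ----------
    origin : (lon0, lat0) mapped to (0, 0).
    ref_lat : latitude whose cosine scales the east-west axis.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    x = (lon - origin[0]) * KM_PER_DEG * np.cos(np.deg2rad(ref_lat))
    y = (lat - origin[1]) * KM_PER_DEG
    return np.column_stack([x, y])


def cell_area_km2(lat: np.ndarray, cell_deg: float) -> np.ndarray:
    """Area of a cell_deg x cell_deg cell centred at latitude ``lat``."""
    lat = np.asarray(lat, dtype=float)
    return (KM_PER_DEG * cell_deg) ** 2 * np.cos(np.deg2rad(lat))


def exponential_correlation(dist_km: np.ndarray, range_km: float) -> np.ndarray:
    """Exponential (Matern nu=1/2) correlation, exp(-d / range)."""
    if range_km <= 0:
        raise ValueError("range_km must be positive")
    return np.exp(-np.asarray(dist_km, dtype=float) / range_km)


def make_grid(
    lon_min: float,
    lon_max: float,
    lat_min: float,
    lat_max: float,
    cell_deg: float,
) -> pd.DataFrame:
    """Cell-centre grid covering the box, with per-cell areas in km^2."""
    n_lon = int(round((lon_max - lon_min) / cell_deg))
    n_lat = int(round((lat_max - lat_min) / cell_deg))
    if n_lon < 1 or n_lat < 1:
        raise ValueError("bounding box smaller than one cell")
    lons = lon_min + cell_deg * (np.arange(n_lon) + 0.5)
    lats = lat_min + cell_deg * (np.arange(n_lat) + 0.5)
    gg_lon, gg_lat = np.meshgrid(lons, lats)
    lon = gg_lon.ravel()
    lat = gg_lat.ravel()
    return pd.DataFrame(
        {"lon": lon, "lat": lat, "area_km2": cell_area_km2(lat, cell_deg)}
    )


@dataclass
class KnotMesh:
    """Reduced-rank spatial support: knots plus per-knot representative area.

    Every observation and every extrapolation-grid cell is attached to its
    nearest knot; ``area_km2[s]`` is the summed area of the extrapolation
    cells assigned to knot ``s``, so that summing fields over knots weighted
    by area integrates them over the extrapolation region.
    """

    knots_lonlat: np.ndarray  # (k, 2)
    knots_km: np.ndarray  # (k, 2)
    area_km2: np.ndarray  # (k,)
    origin: tuple[float, float]
    ref_lat: float
    total_area_km2: float = field(init=False)

    def __post_init__(self) -> None:
        self.knots_lonlat = np.asarray(self.knots_lonlat, dtype=float)
        self.knots_km = np.asarray(self.knots_km, dtype=float)
        self.area_km2 = np.asarray(self.area_km2, dtype=float)
        self.total_area_km2 = float(self.area_km2.sum())

    @property
    def n_knots(self) -> int:
        return self.knots_km.shape[0]

    def to_km(self, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
        return lonlat_to_km(lon, lat, self.origin, self.ref_lat)

    def assign(self, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
        """Index of the nearest knot for each lon/lat point."""
        pts = self.to_km(np.atleast_1d(lon), np.atleast_1d(lat))
        d = cdist(pts, self.knots_km)
        return np.argmin(d, axis=1)

    def knot_distances(self) -> np.ndarray:
        return cdist(self.knots_km, self.knots_km)


def build_knot_mesh(
    obs_lon: np.ndarray,
    obs_lat: np.ndarray,
    extrap_grid: pd.DataFrame,
    n_knots: int,
    seed: int = 0,
) -> KnotMesh:
    """Place knots by k-means over observed locations and attach areas.

    Parameters
    ----------
    extrap_grid : frame with columns lon, lat, area_km2 describing the
        region over which the abundance index is integrated.
    """
    obs_lon = np.asarray(obs_lon, dtype=float)
    obs_lat = np.asarray(obs_lat, dtype=float)
    pts = np.column_stack([obs_lon, obs_lat])
    n_distinct = np.unique(pts, axis=0).shape[0]
    if n_knots > n_distinct:
        raise ValueError(
            f"n_knots={n_knots} exceeds the {n_distinct} distinct observed locations"
        )
    origin = (float(obs_lon.mean()), float(obs_lat.mean()))
    ref_lat = origin[1]
    km = lonlat_to_km(obs_lon, obs_lat, origin, ref_lat)
    if n_knots == n_distinct:
        centers = np.unique(km, axis=0)
    else:
        km_fit = KMeans(n_clusters=n_knots, n_init=4, random_state=seed).fit(km)
        centers = km_fit.cluster_centers_
    # stable ordering regardless of k-means label permutation
    order = np.lexsort((centers[:, 0], centers[:, 1]))
    centers = centers[order]
    lon0, lat0 = origin
    knots_lonlat = np.column_stack(
        [
            lon0 + centers[:, 0] / (KM_PER_DEG * np.cos(np.deg2rad(ref_lat))),
            lat0 + centers[:, 1] / KM_PER_DEG,
        ]
    )
    mesh = KnotMesh(
        knots_lonlat=knots_lonlat,
        knots_km=centers,
        area_km2=np.zeros(len(centers)),
        origin=origin,
        ref_lat=ref_lat,
    )
    if extrap_grid.empty or extrap_grid["area_km2"].sum() <= 0:
        raise ValueError("extrapolation region has zero area")
    cell_knot = mesh.assign(extrap_grid["lon"].to_numpy(), extrap_grid["lat"].to_numpy())
    areas = np.bincount(
        cell_knot, weights=extrap_grid["area_km2"].to_numpy(), minlength=len(centers)
    )
    mesh.area_km2 = areas
    mesh.total_area_km2 = float(areas.sum())
    return mesh
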