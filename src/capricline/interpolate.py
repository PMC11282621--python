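"""Inverse-distance-weighted interpolation surfaces of diversity statistics.

Each grid cell takes the distance-weighted average of the breed values,
with weights d^(-power) on great-circle distances between the cell centre
and the sampling sites; a cell that coincides with a sampling site takes
that site's value exactly.  Being a convex combination, the surface is
bounded by the data range everywhere.  Surfaces are classed into k equal-
width intervals for display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "GridSpec",
    "GridSurface",
    "great_circle_km",
    "idw_interpolate",
    "classify_equal_intervals",
    "surface_from_fixture",
]

_EARTH_RADIUS_KM = 6371.0088  # mean earth radius
_EXACT_HIT_EPS_DEG = 1e-9


@dataclass(frozen=True)
class GridSpec:
    """A rectangular lon/lat grid of cell centres."""

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    n_cols: int
    n_rows: int

    def __post_init__(self) -> None:
        if self.lon_min >= self.lon_max or self.lat_min >= self.lat_max:
            raise ValueError("empty grid extent")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid needs at least one cell")

    def centres(self) -> tuple[np.ndarray, np.ndarray]:
        """Cell-centre coordinate vectors (lons ascending, lats ascending)."""
        lons = np.linspace(self.lon_min, self.lon_max, self.n_cols)
        lats = np.linspace(self.lat_min, self.lat_max, self.n_rows)
        return lons, lats

    @classmethod
    def covering(
        cls, lons: Sequence[float], lats: Sequence[float],
        cell_deg: float = 1.0, pad_deg: float = 2.0,
    ) -> "GridSpec":
        lon_min, lon_max = min(lons) - pad_deg, max(lons) + pad_deg
        lat_min, lat_max = min(lats) - pad_deg, max(lats) + pad_deg
        n_cols = max(2, int(round((lon_max - lon_min) / cell_deg)) + 1)
        n_rows = max(2, int(round((lat_max - lat_min) / cell_deg)) + 1)
        return cls(lon_min, lon_max, lat_min, lat_max, n_cols, n_rows)


@dataclass
class GridSurface:
    """An interpolated statistic on a grid, with equal-interval classes.

    ``values[i, j]`` is the cell at the i-th latitude (ascending, south to
    north) and j-th longitude.  ``class_index`` holds integers 1..k once
    :func:`classify_equal_intervals` has run.
    """

    spec: GridSpec
    values: np.ndarray
    power: float = 2.0
    k: int = 10
    class_index: np.ndarray | None = None

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        """(row, col) of the grid cell whose centre is nearest a point."""
        lons, lats = self.spec.centres()
        return int(np.argmin(np.abs(lats - lat))), int(np.argmin(np.abs(lons - lon)))


def great_circle_km(
    lon1: np.ndarray, lat1: np.ndarray, lon2: np.ndarray, lat2: np.ndarray
) -> np.ndarray:
    """Haversine great-circle distance in km (broadcasting)."""
    lam1, phi1, lam2, phi2 = map(np.radians, (lon1, lat1, lon2, lat2))
    d = (
        np.sin((phi2 - phi1) / 2.0) ** 2
        + np.cos(phi1) * np.cos(phi2) * np.sin((lam2 - lam1) / 2.0) ** 2
    )
    return 2.0 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(d, 0.0, 1.0)))


def idw_interpolate(
    points: Sequence[tuple[float, float, float]],
    grid: GridSpec,
    power: float = 2.0,
) -> GridSurface:
    """Inverse-distance-weighted surface of scattered (lon, lat, value) data.

    All data points contribute to every cell (no search radius), with
    weights d^(-power) on great-circle distance.  A cell centre within
    1e-9 degrees of a data point takes that point's value exactly.
    """
    if power <= 0:
        raise ValueError("power must be > 0")
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValueError("no data points")
    plon, plat, pval = pts[:, 0], pts[:, 1], pts[:, 2]
    lons, lats = grid.centres()
    glon, glat = np.meshgrid(lons, lats)  # (n_rows, n_cols)

    d = great_circle_km(
        glon[..., None], glat[..., None], plon[None, None, :], plat[None, None, :]
    )
    exact = (np.abs(glon[..., None] - plon) < _EXACT_HIT_EPS_DEG) & (
        np.abs(glat[..., None] - plat) < _EXACT_HIT_EPS_DEG
    )
    with np.errstate(divide="ignore"):
        w = d ** (-power)
    values = np.empty(glon.shape)
    hit_any = exact.any(axis=-1)
    # exact hits: take the (first) coincident point's value
    hit_idx = exact.argmax(axis=-1)
    values[hit_any] = pval[hit_idx[hit_any]]
    # d == 0 without a coordinate match (antipodal wrap; degenerate) -> inf
    # weight dominates, which is the sensible limit
    w_finite = np.where(np.isfinite(w), w, 0.0)
    denom = w_finite.sum(axis=-1)
    num = (w_finite * pval).sum(axis=-1)
    free = ~hit_any & (denom > 0)
    values[free] = num[free] / denom[free]
    values[~hit_any & (denom == 0)] = np.nan
    return GridSurface(spec=grid, values=values, power=power)


def classify_equal_intervals(surface: GridSurface, k: int = 10) -> np.ndarray:
    """Split the surface's value range into k equal classes (1..k).

    Classes are half-open [lo, lo + w) except the last, which is closed so
    the global maximum lands in class k.  A constant surface has zero range
    and raises.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    v = surface.values
    finite = np.isfinite(v)
    vmin, vmax = v[finite].min(), v[finite].max()
    if vmax <= vmin:
        raise ValueError("zero range: constant surface cannot be classed")
    width = (vmax - vmin) / k
    idx = np.floor((v - vmin) / width).astype(int) + 1
    idx = np.clip(idx, 1, k)  # global max -> class k
    idx = np.where(finite, idx, 0)
    surface.class_index = idx
    surface.k = k
    return idx


def surface_from_fixture(
    continent: str,
    statistic: str,
    cell_deg: float = 1.0,
    power: float = 2.0,
    k: int = 10,
    pad_deg: float = 2.0,
) -> GridSurface:
    """IDW surface of ho, he or fis over a packaged continental breed set."""
    from .fixtures import load_fixture_tables

    if statistic not in ("ho", "he", "fis"):
        raise ValueError(f"statistic must be ho, he or fis, not {statistic!r}")
    tables = load_fixture_tables()
    if continent not in tables:
        raise KeyError(f"unknown continent {continent!r}")
    breeds, diversity = tables[continent]
    merged = breeds.merge(diversity[["breed_id", statistic]], on="breed_id")
    pts = list(zip(merged["lon"], merged["lat"], merged[statistic]))
    grid = GridSpec.covering(merged["lon"], merged["lat"], cell_deg, pad_deg)
    surf = idw_interpolate(pts, grid, power=power)
    classify_equal_intervals(surf, k)
    return surf
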