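"""Inverse-squared-distance downscaling of gridded surfaces to block groups.

Each block group is assigned its four nearest grid centroids (geodesic
distance), whose daily values are combined with weights proportional to
1/d². Standard errors propagate under an independence assumption:
delta² = Σ w_i² σ_i².
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import CalendarError, GridshedError
from .geodesy import GeoPoint, vincenty_km

__all__ = [
    "GridSeries",
    "NeighborSet",
    "BGEstimateSeries",
    "find_nearest_grids",
    "compute_weights",
    "estimate_bg_day",
    "estimate_bg_day_se",
    "downscale_all",
]

logger = logging.getLogger(__name__)

_EARTH_RADIUS_KM = 6371.0


@dataclass
class GridSeries:
    """Daily concentration and standard-error series for one grid cell."""

    cell_id: str
    centroid: GeoPoint
    values: dict[str, float]  # ISO date -> concentration
    ses: dict[str, float]  # ISO date -> standard error
    resolution_km: int | None = None

    def __post_init__(self) -> None:
        missing = set(self.values) - set(self.ses)
        if missing:
            raise ValueError(
                f"cell {self.cell_id}: dates missing standard errors: {sorted(missing)[:5]}"
            )
        bad_se = [d for d, s in self.ses.items() if s < 0]
        if bad_se:
            raise ValueError(f"cell {self.cell_id}: negative standard errors on {bad_se[:5]}")

    def dates(self) -> list[str]:
        return sorted(self.values)


@dataclass
class NeighborSet:
    """The four nearest grid cells of a block group with their IDW weights."""

    bg_geoid: str
    neighbors: list[tuple[str, float]]  # (cell_id, distance_km), sorted
    weights: np.ndarray

    def __post_init__(self) -> None:
        if len(self.neighbors) != len(self.weights):
            raise ValueError("neighbors and weights length mismatch")
        dists = [d for _, d in self.neighbors]
        if any(d < 0 for d in dists):
            raise ValueError("negative neighbor distance")
        if dists != sorted(dists):
            raise ValueError("neighbors not sorted by distance")
        if abs(float(np.sum(self.weights)) - 1.0) > 1e-12:
            raise ValueError("weights do not sum to 1")


@dataclass
class BGEstimateSeries:
    """Daily concentration estimate (mu) and standard error (delta) per BG."""

    bg_geoid: str
    estimates: dict[str, tuple[float, float]] = field(default_factory=dict)

    def dates(self) -> list[str]:
        return sorted(self.estimates)


def _check_calendar(cells: Sequence[GridSeries]) -> list[str]:
    """All cells must share one contiguous daily calendar; return its dates."""
    if not cells:
        raise GridshedError("empty grid")
    ref = cells[0].dates()
    for c in cells[1:]:
        if c.dates() != ref:
            raise CalendarError(
                f"cell {c.cell_id} calendar differs from cell {cells[0].cell_id}"
            )
    if ref:
        expected = pd.date_range(ref[0], ref[-1], freq="D").strftime("%Y-%m-%d").tolist()
        if ref != expected:
            missing = sorted(set(expected) - set(ref))
            raise CalendarError(f"grid calendar has gaps; first missing dates: {missing[:5]}")
    return ref


def _latlon_to_ecef(lats: np.ndarray, lons: np.ndarray) -> np.ndarray:
    """Unit-sphere 3-D embedding used only to pre-select neighbor candidates."""
    lat_r = np.radians(lats)
    lon_r = np.radians(lons)
    return np.column_stack(
        [
            np.cos(lat_r) * np.cos(lon_r),
            np.cos(lat_r) * np.sin(lon_r),
            np.sin(lat_r),
        ]
    ) * _EARTH_RADIUS_KM


class NeighborFinder:
    """k-nearest grid-centroid lookup by geodesic distance.

    A KD-tree on a spherical embedding pre-selects candidates; the final
    ranking always uses the ellipsoidal Vincenty distance, so results are
    identical to brute force (a candidate buffer absorbs the ~0.3%
    sphere-vs-ellipsoid ordering discrepancy).
    """

    def __init__(self, cells: Sequence[GridSeries]):
        self.cells = list(cells)
        self.cell_ids = [c.cell_id for c in self.cells]
        self.lats = np.array([c.centroid.lat for c in self.cells])
        self.lons = np.array([c.centroid.lon for c in self.cells])
        self._tree = cKDTree(_latlon_to_ecef(self.lats, self.lons))

    def query(self, point: GeoPoint, k: int = 4) -> list[tuple[str, float]]:
        n = len(self.cells)
        if n < k:
            raise GridshedError(f"grid has only {n} cells; {k} neighbors requested")
        n_cand = min(n, max(4 * k, 16))
        _, idx = self._tree.query(_latlon_to_ecef(np.array([point.lat]), np.array([point.lon]))[0], k=n_cand)
        idx = np.atleast_1d(idx)
        dists = vincenty_km(point.lat, point.lon, self.lats[idx], self.lons[idx])
        order = sorted(range(len(idx)), key=lambda j: (dists[j], self.cell_ids[idx[j]]))
        return [(self.cell_ids[idx[j]], float(dists[j])) for j in order[:k]]


def find_nearest_grids(
    bg_centroid: GeoPoint,
    grid: Sequence[GridSeries],
    k: int = 4,
    method: str = "index",
) -> list[tuple[str, float]]:
    """Return the ``k`` nearest grid cells as ``(cell_id, distance_km)``.

    Ties on distance are broken by ascending ``cell_id`` so the result is
    deterministic. ``method`` is ``"index"`` (KD-tree pre-selection) or
    ``"brute"`` (all-pairs Vincenty); both give identical results.
    """
    if len(grid) < k:
        raise GridshedError(f"grid has only {len(grid)} cells; {k} neighbors requested")
    if method == "index":
        return NeighborFinder(grid).query(bg_centroid, k)
    if method == "brute":
        lats = np.array([c.centroid.lat for c in grid])
        lons = np.array([c.centroid.lon for c in grid])
        dists = vincenty_km(bg_centroid.lat, bg_centroid.lon, lats, lons)
        order = sorted(range(len(grid)), key=lambda j: (dists[j], grid[j].cell_id))
        return [(grid[j].cell_id, float(dists[j])) for j in order[:k]]
    raise ValueError(f"unknown method {method!r}")


def compute_weights(distances: Sequence[float]) -> np.ndarray:
    """Inverse-squared-distance weights w_i = (1/d_i²) / Σ (1/d_j²).

    Coincident centroids (d = 0) take the continuous limit of the formula:
    zero-distance entries split all weight equally, everything else gets 0.
    """
    d = np.asarray(distances, dtype=float)
    if np.any(d < 0):
        raise ValueError(f"negative distance in {list(distances)}")
    zero = d == 0.0
    if zero.all() and len(d) > 1:
        raise ValueError("all neighbor distances are zero: degenerate grid")
    if zero.any():
        w = np.zeros_like(d)
        w[zero] = 1.0 / zero.sum()
        return w
    inv_sq = 1.0 / d**2
    return inv_sq / inv_sq.sum()


def estimate_bg_day(weights: Sequence[float], values: Sequence[float]) -> float:
    """Weighted concentration estimate mu = Σ w_i P_i."""
    w = np.asarray(weights, dtype=float)
    p = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError(f"non-finite neighbor value in {list(values)}")
    return float(w @ p)


def estimate_bg_day_se(weights: Sequence[float], ses: Sequence[float]) -> float:
    """Propagated standard error delta = sqrt(Σ w_i² σ_i²)."""
    w = np.asarray(weights, dtype=float)
    s = np.asarray(ses, dtype=float)
    if np.any(s < 0):
        raise ValueError(f"negative standard error in {list(ses)}")
    return float(np.sqrt(np.sum(w**2 * s**2)))


def build_neighbor_set(bg_geoid: str, centroid: GeoPoint, finder: NeighborFinder, k: int = 4) -> NeighborSet:
    neighbors = finder.query(centroid, k)
    weights = compute_weights([d for _, d in neighbors])
    return NeighborSet(bg_geoid=bg_geoid, neighbors=neighbors, weights=weights)


def downscale_all(
    grid: Sequence[GridSeries],
    bgs: Iterable,  # BlockGroup records (geoid, centroid)
    k: int = 4,
) -> list[BGEstimateSeries]:
    """Estimate daily (mu, delta) for every block group.

    Neighbor sets are computed once per BG (grid geometry is static) and
    reused for all dates. A missing value for a neighbor on any date is a
    hard error naming cell and date.
    """
    cells = list(grid)
    dates = _check_calendar(cells)
    finder = NeighborFinder(cells)
    cell_index = {c.cell_id: i for i, c in enumerate(cells)}

    # (n_cells, n_days) value/se matrices for vectorized per-BG estimates
    values = np.empty((len(cells), len(dates)))
    ses = np.empty((len(cells), len(dates)))
    for i, c in enumerate(cells):
        for j, d in enumerate(dates):
            if d not in c.values:
                raise GridshedError(f"cell {c.cell_id} missing value on {d}")
            values[i, j] = c.values[d]
            ses[i, j] = c.ses[d]

    out: list[BGEstimateSeries] = []
    for bg in bgs:
        nset = build_neighbor_set(bg.geoid, bg.centroid, finder, k)
        idx = [cell_index[cid] for cid, _ in nset.neighbors]
        w = nset.weights
        mu = w @ values[idx]
        delta = np.sqrt((w**2) @ (ses[idx] ** 2))
        out.append(
            BGEstimateSeries(
                bg_geoid=bg.geoid,
                estimates={d: (float(mu[j]), float(delta[j])) for j, d in enumerate(dates)},
            )
        )
    logger.info("downscaled %d block groups over %d days", len(out), len(dates))
    return out
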