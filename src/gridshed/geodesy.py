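"""Geodetic distance on the WGS84 ellipsoid via the Vincenty inverse method.

Coordinates are decimal degrees; distances are kilometers. Only the inverse
problem (distance between two known points) is implemented — the direct
problem is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConvergenceError

__all__ = ["GeoPoint", "vincenty_distance", "vincenty_km", "WGS84_A_M", "WGS84_F"]

# WGS84 ellipsoid. The semi-major axis is in meters; distances are
# converted to km on return.
WGS84_A_M = 6378137.0
WGS84_F = 1.0 / 298.257223563
_B_M = WGS84_A_M * (1.0 - WGS84_F)

_CONVERGENCE_TOL_RAD = 1e-12
_MAX_ITERATIONS = 200


@dataclass(frozen=True)
class GeoPoint:
    """A latitude/longitude pair in decimal degrees.

    Raises ``ValueError`` for non-finite or out-of-range coordinates.
    """

    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lat) and math.isfinite(self.lon)):
            raise ValueError(f"coordinates must be finite, got ({self.lat}, {self.lon})")
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude {self.lon} outside [-180, 180]")


def vincenty_km(
    lat1: float,
    lon1: float,
    lats2: np.ndarray,
    lons2: np.ndarray,
) -> np.ndarray:
    """Vectorized Vincenty inverse distance from one point to many, in km.

    Iterates the longitude-difference equation until the update falls below
    1e-12 rad for every element, with a hard cap of 200 iterations.

    Raises
    ------
    ConvergenceError
        If any pair fails to converge within the iteration cap (this occurs
        only for nearly antipodal points, never at continental scales).
    """
    lats2 = np.asarray(lats2, dtype=float)
    lons2 = np.asarray(lons2, dtype=float)

    phi1 = math.radians(lat1)
    phi2 = np.radians(lats2)
    L = np.radians(lons2) - math.radians(lon1)

    U1 = math.atan((1.0 - WGS84_F) * math.tan(phi1))
    U2 = np.arctan((1.0 - WGS84_F) * np.tan(phi2))
    sinU1, cosU1 = math.sin(U1), math.cos(U1)
    sinU2, cosU2 = np.sin(U2), np.cos(U2)

    lam = L.copy()
    converged = np.zeros(lam.shape, dtype=bool)
    sin_sigma = np.zeros_like(lam)
    cos_sigma = np.ones_like(lam)
    sigma = np.zeros_like(lam)
    cos_sq_alpha = np.ones_like(lam)
    cos2sigma_m = np.zeros_like(lam)

    for _ in range(_MAX_ITERATIONS):
        sin_lam = np.sin(lam)
        cos_lam = np.cos(lam)
        sin_sigma = np.sqrt(
            (cosU2 * sin_lam) ** 2 + (cosU1 * sinU2 - sinU1 * cosU2 * cos_lam) ** 2
        )
        cos_sigma = sinU1 * sinU2 + cosU1 * cosU2 * cos_lam
        sigma = np.arctan2(sin_sigma, cos_sigma)

        coincident = sin_sigma == 0.0
        with np.errstate(divide="ignore", invalid="ignore"):
            sin_alpha = np.where(coincident, 0.0, cosU1 * cosU2 * sin_lam / sin_sigma)
        cos_sq_alpha = 1.0 - sin_alpha**2
        # cos2sigma_m is indeterminate on the equator (cos²α = 0); Vincenty's
        # prescription is to substitute 0 there.
        with np.errstate(divide="ignore", invalid="ignore"):
            cos2sigma_m = np.where(
                cos_sq_alpha == 0.0,
                0.0,
                cos_sigma - 2.0 * sinU1 * sinU2 / np.where(cos_sq_alpha == 0.0, 1.0, cos_sq_alpha),
            )

        C = WGS84_F / 16.0 * cos_sq_alpha * (4.0 + WGS84_F * (4.0 - 3.0 * cos_sq_alpha))
        lam_new = L + (1.0 - C) * WGS84_F * sin_alpha * (
            sigma
            + C * sin_sigma * (cos2sigma_m + C * cos_sigma * (-1.0 + 2.0 * cos2sigma_m**2))
        )
        newly = (np.abs(lam_new - lam) < _CONVERGENCE_TOL_RAD) | coincident
        # freeze converged elements so each pair's result is independent of
        # whatever else shares the batch
        lam = np.where(converged, lam, lam_new)
        converged |= newly
        if converged.all():
            break
    else:
        n_bad = int((~converged).sum())
        raise ConvergenceError(
            f"Vincenty inverse failed to converge for {n_bad} point pair(s) "
            f"after {_MAX_ITERATIONS} iterations (nearly antipodal input)"
        )

    # recompute the spherical quantities from the converged lambda so the
    # result is a pure function of the input pair
    sin_lam = np.sin(lam)
    cos_lam = np.cos(lam)
    sin_sigma = np.sqrt(
        (cosU2 * sin_lam) ** 2 + (cosU1 * sinU2 - sinU1 * cosU2 * cos_lam) ** 2
    )
    cos_sigma = sinU1 * sinU2 + cosU1 * cosU2 * cos_lam
    sigma = np.arctan2(sin_sigma, cos_sigma)
    with np.errstate(divide="ignore", invalid="ignore"):
        sin_alpha = np.where(sin_sigma == 0.0, 0.0, cosU1 * cosU2 * sin_lam / sin_sigma)
    cos_sq_alpha = 1.0 - sin_alpha**2
    with np.errstate(divide="ignore", invalid="ignore"):
        cos2sigma_m = np.where(
            cos_sq_alpha == 0.0,
            0.0,
            cos_sigma - 2.0 * sinU1 * sinU2 / np.where(cos_sq_alpha == 0.0, 1.0, cos_sq_alpha),
        )

    u_sq = cos_sq_alpha * (WGS84_A_M**2 - _B_M**2) / _B_M**2
    A = 1.0 + u_sq / 16384.0 * (4096.0 + u_sq * (-768.0 + u_sq * (320.0 - 175.0 * u_sq)))
    B = u_sq / 1024.0 * (256.0 + u_sq * (-128.0 + u_sq * (74.0 - 47.0 * u_sq)))
    delta_sigma = (
        B
        * sin_sigma
        * (
            cos2sigma_m
            + B
            / 4.0
            * (
                cos_sigma * (-1.0 + 2.0 * cos2sigma_m**2)
                - B
                / 6.0
                * cos2sigma_m
                * (-3.0 + 4.0 * sin_sigma**2)
                * (-3.0 + 4.0 * cos2sigma_m**2)
            )
        )
    )
    dist_m = _B_M * A * (sigma - delta_sigma)
    return dist_m / 1000.0


def vincenty_distance(a: GeoPoint, b: GeoPoint) -> float:
    """Geodesic distance between two points in kilometers.

    Symmetric, zero for coincident points, and computed on the WGS84
    ellipsoid. Raises :class:`ConvergenceError` for nearly antipodal pairs.
    """
    if a.lat == b.lat and a.lon == b.lon:
        return 0.0
    result = vincenty_km(a.lat, a.lon, np.array([b.lat]), np.array([b.lon]))
    return float(result[0])
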