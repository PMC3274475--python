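"""Comparison of block-group estimates against ground-station observations.

Metrics: mean absolute deviation (MAD), pooled Pearson correlation, and the
distribution of absolute deviations, stratifiable by year, meteorological
season (DJF/MAM/JJA/SON), and urban/rural status. Quantiles use linear
interpolation between order statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .downscale import BGEstimateSeries
from .errors import GridshedError

__all__ = [
    "StationObservation",
    "ComparisonReport",
    "pair_observations",
    "mad",
    "pearson_r",
    "absdev_distribution",
    "stratified_report",
    "season_of",
]

logger = logging.getLogger(__name__)

VALID_STRATA = ("year", "season", "urban_rural")

_SEASONS = {
    12: "DJF", 1: "DJF", 2: "DJF",
    3: "MAM", 4: "MAM", 5: "MAM",
    6: "JJA", 7: "JJA", 8: "JJA",
    9: "SON", 10: "SON", 11: "SON",
}


@dataclass(frozen=True)
class StationObservation:
    """One daily observation at a monitoring station assigned to a BG."""

    station_id: str
    bg_geoid: str
    date: str
    observed: float
    urban_rural: str | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.observed):
            raise ValueError(f"station {self.station_id}: non-finite observation")
        if self.urban_rural not in (None, "urban", "rural"):
            raise ValueError(f"urban_rural must be 'urban'/'rural', got {self.urban_rural!r}")


@dataclass(frozen=True)
class ComparisonReport:
    stratum: str
    n_stations: int
    n_obs: int
    mad: float
    r: float | None
    absdev_stats: tuple[float, float, float, float, float, float, float]  # min,p5,p10,median,p90,p95,max


def season_of(date: str) -> str:
    return _SEASONS[int(date[5:7])]


def pair_observations(
    stations: Sequence[StationObservation],
    bg_est: Sequence[BGEstimateSeries],
) -> pd.DataFrame:
    """Join station observations to BG estimates on (bg_geoid, date).

    One row per (station, date) with both values present; stations whose BG
    has no estimate series are excluded with a warning. Columns:
    station_id, bg_geoid, date, observed, estimated, urban_rural, year,
    season.
    """
    est_by_geoid = {s.bg_geoid: s for s in bg_est}
    rows = []
    dropped_stations: set[str] = set()
    for obs in stations:
        series = est_by_geoid.get(obs.bg_geoid)
        if series is None:
            dropped_stations.add(obs.station_id)
            continue
        entry = series.estimates.get(obs.date)
        if entry is None:
            continue
        rows.append(
            {
                "station_id": obs.station_id,
                "bg_geoid": obs.bg_geoid,
                "date": obs.date,
                "observed": obs.observed,
                "estimated": entry[0],
                "urban_rural": obs.urban_rural,
                "year": obs.date[:4],
                "season": season_of(obs.date),
            }
        )
    if dropped_stations:
        logger.warning(
            "%d station(s) referenced BGs without estimates and were excluded: %s",
            len(dropped_stations),
            sorted(dropped_stations)[:5],
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "station_id", "bg_geoid", "date", "observed", "estimated",
            "urban_rural", "year", "season",
        ],
    )
    df.attrs["n_dropped_stations"] = len(dropped_stations)
    return df


def mad(pairs: pd.DataFrame) -> float:
    """Mean absolute deviation of estimates from observations."""
    if len(pairs) == 0:
        raise GridshedError("no pairs: MAD undefined")
    return float(np.mean(np.abs(pairs["estimated"].to_numpy() - pairs["observed"].to_numpy())))


def pearson_r(pairs: pd.DataFrame) -> float | None:
    """Pooled sample Pearson correlation; None if undefined (constant column
    or fewer than two pairs)."""
    if len(pairs) < 2:
        return None
    x = pairs["observed"].to_numpy(dtype=float)
    y = pairs["estimated"].to_numpy(dtype=float)
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return None
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))


def absdev_distribution(pairs: pd.DataFrame) -> tuple[float, ...]:
    """(min, p5, p10, median, p90, p95, max) of |estimated − observed|."""
    if len(pairs) == 0:
        raise GridshedError("no pairs: distribution undefined")
    dev = np.abs(pairs["estimated"].to_numpy() - pairs["observed"].to_numpy())
    qs = np.quantile(dev, [0.05, 0.10, 0.50, 0.90, 0.95], method="linear")
    return (float(dev.min()), *[float(q) for q in qs], float(dev.max()))


def _report_for(label: str, sub: pd.DataFrame) -> ComparisonReport:
    return ComparisonReport(
        stratum=label,
        n_stations=int(sub["station_id"].nunique()),
        n_obs=len(sub),
        mad=mad(sub),
        r=pearson_r(sub),
        absdev_stats=absdev_distribution(sub),
    )


def stratified_report(
    pairs: pd.DataFrame,
    strata: Sequence[str] = (),
) -> list[ComparisonReport]:
    """Overall report plus one report per level of each requested stratum."""
    unknown = set(strata) - set(VALID_STRATA)
    if unknown:
        raise ValueError(f"unknown strata: {sorted(unknown)}")
    if len(pairs) == 0:
        raise GridshedError("no pairs to report on")

    reports = [_report_for("overall", pairs)]
    for stratum in strata:
        col = pairs[stratum]
        if stratum == "urban_rural" and col.isna().all():
            raise GridshedError("urban_rural stratum requested but column is empty")
        for level, sub in pairs.groupby(col, dropna=True, observed=True):
            if len(sub) == 0:
                logger.info("stratum %s=%s has no pairs; omitted", stratum, level)
                continue
            reports.append(_report_for(f"{stratum}={level}", sub))
    return reports
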