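"""Population-weighted aggregation of block-group estimates to larger units.

Census geography nests by GEOID prefix: state (2) < county (5) <
tract (11) < block group (12). The national unit is labeled "US".
Exposure for a unit-day is PE = Σ a_i μ_i with a_i = pop_i / Σ pop_j, and
its standard error is ψ = sqrt(Σ a_i² δ_i²) under independence across BGs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .downscale import BGEstimateSeries
from .errors import CalendarError, GridshedError
from .geodesy import GeoPoint

__all__ = [
    "BlockGroup",
    "CGUExposureSeries",
    "LEVELS",
    "build_hierarchy",
    "aggregate_exposure",
    "aggregate_all",
]

logger = logging.getLogger(__name__)

# level -> GEOID prefix length (national is the special "US" unit)
LEVELS: dict[str, int | None] = {
    "bg": 12,
    "tract": 11,
    "county": 5,
    "state": 2,
    "national": None,
}


@dataclass(frozen=True)
class BlockGroup:
    """A census block group: 12-digit GEOID, centroid, annual population."""

    geoid: str
    centroid: GeoPoint
    population: int

    def __post_init__(self) -> None:
        validate_geoid(self.geoid)
        if self.population < 0:
            raise ValueError(f"BG {self.geoid}: negative population {self.population}")


@dataclass
class CGUExposureSeries:
    """Daily population exposure (pe) and standard error (psi) for one unit."""

    geoid: str
    level: str
    population: int
    exposures: dict[str, tuple[float, float]] = field(default_factory=dict)


def validate_geoid(geoid: str) -> None:
    if not (isinstance(geoid, str) and len(geoid) == 12 and geoid.isdigit()):
        raise ValueError(f"malformed 12-digit BG GEOID: {geoid!r}")


def build_hierarchy(
    geoids: Iterable[str],
    levels: Sequence[str] = ("tract", "county", "state", "national"),
) -> dict[str, dict[str, list[str]]]:
    """Group BG GEOIDs into parent units per level by FIPS prefix.

    Returns ``{level: {unit_geoid: [bg_geoid, ...]}}``. Malformed GEOIDs
    raise a single error listing all offenders.
    """
    geoids = list(geoids)
    bad = [g for g in geoids if not (isinstance(g, str) and len(g) == 12 and g.isdigit())]
    if bad:
        raise ValueError(f"malformed BG GEOIDs: {bad[:10]}" + (" ..." if len(bad) > 10 else ""))
    unknown = set(levels) - set(LEVELS)
    if unknown:
        raise ValueError(f"unknown levels: {sorted(unknown)}")

    out: dict[str, dict[str, list[str]]] = {}
    for level in levels:
        width = LEVELS[level]
        groups: dict[str, list[str]] = {}
        for g in geoids:
            key = "US" if width is None else g[:width]
            groups.setdefault(key, []).append(g)
        out[level] = groups
    return out


def aggregate_exposure(
    members: Sequence[tuple[BGEstimateSeries, int]],
) -> dict[str, tuple[float, float]]:
    """Population-weighted (pe, psi) per date over member BG series.

    Zero-population members contribute nothing; a unit whose total
    population is zero has no defined exposure and raises.
    """
    if not members:
        raise GridshedError("no member BGs to aggregate")
    total_pop = sum(pop for _, pop in members)
    if total_pop <= 0:
        geoids = [s.bg_geoid for s, _ in members]
        raise GridshedError(
            f"unit containing BGs {geoids[:5]} has zero total population: exposure undefined"
        )
    calendars = {tuple(s.dates()) for s, _ in members}
    if len(calendars) > 1:
        raise CalendarError("member BG series do not share one calendar")
    dates = members[0][0].dates()

    weights = np.array([pop / total_pop for _, pop in members])
    mus = np.array([[s.estimates[d][0] for d in dates] for s, _ in members])
    deltas = np.array([[s.estimates[d][1] for d in dates] for s, _ in members])
    pe = weights @ mus
    psi = np.sqrt((weights**2) @ (deltas**2))
    return {d: (float(pe[j]), float(psi[j])) for j, d in enumerate(dates)}


def aggregate_all(
    bg_series: Sequence[BGEstimateSeries],
    bgs: Sequence[BlockGroup],
    levels: Sequence[str] = ("tract", "county", "state", "national"),
) -> list[CGUExposureSeries]:
    """One exposure series per unit per requested level.

    Every BG estimate must have a matching population record. BGs with zero
    population are excluded from weighting (logged); units consisting only
    of zero-population BGs are skipped with a warning.
    """
    pop_by_geoid = {bg.geoid: bg.population for bg in bgs}
    series_by_geoid: dict[str, BGEstimateSeries] = {}
    for s in bg_series:
        if s.bg_geoid not in pop_by_geoid:
            raise GridshedError(f"BG estimate {s.bg_geoid} has no population record")
        series_by_geoid[s.bg_geoid] = s

    n_zero = sum(1 for g in series_by_geoid if pop_by_geoid[g] == 0)
    if n_zero:
        logger.info("excluding %d zero-population BGs from exposure weighting", n_zero)

    hierarchy = build_hierarchy(series_by_geoid.keys(), levels=levels)
    out: list[CGUExposureSeries] = []
    for level, units in hierarchy.items():
        for unit_geoid, member_geoids in sorted(units.items()):
            members = [
                (series_by_geoid[g], pop_by_geoid[g])
                for g in member_geoids
                if pop_by_geoid[g] > 0
            ]
            total_pop = sum(pop_by_geoid[g] for g in member_geoids)
            if not members:
                logger.warning(
                    "unit %s (%s) has zero total population; skipped", unit_geoid, level
                )
                continue
            out.append(
                CGUExposureSeries(
                    geoid=unit_geoid,
                    level=level,
                    population=total_pop,
                    exposures=aggregate_exposure(members),
                )
            )
    logger.info("aggregated %d units across levels %s", len(out), list(levels))
    return out
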