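"""Percentile day-rank summaries, exceedance-day counts, map classes, and
population-at-risk tables.

The tail summary follows a day-rank convention: the value reported for tail
fraction p over D days is the k-th highest daily value with
k = max(1, round(p·D)) (half rounds away from zero), e.g. the 7th-highest
day for p = 0.02 over a 365-day year.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .aggregate import LEVELS

__all__ = [
    "StandardConfig",
    "ExceedanceRecord",
    "DEFAULT_STANDARDS",
    "kth_highest",
    "count_exceedance_days",
    "class_breaks",
    "classify",
    "population_at_risk",
]


@dataclass(frozen=True)
class StandardConfig:
    """A daily air-quality standard plus map-class layout.

    Defaults follow the daily NAAQS forms: 35 μg/m³ (24-h PM2.5) and
    75 ppb (8-h ozone), with five classes of width 10 anchored so that the
    second-highest cut point equals the standard.
    """

    pollutant: str
    threshold: float
    class_width: float = 10.0
    n_classes: int = 5

    def __post_init__(self) -> None:
        if self.pollutant not in ("pm25", "ozone"):
            raise ValueError(f"unknown pollutant {self.pollutant!r}")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.class_width <= 0:
            raise ValueError("class_width must be positive")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")

    @classmethod
    def for_pollutant(cls, pollutant: str) -> "StandardConfig":
        if pollutant not in DEFAULT_STANDARDS:
            raise ValueError(f"unknown pollutant {pollutant!r}")
        return cls(pollutant=pollutant, threshold=DEFAULT_STANDARDS[pollutant])


DEFAULT_STANDARDS: dict[str, float] = {"pm25": 35.0, "ozone": 75.0}


@dataclass(frozen=True)
class ExceedanceRecord:
    """Exceedance-day count and population for one BG."""

    geoid: str
    pollutant: str
    days_exceeding: int
    population: int

    def __post_init__(self) -> None:
        if self.days_exceeding < 0:
            raise ValueError("days_exceeding must be >= 0")


def day_rank(p: float, n_days: int) -> int:
    """Rank (from the top) selected for tail fraction ``p`` over ``n_days``.

    k = max(1, round(p·D)) with half-away-from-zero rounding, so p = 0.02
    over 365 days gives k = 7 (7.3 → 7) and p = 0.10 gives k = 37
    (36.5 → 37).
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"tail fraction must be in (0, 1), got {p}")
    if n_days < 1:
        raise ValueError("series must be non-empty")
    return max(1, math.floor(p * n_days + 0.5))


def kth_highest(values: Sequence[float], p: float) -> tuple[float, int]:
    """The k-th largest daily value for tail fraction ``p`` and its rank k."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty series")
    k = day_rank(p, arr.size)
    value = float(np.sort(arr)[arr.size - k])
    return value, k


def count_exceedance_days(series: Sequence[float], cfg: StandardConfig) -> int:
    """Number of days with value strictly above the configured standard."""
    arr = np.asarray(series, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("series contains non-finite values")
    return int(np.sum(arr > cfg.threshold))


def class_breaks(cfg: StandardConfig) -> tuple[float, ...]:
    """Ordered map-class cut points.

    For the default 5-class layout: (t−2w, t−w, t, t+w) with t the standard
    and w the class width, so PM2.5 yields (15, 25, 35, 45) and ozone
    (55, 65, 75, 85). Classes are the intervals (−∞, t−2w], …, (t+w, ∞).
    """
    if cfg.n_classes != 5:
        raise ValueError("only the 5-class layout is supported")
    t, w = cfg.threshold, cfg.class_width
    return (t - 2 * w, t - w, t, t + w)


def classify(value: float, breaks: Sequence[float]) -> int:
    """1-based class index of ``value`` under ordered breaks.

    Intervals are closed on the right: class i is (b_{i-1}, b_i].
    """
    if not math.isfinite(value):
        raise ValueError("cannot classify non-finite value")
    for i, b in enumerate(breaks, start=1):
        if value <= b:
            return i
    return len(breaks) + 1


def population_at_risk(
    exceedance: Sequence[ExceedanceRecord],
    min_days: int,
    level: str,
) -> list[dict]:
    """Population meeting an exceedance-day criterion, rolled up per unit.

    Returns one row per unit at ``level`` with keys ``geoid``,
    ``population_at_risk``, ``total_population`` and ``percent``
    (``None`` when the unit's total population is zero).
    """
    if min_days < 1:
        raise ValueError("min_days must be >= 1")
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}")
    width = LEVELS[level]

    totals: dict[str, int] = {}
    at_risk: dict[str, int] = {}
    for rec in exceedance:
        key = "US" if width is None else rec.geoid[:width]
        totals[key] = totals.get(key, 0) + rec.population
        if rec.days_exceeding >= min_days:
            at_risk[key] = at_risk.get(key, 0) + rec.population

    rows = []
    for key in sorted(totals):
        risk = at_risk.get(key, 0)
        total = totals[key]
        rows.append(
            {
                "geoid": key,
                "population_at_risk": risk,
                "total_population": total,
                "percent": (100.0 * risk / total) if total > 0 else None,
            }
        )
    return rows
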