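"""Synthetic input generator: gridded daily surfaces with standard errors,
block groups with nested FIPS GEOIDs and populations, and noisy stations.

The simulated surface is baseline + seasonal sinusoid + fixed Gaussian
spatial bumps + per-cell AR(1) temporal noise. The stored "truth" omits the
AR(1) term, so station noise is the only stochastic gap in validation
recovery experiments. Everything is a pure function of (config, seed): one
global seed is split into independent per-component streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .aggregate import BlockGroup
from .downscale import GridSeries
from .errors import ConfigError
from .geodesy import GeoPoint
from .validation import StationObservation

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "make_grid",
    "simulate_field",
    "make_block_groups",
    "make_stations",
    "generate_dataset",
]

_KM_PER_DEG_LAT = 110.574
_KM_PER_DEG_LON_EQ = 111.320


@dataclass(frozen=True)
class SimConfig:
    n_rows: int = 10
    n_cols: int = 10
    spacing_km: float = 36.0
    origin: GeoPoint = field(default_factory=lambda: GeoPoint(38.0, -90.0))
    n_days: int = 30
    start_date: str = "2006-01-01"
    n_bgs: int = 54
    n_states: int = 3
    counties_per_state: int = 2
    tracts_per_county: int = 3
    pop_low: int = 600
    pop_high: int = 3000
    station_fraction: float = 0.3
    two_station_fraction: float = 0.05
    station_noise_sd: float = 1.0
    baseline: float = 20.0
    seasonal_amplitude: float = 5.0
    n_bumps: int = 3
    bump_amplitude: float = 8.0
    bump_scale_km: float = 80.0
    ar1_phi: float = 0.5
    innovation_sd: float = 1.0
    se_scale: float = 0.5
    se_floor: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 2 or self.n_cols < 2:
            raise ConfigError("lattice must be at least 2x2")
        if self.n_days < 1 or self.n_bgs < 1:
            raise ConfigError("n_days and n_bgs must be positive")
        if not (0 < self.pop_low <= self.pop_high):
            raise ConfigError("population bounds must satisfy 0 < pop_low <= pop_high")
        if not 0.0 <= self.ar1_phi < 1.0:
            raise ConfigError("ar1_phi must be in [0, 1)")
        if self.station_noise_sd < 0:
            raise ConfigError("station_noise_sd must be >= 0")
        if min(self.n_states, self.counties_per_state, self.tracts_per_county) < 1:
            raise ConfigError("hierarchy counts must be positive")

    def dates(self) -> list[str]:
        return (
            pd.date_range(self.start_date, periods=self.n_days, freq="D")
            .strftime("%Y-%m-%d")
            .tolist()
        )

    def _streams(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(4)
        names = ("field", "se", "bgs", "stations")
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}


@dataclass
class SyntheticTruth:
    """Noise-free field values: per grid cell and at BG centroids."""

    cell_truth: dict[str, dict[str, float]]  # cell_id -> date -> value
    bg_truth: dict[str, dict[str, float]]  # bg_geoid -> date -> value


def _deg_steps(cfg: SimConfig) -> tuple[float, float]:
    dlat = cfg.spacing_km / _KM_PER_DEG_LAT
    dlon = cfg.spacing_km / (_KM_PER_DEG_LON_EQ * math.cos(math.radians(cfg.origin.lat)))
    return dlat, dlon


def make_grid(cfg: SimConfig) -> list[tuple[str, GeoPoint]]:
    """Regular n_rows × n_cols lattice of centroids, ≈spacing_km apart.

    Cell ids encode row/column as ``g<row>_<col>``.
    """
    dlat, dlon = _deg_steps(cfg)
    cells = []
    for r in range(cfg.n_rows):
        for c in range(cfg.n_cols):
            pt = GeoPoint(cfg.origin.lat + r * dlat, cfg.origin.lon + c * dlon)
            cells.append((f"g{r:03d}_{c:03d}", pt))
    return cells


def _bumps(cfg: SimConfig, rng: np.random.Generator) -> list[tuple[float, float, float]]:
    """Gaussian bump centers (lat, lon) and shared amplitude, within extent."""
    dlat, dlon = _deg_steps(cfg)
    lat_hi = cfg.origin.lat + (cfg.n_rows - 1) * dlat
    lon_hi = cfg.origin.lon + (cfg.n_cols - 1) * dlon
    return [
        (rng.uniform(cfg.origin.lat, lat_hi), rng.uniform(cfg.origin.lon, lon_hi), cfg.bump_amplitude)
        for _ in range(cfg.n_bumps)
    ]


def _smooth_value(
    lat: float, lon: float, day_index: int, cfg: SimConfig,
    bumps: Sequence[tuple[float, float, float]],
) -> float:
    """Noise-free field: baseline + seasonal sinusoid + spatial bumps."""
    seasonal = cfg.seasonal_amplitude * math.sin(2.0 * math.pi * day_index / 365.25)
    total = cfg.baseline + seasonal
    scale_deg = cfg.bump_scale_km / _KM_PER_DEG_LAT
    for blat, blon, amp in bumps:
        dlat = lat - blat
        dlon = (lon - blon) * math.cos(math.radians(lat))
        total += amp * math.exp(-(dlat**2 + dlon**2) / (2.0 * scale_deg**2))
    return total


def simulate_field(
    cells: Sequence[tuple[str, GeoPoint]],
    cfg: SimConfig,
) -> tuple[list[GridSeries], SyntheticTruth]:
    """Daily values + positive standard errors per cell, plus the truth.

    Per-cell AR(1) noise (parameter ``ar1_phi``, innovations
    N(0, innovation_sd²)) is added to the smooth field; the AR(1) state is
    initialized from its stationary distribution. Standard errors are
    ``se_floor + se_scale·|N(0,1)|``.
    """
    streams = cfg._streams()
    rng_field = streams["field"]
    rng_se = streams["se"]
    bumps = _bumps(cfg, rng_field)
    dates = cfg.dates()
    n_cells, n_days = len(cells), cfg.n_days

    # AR(1) noise matrix (cells x days)
    noise = np.zeros((n_cells, n_days))
    if cfg.innovation_sd > 0:
        stat_sd = cfg.innovation_sd / math.sqrt(1.0 - cfg.ar1_phi**2)
        noise[:, 0] = rng_field.normal(0.0, stat_sd, n_cells)
        innov = rng_field.normal(0.0, cfg.innovation_sd, (n_cells, n_days))
        for t in range(1, n_days):
            noise[:, t] = cfg.ar1_phi * noise[:, t - 1] + innov[:, t]

    ses = cfg.se_floor + cfg.se_scale * np.abs(rng_se.normal(0.0, 1.0, (n_cells, n_days)))

    series: list[GridSeries] = []
    cell_truth: dict[str, dict[str, float]] = {}
    for i, (cell_id, pt) in enumerate(cells):
        smooth = np.array(
            [_smooth_value(pt.lat, pt.lon, t, cfg, bumps) for t in range(n_days)]
        )
        vals = smooth + noise[i]
        series.append(
            GridSeries(
                cell_id=cell_id,
                centroid=pt,
                values={d: float(v) for d, v in zip(dates, vals)},
                ses={d: float(s) for d, s in zip(dates, ses[i])},
                resolution_km=int(cfg.spacing_km),
            )
        )
        cell_truth[cell_id] = {d: float(v) for d, v in zip(dates, smooth)}

    truth = SyntheticTruth(cell_truth=cell_truth, bg_truth={})
    truth._bumps = bumps  # retained so BG truth uses the same field
    return series, truth


def make_block_groups(cfg: SimConfig) -> list[BlockGroup]:
    """Block groups with nested GEOIDs, uniform centroids, and populations.

    n_bgs must divide evenly into the configured
    states × counties × tracts hierarchy with 1–9 BGs per tract (the BG
    code is a single digit). Populations are triangular on
    [pop_low, pop_high] with mode 1500 (clipped into the bounds).
    """
    n_tracts = cfg.n_states * cfg.counties_per_state * cfg.tracts_per_county
    if cfg.n_bgs % n_tracts != 0:
        raise ConfigError(
            f"n_bgs={cfg.n_bgs} does not divide evenly over {n_tracts} tracts"
        )
    bgs_per_tract = cfg.n_bgs // n_tracts
    if not 1 <= bgs_per_tract <= 9:
        raise ConfigError(f"{bgs_per_tract} BGs per tract outside the 1-9 code range")

    rng = cfg._streams()["bgs"]
    dlat, dlon = _deg_steps(cfg)
    lat_hi = cfg.origin.lat + (cfg.n_rows - 1) * dlat
    lon_hi = cfg.origin.lon + (cfg.n_cols - 1) * dlon

    mode = min(max(1500.0, cfg.pop_low), cfg.pop_high)
    out: list[BlockGroup] = []
    for s in range(cfg.n_states):
        for c in range(cfg.counties_per_state):
            for t in range(cfg.tracts_per_county):
                for b in range(bgs_per_tract):
                    geoid = f"{s + 1:02d}{c + 1:03d}{(t + 1) * 100:06d}{b + 1:d}"
                    pt = GeoPoint(
                        float(rng.uniform(cfg.origin.lat, lat_hi)),
                        float(rng.uniform(cfg.origin.lon, lon_hi)),
                    )
                    pop = int(round(rng.triangular(cfg.pop_low, mode, cfg.pop_high)))
                    out.append(BlockGroup(geoid=geoid, centroid=pt, population=pop))
    return out


def compute_bg_truth(
    bgs: Sequence[BlockGroup], truth: SyntheticTruth, cfg: SimConfig
) -> None:
    """Fill ``truth.bg_truth`` by evaluating the smooth field at BG centroids."""
    bumps = getattr(truth, "_bumps", [])
    dates = cfg.dates()
    for bg in bgs:
        truth.bg_truth[bg.geoid] = {
            d: _smooth_value(bg.centroid.lat, bg.centroid.lon, t, cfg, bumps)
            for t, d in enumerate(dates)
        }


def make_stations(
    bgs: Sequence[BlockGroup],
    truth: SyntheticTruth,
    cfg: SimConfig,
) -> list[StationObservation]:
    """Noisy daily station observations: BG truth + N(0, station_noise_sd).

    ``station_fraction`` of BGs receive one station; of those,
    ``two_station_fraction`` of all BGs receive a second, mirroring the
    0–2 stations-per-BG regime. Stations are tagged urban/rural at random.
    """
    if not truth.bg_truth:
        compute_bg_truth(bgs, truth, cfg)
    rng = cfg._streams()["stations"]
    dates = cfg.dates()
    out: list[StationObservation] = []
    for bg in bgs:
        u = rng.uniform()
        n_st = 2 if u < cfg.two_station_fraction else (1 if u < cfg.station_fraction else 0)
        for j in range(n_st):
            sid = f"st_{bg.geoid}_{j}"
            ur = "urban" if rng.uniform() < 0.5 else "rural"
            noise = rng.normal(0.0, cfg.station_noise_sd, len(dates)) if cfg.station_noise_sd > 0 else np.zeros(len(dates))
            for d, eps in zip(dates, noise):
                out.append(
                    StationObservation(
                        station_id=sid,
                        bg_geoid=bg.geoid,
                        date=d,
                        observed=truth.bg_truth[bg.geoid][d] + float(eps),
                        urban_rural=ur,
                    )
                )
    return out


def generate_dataset(cfg: SimConfig):
    """Full synthetic dataset: (grid series, block groups, stations, truth)."""
    cells = make_grid(cfg)
    grid, truth = simulate_field(cells, cfg)
    bgs = make_block_groups(cfg)
    compute_bg_truth(bgs, truth, cfg)
    stations = make_stations(bgs, truth, cfg)
    return grid, bgs, stations, truth
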