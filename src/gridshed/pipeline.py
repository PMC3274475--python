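"""Stage drivers shared by the CLI: downscale → aggregate → summarize →
validate, plus the full chained run."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io
from .aggregate import aggregate_all
from .downscale import downscale_all
from .errors import ConfigError
from .summaries import (
    ExceedanceRecord,
    StandardConfig,
    class_breaks,
    classify,
    count_exceedance_days,
    kth_highest,
    population_at_risk,
)
from .validation import pair_observations, stratified_report

logger = logging.getLogger(__name__)

DEFAULT_LEVELS = ("tract", "county", "state", "national")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    grid: str
    bg: str
    out_dir: str
    pollutant: str = "pm25"
    threshold: float | None = None  # None -> pollutant default
    class_width: float = 10.0
    k: int = 4
    levels: tuple[str, ...] = DEFAULT_LEVELS
    min_days: tuple[int, ...] = (7, 14, 28)
    stations: str | None = None
    strata: tuple[str, ...] = ()

    def standard(self) -> StandardConfig:
        if self.threshold is None:
            return StandardConfig.for_pollutant(self.pollutant)
        return StandardConfig(
            pollutant=self.pollutant, threshold=self.threshold, class_width=self.class_width
        )


def run_downscale(grid_path: str, bg_path: str, out_path: str, k: int = 4) -> None:
    grid = io.load_grid(grid_path)
    bgs = io.load_block_groups(bg_path)
    series = downscale_all(grid, bgs, k=k)
    io.write_bg_estimates(series, out_path)


def run_aggregate(bg_est_path: str, bg_path: str, out_path: str, levels=DEFAULT_LEVELS) -> None:
    series = io.load_bg_estimates(bg_est_path)
    bgs = io.load_block_groups(bg_path)
    io.write_exposures(aggregate_all(series, bgs, levels=levels), out_path)


def summarize_tables(
    exposures: pd.DataFrame,
    bg_est: list,
    bgs: list,
    cfg: StandardConfig,
    min_days: tuple[int, ...] = (7, 14, 28),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the percentile/exceedance summary and population-at-risk tables.

    Percentile summaries are computed on PE per aggregated unit and on μ per
    BG; exceedance days are counted on BG μ only. The applied day ranks are
    exposed as columns p98_k / p90_k.
    """
    breaks = class_breaks(cfg)
    rows = []

    for s in bg_est:
        mus = [s.estimates[d][0] for d in s.dates()]
        (v98, k98) = kth_highest(mus, 0.02)
        (v90, k90) = kth_highest(mus, 0.10)
        rows.append(
            {
                "geoid": s.bg_geoid,
                "level": "bg",
                "pollutant": cfg.pollutant,
                "p98_value": v98,
                "p98_k": k98,
                "p90_value": v90,
                "p90_k": k90,
                "days_exceeding": count_exceedance_days(mus, cfg),
                "class_p98": classify(v98, breaks),
                "class_p90": classify(v90, breaks),
            }
        )

    for (geoid, level), sub in exposures.groupby(["geoid", "level"], sort=True):
        pes = sub.sort_values("date")["pe"].to_numpy()
        (v98, k98) = kth_highest(pes, 0.02)
        (v90, k90) = kth_highest(pes, 0.10)
        rows.append(
            {
                "geoid": geoid,
                "level": level,
                "pollutant": cfg.pollutant,
                "p98_value": v98,
                "p98_k": k98,
                "p90_value": v90,
                "p90_k": k90,
                "days_exceeding": pd.NA,
                "class_p98": classify(v98, breaks),
                "class_p90": classify(v90, breaks),
            }
        )
    summary = pd.DataFrame(rows)

    pop_by_geoid = {b.geoid: b.population for b in bgs}
    records = []
    for row in summary[summary["level"] == "bg"].itertuples():
        if row.geoid not in pop_by_geoid:
            raise ConfigError(f"BG {row.geoid} has no population record")
        records.append(
            ExceedanceRecord(
                geoid=row.geoid,
                pollutant=cfg.pollutant,
                days_exceeding=int(row.days_exceeding),
                population=pop_by_geoid[row.geoid],
            )
        )

    par_rows = []
    for level in ("county", "state", "national"):
        for md in min_days:
            for r in population_at_risk(records, md, level):
                par_rows.append(
                    {
                        "geoid": r["geoid"],
                        "level": level,
                        "pollutant": cfg.pollutant,
                        "min_days": md,
                        "population_at_risk": r["population_at_risk"],
                        "percent": r["percent"],
                    }
                )
    return summary, pd.DataFrame(par_rows)


def run_summarize(
    exposures_path: str,
    bg_est_path: str,
    bg_path: str,
    out_dir: str,
    cfg: StandardConfig,
    min_days: tuple[int, ...] = (7, 14, 28),
) -> None:
    exposures = io.read_table(exposures_path, "exposures")
    bg_est = io.load_bg_estimates(bg_est_path)
    bgs = io.load_block_groups(bg_path)
    summary, par = summarize_tables(exposures, bg_est, bgs, cfg, min_days)
    out = Path(out_dir)
    io.write_frame(summary, out / "summary.csv")
    io.write_frame(par, out / "population_at_risk.csv")


def run_validate(bg_est_path: str, stations_path: str, out_path: str, strata=()) -> None:
    bg_est = io.load_bg_estimates(bg_est_path)
    stations = io.load_stations(stations_path)
    pairs = pair_observations(stations, bg_est)
    reports = stratified_report(pairs, strata=strata)
    rows = []
    for r in reports:
        mn, p5, p10, med, p90, p95, mx = r.absdev_stats
        rows.append(
            {
                "stratum": r.stratum,
                "n_stations": r.n_stations,
                "n_obs": r.n_obs,
                "mad": r.mad,
                "r": r.r if r.r is not None else "",
                "absdev_min": mn,
                "absdev_p5": p5,
                "absdev_p10": p10,
                "absdev_median": med,
                "absdev_p90": p90,
                "absdev_p95": p95,
                "absdev_max": mx,
            }
        )
    io.write_frame(pd.DataFrame(rows), out_path)


def run_pipeline(cfg: RunConfig) -> None:
    """Execute downscale → aggregate → summarize (→ validate) end to end."""
    if cfg.strata and cfg.stations is None:
        raise ConfigError("validation strata requested but no stations file supplied")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "downscale"
    try:
        run_downscale(cfg.grid, cfg.bg, str(out / "bg_est.csv"), k=cfg.k)
        stage = "aggregate"
        run_aggregate(str(out / "bg_est.csv"), cfg.bg, str(out / "exposures.csv"), levels=cfg.levels)
        stage = "summarize"
        run_summarize(
            str(out / "exposures.csv"),
            str(out / "bg_est.csv"),
            cfg.bg,
            str(out),
            cfg.standard(),
            cfg.min_days,
        )
        if cfg.stations is not None:
            stage = "validate"
            run_validate(
                str(out / "bg_est.csv"), cfg.stations, str(out / "validation.csv"), cfg.strata
            )
    except Exception as exc:
        raise type(exc)(f"[stage {stage}] {exc}") from exc
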