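"""CSV readers/writers with schema validation.

All tables are comma-separated UTF-8 with a mandatory header. GEOIDs are
always read and written as zero-padded strings (a leading-zero state FIPS
like "04" must survive a round trip), dates as ISO-8601 strings, and floats
at full double precision ("%.17g") so reruns are byte-identical.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .aggregate import BlockGroup, CGUExposureSeries
from .downscale import BGEstimateSeries, GridSeries
from .errors import SchemaError
from .geodesy import GeoPoint
from .validation import StationObservation

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.17g"

_GEOID_RE = re.compile(r"^\d{12}$")
_DATE_RE = re.compile(r"^\d{4}-\d{2}-\d{2}$")

# schema: column -> (dtype for read, validator or None)
SCHEMAS: dict[str, dict] = {
    "grid": {
        "columns": {
            "cell_id": str,
            "lat": float,
            "lon": float,
            "date": str,
            "value": float,
            "se": float,
        },
        "checks": {
            "date": ("ISO-8601 date", lambda s: s.str.match(_DATE_RE)),
            "lat": ("latitude in [-90, 90]", lambda s: (s >= -90) & (s <= 90)),
            "lon": ("longitude in [-180, 180]", lambda s: (s >= -180) & (s <= 180)),
            "se": ("non-negative standard error", lambda s: s >= 0),
        },
    },
    "bg": {
        "columns": {"geoid": str, "lat": float, "lon": float, "population": int},
        "checks": {
            "geoid": ("12-digit GEOID", lambda s: s.str.match(_GEOID_RE)),
            "lat": ("latitude in [-90, 90]", lambda s: (s >= -90) & (s <= 90)),
            "lon": ("longitude in [-180, 180]", lambda s: (s >= -180) & (s <= 180)),
            "population": ("non-negative population", lambda s: s >= 0),
        },
    },
    "bg_est": {
        "columns": {"geoid": str, "date": str, "mu": float, "delta": float},
        "checks": {
            "geoid": ("12-digit GEOID", lambda s: s.str.match(_GEOID_RE)),
            "date": ("ISO-8601 date", lambda s: s.str.match(_DATE_RE)),
            "delta": ("non-negative delta", lambda s: s >= 0),
        },
    },
    "stations": {
        "columns": {"station_id": str, "bg_geoid": str, "date": str, "observed": float},
        "optional": {"urban_rural": str},
        "checks": {
            "bg_geoid": ("12-digit GEOID", lambda s: s.str.match(_GEOID_RE)),
            "date": ("ISO-8601 date", lambda s: s.str.match(_DATE_RE)),
        },
    },
    "exposures": {
        "columns": {
            "geoid": str,
            "level": str,
            "date": str,
            "pe": float,
            "psi": float,
            "population": int,
        },
        "checks": {
            "date": ("ISO-8601 date", lambda s: s.str.match(_DATE_RE)),
            "psi": ("non-negative psi", lambda s: s >= 0),
        },
    },
    "truth": {
        "columns": {"bg_geoid": str, "date": str, "truth": float},
        "checks": {
            "bg_geoid": ("12-digit GEOID", lambda s: s.str.match(_GEOID_RE)),
            "date": ("ISO-8601 date", lambda s: s.str.match(_DATE_RE)),
        },
    },
}


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV against a named schema.

    Missing columns are a hard error; row-level violations raise a
    :class:`SchemaError` reporting the count and the first offending line
    numbers (1-based, header = line 1).
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    spec = SCHEMAS[schema]
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file not found")

    str_cols = [c for c, t in spec["columns"].items() if t is str]
    str_cols += [c for c in spec.get("optional", {})]
    df = pd.read_csv(path, dtype={c: str for c in str_cols}, float_precision="round_trip")

    missing = set(spec["columns"]) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {sorted(missing)}")
    if len(df) == 0:
        logger.warning("%s: empty table (header only)", path)
        return df

    for col, typ in spec["columns"].items():
        if typ in (float, int):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()] + 2
            if len(bad):
                raise SchemaError(
                    f"{path}: column {col!r}: {len(bad)} unparseable value(s), "
                    f"first at line(s) {list(bad[:5])}"
                )
            if coerced.isna().any():
                bad = df.index[coerced.isna()] + 2
                raise SchemaError(
                    f"{path}: column {col!r}: {int(coerced.isna().sum())} missing value(s), "
                    f"first at line(s) {list(bad[:5])}"
                )
            df[col] = coerced.astype(typ)

    for col, (desc, check) in spec.get("checks", {}).items():
        ok = check(df[col])
        if not ok.all():
            bad = df.index[~ok] + 2
            raise SchemaError(
                f"{path}: column {col!r}: {int((~ok).sum())} row(s) violate '{desc}', "
                f"first at line(s) {list(bad[:5])}"
            )
    return df


def _write(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# domain-object loaders


def load_grid(path: str | Path) -> list[GridSeries]:
    df = read_table(path, "grid")
    out = []
    for cell_id, sub in df.groupby("cell_id", sort=True):
        lat, lon = sub["lat"].iloc[0], sub["lon"].iloc[0]
        if sub["lat"].nunique() > 1 or sub["lon"].nunique() > 1:
            raise SchemaError(f"cell {cell_id}: inconsistent centroid coordinates")
        out.append(
            GridSeries(
                cell_id=str(cell_id),
                centroid=GeoPoint(float(lat), float(lon)),
                values=dict(zip(sub["date"], sub["value"].astype(float))),
                ses=dict(zip(sub["date"], sub["se"].astype(float))),
            )
        )
    return out


def load_block_groups(path: str | Path) -> list[BlockGroup]:
    df = read_table(path, "bg")
    return [
        BlockGroup(
            geoid=row.geoid,
            centroid=GeoPoint(float(row.lat), float(row.lon)),
            population=int(row.population),
        )
        for row in df.itertuples()
    ]


def load_bg_estimates(path: str | Path) -> list[BGEstimateSeries]:
    df = read_table(path, "bg_est")
    out = []
    for geoid, sub in df.groupby("geoid", sort=True):
        out.append(
            BGEstimateSeries(
                bg_geoid=str(geoid),
                estimates={
                    d: (float(m), float(dl))
                    for d, m, dl in zip(sub["date"], sub["mu"], sub["delta"])
                },
            )
        )
    return out


def load_stations(path: str | Path) -> list[StationObservation]:
    df = read_table(path, "stations")
    has_ur = "urban_rural" in df.columns
    out = []
    for row in df.itertuples():
        ur = getattr(row, "urban_rural", None) if has_ur else None
        if isinstance(ur, float) and np.isnan(ur):
            ur = None
        if ur is not None and not isinstance(ur, str):
            ur = None
        out.append(
            StationObservation(
                station_id=row.station_id,
                bg_geoid=row.bg_geoid,
                date=row.date,
                observed=float(row.observed),
                urban_rural=ur,
            )
        )
    return out


# ---------------------------------------------------------------------------
# writers


def write_grid(grid: list[GridSeries], path: str | Path) -> None:
    rows = [
        {
            "cell_id": g.cell_id,
            "lat": g.centroid.lat,
            "lon": g.centroid.lon,
            "date": d,
            "value": g.values[d],
            "se": g.ses[d],
        }
        for g in grid
        for d in g.dates()
    ]
    _write(pd.DataFrame(rows), path)


def write_block_groups(bgs: list[BlockGroup], path: str | Path) -> None:
    rows = [
        {"geoid": b.geoid, "lat": b.centroid.lat, "lon": b.centroid.lon, "population": b.population}
        for b in bgs
    ]
    _write(pd.DataFrame(rows), path)


def write_bg_estimates(series: list[BGEstimateSeries], path: str | Path) -> None:
    rows = [
        {"geoid": s.bg_geoid, "date": d, "mu": s.estimates[d][0], "delta": s.estimates[d][1]}
        for s in series
        for d in s.dates()
    ]
    _write(pd.DataFrame(rows), path)


def write_stations(stations: list[StationObservation], path: str | Path) -> None:
    rows = [
        {
            "station_id": s.station_id,
            "bg_geoid": s.bg_geoid,
            "date": s.date,
            "observed": s.observed,
            "urban_rural": s.urban_rural or "",
        }
        for s in stations
    ]
    _write(pd.DataFrame(rows), path)


def write_exposures(series: list[CGUExposureSeries], path: str | Path) -> None:
    rows = [
        {
            "geoid": s.geoid,
            "level": s.level,
            "date": d,
            "pe": s.exposures[d][0],
            "psi": s.exposures[d][1],
            "population": s.population,
        }
        for s in series
        for d in sorted(s.exposures)
    ]
    _write(pd.DataFrame(rows), path)


def write_truth(bg_truth: dict[str, dict[str, float]], path: str | Path) -> None:
    rows = [
        {"bg_geoid": g, "date": d, "truth": v}
        for g, days in bg_truth.items()
        for d, v in sorted(days.items())
    ]
    _write(pd.DataFrame(rows), path)


def write_frame(df: pd.DataFrame, path: str | Path) -> None:
    """Write an arbitrary report table with the package float format."""
    _write(df, path)
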