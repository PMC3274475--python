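from pathlib import Path

import pytest

from gridshed.geodesy import GeoPoint
from gridshed.synthetic import SimConfig, generate_dataset

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(
        n_rows=6,
        n_cols=6,
        spacing_km=36.0,
        origin=GeoPoint(38.0, -90.0),
        n_days=20,
        n_bgs=36,
        n_states=3,
        counties_per_state=2,
        tracts_per_county=2,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    """(grid, bgs, stations, truth) for a 6x6 lattice, 36 BGs, 20 days."""
    return generate_dataset(small_cfg)


@pytest.fixture
def geodesic_oracle_path() -> Path:
    return DATA_DIR / "geodesic_oracle.csv"
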