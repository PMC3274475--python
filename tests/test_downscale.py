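import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gridshed.downscale import (
    BGEstimateSeries,
    GridSeries,
    compute_weights,
    downscale_all,
    estimate_bg_day,
    estimate_bg_day_se,
    find_nearest_grids,
)
from gridshed.aggregate import BlockGroup
from gridshed.errors import CalendarError, GridshedError
from gridshed.geodesy import GeoPoint, vincenty_distance


def _cell(cell_id, lat, lon, dates=("2006-01-01",), value=10.0, se=1.0):
    return GridSeries(
        cell_id=cell_id,
        centroid=GeoPoint(lat, lon),
        values={d: value for d in dates},
        ses={d: se for d in dates},
    )


def _lattice(n_rows=4, n_cols=4, step=0.3, lat0=38.0, lon0=-90.0, **kw):
    cells = []
    for r in range(n_rows):
        for c in range(n_cols):
            cells.append(_cell(f"g{r}{c}", lat0 + r * step, lon0 + c * step, **kw))
    return cells


class TestFindNearestGrids:
    def test_point_inside_cell_gets_bounding_four(self):
        # 4x4 lattice; a point inside the square spanned by rows 1-2 and
        # cols 1-2 must pick exactly those four corner centroids
        cells = _lattice()
        point = GeoPoint(38.0 + 1.4 * 0.3, -90.0 + 1.6 * 0.3)
        got = {cid for cid, _ in find_nearest_grids(point, cells, k=4)}
        assert got == {"g11", "g12", "g21", "g22"}

    def test_coincident_centroid_first_with_zero_distance(self):
        cells = _lattice()
        got = find_nearest_grids(GeoPoint(38.3, -89.7), cells, k=4)
        assert got[0] == ("g11", 0.0)

    def test_tie_break_lexicographic(self):
        # 5 cells: 4 equidistant on a cross plus one farther; only 4 slots.
        # Make all four cross arms exactly symmetric in longitude.
        cells = [
            _cell("e_west", 38.0, -90.1),
            _cell("a_east", 38.0, -89.9),
            _cell("c_far", 39.5, -90.0),
            _cell("b_east2", 38.0, -89.9),  # duplicate location, distinct id
            _cell("d_west2", 38.0, -90.1),
        ]
        got = find_nearest_grids(GeoPoint(38.0, -90.0), cells, k=4)
        # equidistant entries sorted by cell_id
        assert [cid for cid, _ in got] == ["a_east", "b_east2", "d_west2", "e_west"]

    def test_distances_nondecreasing(self):
        cells = _lattice()
        got = find_nearest_grids(GeoPoint(38.1, -89.8), cells, k=6)
        ds = [d for _, d in got]
        assert ds == sorted(ds)

    def test_too_few_cells(self):
        with pytest.raises(GridshedError, match="3 cells"):
            find_nearest_grids(GeoPoint(38, -90), _lattice(1, 3), k=4)

    @pytest.mark.parametrize("seed", range(20))
    def test_index_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        cells = _lattice(10, 10, step=0.33)
        point = GeoPoint(38.0 + rng.uniform(0, 9 * 0.33), -90.0 + rng.uniform(0, 9 * 0.33))
        assert find_nearest_grids(point, cells, 4, method="index") == \
            find_nearest_grids(point, cells, 4, method="brute")


class TestComputeWeights:
    def test_equal_distances(self):
        np.testing.assert_allclose(compute_weights([10, 10, 10, 10]), [0.25] * 4)

    def test_direct_substitution(self):
        np.testing.assert_allclose(
            compute_weights([1, 2, 2, 2]), [4 / 7, 1 / 7, 1 / 7, 1 / 7], rtol=1e-15
        )

    def test_zero_distance_takes_all(self):
        np.testing.assert_allclose(compute_weights([0, 5, 7, 9]), [1, 0, 0, 0])

    def test_two_zero_distances_split(self):
        np.testing.assert_allclose(compute_weights([0, 0, 7, 9]), [0.5, 0.5, 0, 0])

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            compute_weights([1, -1, 2, 3])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            compute_weights([0, 0, 0, 0])

    @settings(max_examples=100, deadline=None)
    @given(
        d=st.lists(st.floats(min_value=0.01, max_value=1e4), min_size=4, max_size=4),
        scale=st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_sum_one_and_scale_invariance(self, d, scale):
        w = compute_weights(d)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all((w >= 0) & (w <= 1))
        np.testing.assert_allclose(w, compute_weights([x * scale for x in d]), rtol=1e-9)


class TestEstimateBgDay:
    def test_equal_weights(self):
        assert estimate_bg_day([0.25] * 4, [10, 20, 30, 40]) == pytest.approx(25.0)

    def test_constant_field(self):
        w = compute_weights([1, 3, 5, 7])
        assert estimate_bg_day(w, [7.7] * 4) == pytest.approx(7.7)

    def test_degenerate_weight(self):
        assert estimate_bg_day([1, 0, 0, 0], [13, 99, 99, 99]) == pytest.approx(13.0)

    def test_non_finite_value_rejected(self):
        with pytest.raises(ValueError):
            estimate_bg_day([0.25] * 4, [1, 2, float("nan"), 4])

    @settings(max_examples=100, deadline=None)
    @given(
        d=st.lists(st.floats(min_value=0.01, max_value=100), min_size=4, max_size=4),
        p=st.lists(st.floats(min_value=-50, max_value=150), min_size=4, max_size=4),
    )
    def test_convexity(self, d, p):
        mu = estimate_bg_day(compute_weights(d), p)
        assert min(p) - 1e-9 <= mu <= max(p) + 1e-9


class TestEstimateBgDaySe:
    def test_equal_weights_sigma_two(self):
        # delta^2 = 4 * (1/16) * 4 = 1
        assert estimate_bg_day_se([0.25] * 4, [2, 2, 2, 2]) == pytest.approx(1.0)

    def test_degenerate_weight(self):
        assert estimate_bg_day_se([1, 0, 0, 0], [3, 9, 9, 9]) == pytest.approx(3.0)

    def test_zero_noise(self):
        assert estimate_bg_day_se([0.25] * 4, [0, 0, 0, 0]) == 0.0

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            estimate_bg_day_se([0.25] * 4, [1, -1, 1, 1])

    def test_bounded_by_max_sigma(self):
        w = compute_weights([1, 2, 3, 4])
        s = [1.0, 5.0, 2.0, 3.0]
        assert estimate_bg_day_se(w, s) <= max(s)

    def test_monotone_in_sigma(self):
        w = compute_weights([1, 2, 3, 4])
        base = estimate_bg_day_se(w, [1, 1, 1, 1])
        for i in range(4):
            s = [1.0, 1.0, 1.0, 1.0]
            s[i] = 2.0
            assert estimate_bg_day_se(w, s) >= base


def _bg(geoid, lat, lon, pop=1000):
    return BlockGroup(geoid=geoid, centroid=GeoPoint(lat, lon), population=pop)


class TestDownscaleAll:
    DATES = ("2006-01-01", "2006-01-02", "2006-01-03")

    def test_constant_field(self):
        cells = _lattice(dates=self.DATES, value=42.0, se=0.5)
        bgs = [_bg("130890212001", 38.4, -89.5), _bg("130890212002", 38.7, -89.2)]
        for s in downscale_all(cells, bgs):
            for d in self.DATES:
                assert s.estimates[d][0] == pytest.approx(42.0, rel=1e-9)

    def test_coincident_bg_reproduces_cell_series(self):
        rng = np.random.default_rng(3)
        cells = _lattice(dates=self.DATES)
        target = cells[5]  # g11
        for d in self.DATES:
            target.values[d] = float(rng.uniform(5, 50))
            target.ses[d] = float(rng.uniform(0.1, 2))
        bgs = [_bg("130890212001", target.centroid.lat, target.centroid.lon)]
        (series,) = downscale_all(cells, bgs)
        for d in self.DATES:
            assert series.estimates[d] == pytest.approx((target.values[d], target.ses[d]))

    def test_matches_brute_force_oracle(self):
        """50 random BGs on a 10x10 lattice vs all-pairs nearest-4 oracle."""
        rng = np.random.default_rng(11)
        dates = [f"2006-01-{i + 1:02d}" for i in range(5)]
        cells = _lattice(10, 10, step=0.33, dates=dates)
        for c in cells:
            for d in dates:
                c.values[d] = float(rng.uniform(0, 60))
                c.ses[d] = float(rng.uniform(0.05, 3))
        bgs = [
            _bg(f"{i + 1:012d}",
                38.0 + rng.uniform(0, 9 * 0.33), -90.0 + rng.uniform(0, 9 * 0.33))
            for i in range(50)
        ]
        result = {s.bg_geoid: s for s in downscale_all(cells, bgs)}
        for bg in bgs:
            # oracle: brute-force distances, direct formulas
            dists = [(vincenty_distance(bg.centroid, c.centroid), c.cell_id, c) for c in cells]
            dists.sort(key=lambda t: (t[0], t[1]))
            top = dists[:4]
            inv = [1.0 / t[0] ** 2 for t in top]
            w = [x / sum(inv) for x in inv]
            for d in dates:
                mu = sum(wi * t[2].values[d] for wi, t in zip(w, top))
                delta = math.sqrt(sum(wi**2 * t[2].ses[d] ** 2 for wi, t in zip(w, top)))
                got = result[bg.geoid].estimates[d]
                assert got[0] == pytest.approx(mu, rel=1e-12)
                assert got[1] == pytest.approx(delta, rel=1e-12)

    def test_calendar_gap_rejected(self):
        cells = _lattice(dates=("2006-01-01", "2006-01-03"))
        with pytest.raises(CalendarError, match="gaps"):
            downscale_all(cells, [_bg("130890212001", 38.4, -89.5)])

    def test_mismatched_calendars_rejected(self):
        cells = _lattice(dates=self.DATES)
        cells[0] = _cell("g00", 38.0, -90.0, dates=("2006-01-01",))
        with pytest.raises(CalendarError):
            downscale_all(cells, [_bg("130890212001", 38.4, -89.5)])

    def test_convexity_on_random_field(self):
        rng = np.random.default_rng(5)
        dates = self.DATES
        cells = _lattice(6, 6, dates=dates)
        for c in cells:
            for d in dates:
                c.values[d] = float(rng.uniform(0, 100))
        bgs = [_bg(f"{i + 1:012d}", 38.0 + rng.uniform(0, 1.5), -90.0 + rng.uniform(0, 1.5))
               for i in range(20)]
        cell_by_id = {c.cell_id: c for c in cells}
        for s in downscale_all(cells, bgs):
            bg = next(b for b in bgs if b.geoid == s.bg_geoid)
            nbrs = find_nearest_grids(bg.centroid, cells, 4)
            for d in dates:
                vals = [cell_by_id[cid].values[d] for cid, _ in nbrs]
                assert min(vals) - 1e-9 <= s.estimates[d][0] <= max(vals) + 1e-9
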