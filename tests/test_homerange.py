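import datetime as dt

import numpy as np
import pandas as pd
import pytest

from paircohesion import (
    MovementConfig,
    PeriodSplit,
    UtilizationDistribution,
    bhattacharyya,
    estimate_ud,
    home_range_area,
    simulate_pair_tracks,
    split_and_summarize,
)
from paircohesion.errors import GridMismatchError, InsufficientDataError, InvalidParameterError
from paircohesion.homerange import GridSpec, common_grid


def uniform_ud(grid, cells):
    """UD with equal mass on the given (iy, ix) cells."""
    mass = np.zeros((grid.ny, grid.nx))
    for iy, ix in cells:
        mass[iy, ix] = 1.0
    return UtilizationDistribution(grid, mass / mass.sum())


class TestEstimateUD:
    def test_identical_points_concentrate_in_one_cell(self):
        pts = np.tile([55.0, 55.0], (50, 1))
        ud = estimate_ud(pts, bandwidth=1.0, cell_size=10.0)
        assert ud.mass.max() >= 0.99

    def test_mass_normalized_for_random_points(self):
        rng = np.random.default_rng(0)
        ud = estimate_ud(rng.normal(0, 40, size=(300, 2)))
        assert ud.mass.sum() == pytest.approx(1.0, abs=1e-9)
        assert (ud.mass >= 0).all()

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            estimate_ud(np.zeros((5, 2)))

    def test_matches_statsmodels_kde_cross_check(self):
        # independent oracle: statsmodels' product-Gaussian KDE on the same grid
        from statsmodels.nonparametric.kernel_density import KDEMultivariate

        rng = np.random.default_rng(1)
        pts = rng.normal(0, 50, size=(400, 2))
        bw = 20.0
        grid = GridSpec(-200.0, -200.0, 10.0, 40, 40)
        ud = estimate_ud(pts, bandwidth=bw, grid=grid)
        kde = KDEMultivariate(data=pts, var_type="cc", bw=[bw, bw])
        cx, cy = grid.centers()
        gx, gy = np.meshgrid(cx, cy)
        ref = kde.pdf(np.column_stack([gx.ravel(), gy.ravel()])).reshape(grid.ny, grid.nx)
        ref = ref / ref.sum()
        assert np.abs(ud.mass - ref).max() < 1e-9


class TestHomeRangeArea:
    def test_gaussian_isopleth_matches_closed_form(self):
        # 95% region of an isotropic Gaussian has area pi*sigma^2*chi2_0.95(2)
        rng = np.random.default_rng(2)
        sigma = 50.0
        pts = rng.normal(0, sigma, size=(5000, 2))
        ud = estimate_ud(pts, cell_size=5.0)
        area = home_range_area(ud, level=0.95)
        expected = np.pi * sigma**2 * 5.99 / 1e6
        assert area == pytest.approx(expected, rel=0.15)

    def test_uniform_mass_cell_count(self):
        grid = GridSpec(0.0, 0.0, 10.0, 10, 4)
        k = 40
        ud = uniform_ud(grid, [(iy, ix) for iy in range(4) for ix in range(10)])
        area = home_range_area(ud, level=0.95)
        assert area == pytest.approx(np.ceil(0.95 * k) * 100 / 1e6)

    def test_level_one_covers_all_positive_cells(self):
        grid = GridSpec(0.0, 0.0, 10.0, 5, 5)
        ud = uniform_ud(grid, [(0, 0), (1, 1), (2, 2)])
        assert home_range_area(ud, level=1.0) == pytest.approx(3 * 100 / 1e6)

    def test_area_non_decreasing_in_level(self):
        rng = np.random.default_rng(3)
        ud = estimate_ud(rng.normal(0, 30, size=(500, 2)))
        areas = [home_range_area(ud, lv) for lv in (0.5, 0.8, 0.95, 1.0)]
        assert areas == sorted(areas)

    def test_invalid_level(self):
        grid = GridSpec(0.0, 0.0, 10.0, 2, 2)
        ud = uniform_ud(grid, [(0, 0)])
        with pytest.raises(InvalidParameterError):
            home_range_area(ud, level=1.5)


class TestBhattacharyya:
    def test_self_overlap_is_one(self):
        rng = np.random.default_rng(4)
        ud = estimate_ud(rng.normal(0, 30, size=(200, 2)))
        assert bhattacharyya(ud, ud) == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_supports_give_zero(self):
        grid = GridSpec(0.0, 0.0, 10.0, 10, 10)
        a = uniform_ud(grid, [(0, 0), (0, 1)])
        b = uniform_ud(grid, [(9, 8), (9, 9)])
        assert bhattacharyya(a, b) == 0.0

    def test_half_overlapping_uniforms_give_half(self):
        grid = GridSpec(0.0, 0.0, 10.0, 10, 20)
        a = uniform_ud(grid, [(iy, ix) for iy in range(10) for ix in range(10)])
        b = uniform_ud(grid, [(iy, ix) for iy in range(5, 15) for ix in range(10)])
        assert bhattacharyya(a, b) == pytest.approx(0.5, abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        grid = GridSpec(-150.0, -150.0, 10.0, 30, 30)
        a = estimate_ud(rng.normal(0, 30, size=(200, 2)), bandwidth=20.0, grid=grid)
        b = estimate_ud(rng.normal(20, 30, size=(200, 2)), bandwidth=20.0, grid=grid)
        assert bhattacharyya(a, b) == pytest.approx(bhattacharyya(b, a), abs=1e-14)
        assert 0.0 <= bhattacharyya(a, b) <= 1.0

    def test_grid_mismatch_rejected(self):
        a = uniform_ud(GridSpec(0.0, 0.0, 10.0, 5, 5), [(0, 0)])
        b = uniform_ud(GridSpec(5.0, 0.0, 10.0, 5, 5), [(0, 0)])
        with pytest.raises(GridMismatchError):
            bhattacharyya(a, b)

    def test_stable_under_finer_regridding(self):
        # BC is a discretized integral: halving the cell size barely moves it
        rng = np.random.default_rng(6)
        pa = rng.normal(0, 60, size=(400, 2))
        pb = rng.normal(30, 60, size=(400, 2))
        bw = 60.0
        bcs = []
        for cell in (8.0, 4.0):
            grid = common_grid(pa, pb, bw, cell_size=cell)
            ua = estimate_ud(pa, bandwidth=bw, grid=grid)
            ub = estimate_ud(pb, bandwidth=bw, grid=grid)
            bcs.append(bhattacharyya(ua, ub))
        assert abs(bcs[0] - bcs[1]) < 1e-3

    def test_pair_bc_monotone_in_coupling(self):
        # territory centers 100 m apart: only following can merge space use
        means = {}
        for coupling in (0.2, 0.9):
            bcs = []
            for seed in range(20):
                cfg = MovementConfig(
                    centers={"A": (0.0, 0.0), "B": (100.0, 0.0)},
                    coupling=coupling,
                    follow_lag_mean=60.0,
                )
                ta, tb = simulate_pair_tracks(cfg, duration=1000 * 15.0, seed=seed)
                grid = common_grid(ta.xy, tb.xy, 30.0, cell_size=10.0)
                ua = estimate_ud(ta.xy, bandwidth=30.0, grid=grid)
                ub = estimate_ud(tb.xy, bandwidth=30.0, grid=grid)
                bcs.append(bhattacharyya(ua, ub))
            means[coupling] = np.mean(bcs)
        assert means[0.9] > means[0.2]


class TestSplitAndSummarize:
    @staticmethod
    def _split(days=14, start=dt.date(2023, 9, 7), breeding_end=dt.date(2023, 9, 14)):
        sunrise = {
            start + dt.timedelta(days=i): dt.datetime(
                2023, 9, 7 + 0, 6, tzinfo=dt.timezone.utc
            ).timestamp()
            + i * 86400.0
            for i in range(days)
        }
        return PeriodSplit(week1_start=start, breeding_end=breeding_end, sunrise_s=sunrise)

    def test_section_boundary_half_open(self):
        split = self._split()
        sunrise = next(iter(split.sunrise_s.values()))
        out = split.assign(np.array([sunrise + 3 * 3600.0]))
        assert out["section"].iloc[0] == 2  # exactly +3 h -> second section

    def test_twelve_individuals_make_66_dyads(self):
        split = self._split(days=7, breeding_end=dt.date(2023, 10, 1))
        rng = np.random.default_rng(7)
        sunrise = next(iter(split.sunrise_s.values()))
        frames, meta = [], []
        for i in range(12):
            pts = rng.normal(i * 50.0, 20.0, size=(30, 2))
            frames.append(
                pd.DataFrame(
                    {
                        "tag_id": f"T{i:02d}",
                        "window_start": sunrise + np.arange(30) * 15.0,
                        "x": pts[:, 0],
                        "y": pts[:, 1],
                    }
                )
            )
            meta.append({"tag_id": f"T{i:02d}", "sex": "FM"[i % 2], "pair_id": f"P{i // 2}"})
        areas, dyads = split_and_summarize(
            pd.concat(frames, ignore_index=True), pd.DataFrame(meta), split
        )
        assert len(dyads) == 66  # C(12, 2)
        assert (dyads["dyad_type"] == "pair_bonded").sum() == 6
        assert len(areas) == 12

    def test_periods_split_at_breeding_end(self):
        split = self._split(days=14, breeding_end=dt.date(2023, 9, 14))
        t0 = next(iter(split.sunrise_s.values()))
        times = np.concatenate([t0 + np.arange(20) * 15.0, t0 + 10 * 86400.0 + np.arange(20) * 15.0])
        est = pd.DataFrame(
            {"tag_id": "T0", "window_start": times, "x": np.zeros(40), "y": np.zeros(40)}
        )
        meta = pd.DataFrame([{"tag_id": "T0", "sex": "F", "pair_id": "P0"}])
        areas, _ = split_and_summarize(est, meta, split)
        assert set(areas["period"]) == {"breeding", "post_breeding"}
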