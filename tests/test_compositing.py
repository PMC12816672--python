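import numpy as np
import pandas as pd
import pytest

from floatscan.compositing import (
    AreaSeries,
    DensityGrid,
    ZoneMask,
    aggregate_areas,
    area_series_from_grids,
    composite,
    integrate_area,
    niche_footprint,
)
from floatscan.unmixing import Detection


def make_detection(chi, observed=None, legend=("trichodesmium",)):
    chi = np.asarray(chi, dtype=float)
    mask = chi > 0
    types = np.where(mask, 0, -1).astype(np.int16)
    return Detection(
        mask=mask,
        chi=chi,
        fa_type=types,
        similarity=np.where(mask, 1.0, np.nan),
        type_legend=legend,
        observed=observed,
    )


class TestComposite:
    def test_single_detection_identity(self):
        chi = np.zeros((4, 4))
        chi[1, 1] = 0.3
        grid = composite([make_detection(chi)], period=(2003, 6))
        np.testing.assert_allclose(grid.grid, chi)
        assert (grid.n_obs == 1).all()

    def test_mean_of_two(self):
        a = np.zeros((4, 4)); a[0, 0] = 0.2
        b = np.zeros((4, 4)); b[0, 0] = 0.4
        grid = composite([make_detection(a), make_detection(b)], period=(2003, 6))
        assert grid.grid[0, 0] == pytest.approx(0.3)

    def test_invalid_observations_excluded_from_denominator(self):
        chi = np.zeros((4, 4)); chi[2, 2] = 0.3
        obs_off = np.zeros((4, 4), bool)
        dets = [
            make_detection(chi),
            make_detection(np.zeros((4, 4)), observed=obs_off),
            make_detection(np.zeros((4, 4)), observed=obs_off),
        ]
        grid = composite(dets, period=(2003, 7))
        assert grid.grid[2, 2] == pytest.approx(0.3)
        assert grid.n_obs[2, 2] == 1

    def test_never_observed_cell_is_nan(self):
        obs = np.ones((4, 4), bool); obs[3, 3] = False
        grid = composite([make_detection(np.zeros((4, 4)), observed=obs)], period=(2003,))
        assert np.isnan(grid.grid[3, 3])
        assert grid.n_obs[3, 3] == 0

    def test_by_type_filter(self):
        chi = np.zeros((4, 4)); chi[0, 0] = 0.5; chi[1, 1] = 0.25
        det = make_detection(chi, legend=("trichodesmium", "ulva_prolifera"))
        det.fa_type[1, 1] = 1  # second pixel is ulva
        g = composite([det], period=(2003, 6), fa_type="ulva_prolifera")
        assert g.grid[1, 1] == 0.25
        assert g.grid[0, 0] == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            composite([], period=(2003, 6))


class TestIntegrateArea:
    def test_uniform_product(self):
        grid = DensityGrid(
            grid=np.full((10, 10), 0.01), n_obs=np.ones((10, 10), int), period=(2003,),
            cell_area=1.0,
        )
        assert integrate_area(grid) == pytest.approx(1.0)

    def test_empty_grid_zero(self):
        grid = DensityGrid(
            grid=np.full((5, 5), np.nan), n_obs=np.zeros((5, 5), int), period=(2003,)
        )
        assert integrate_area(grid) == 0.0

    def test_zone_restriction(self):
        grid = DensityGrid(
            grid=np.full((4, 4), 0.5), n_obs=np.ones((4, 4), int), period=(2003,)
        )
        zone = ZoneMask(zone_id=1, mask=np.eye(4, dtype=bool))
        assert integrate_area(grid, zone) == pytest.approx(2.0)

    def test_per_row_cell_areas(self):
        grid = DensityGrid(
            grid=np.full((2, 3), 1.0), n_obs=np.ones((2, 3), int), period=(2003,),
            cell_area=np.array([1.0, 2.0]),
        )
        assert integrate_area(grid) == pytest.approx(3 * 1.0 + 3 * 2.0)

    def test_generator_bookkeeping_recovered(self, library, clean_scene):
        from floatscan.unmixing import quantify_scene

        det = quantify_scene(clean_scene, clean_scene.truth.fa_mask, library)
        grid = composite([det], period=(2003, 6), cell_area=clean_scene.pixel_area)
        assert integrate_area(grid) == pytest.approx(clean_scene.truth_area_km2(), rel=1e-9)


class TestNicheFootprint:
    def grids(self, *cells, shape=(6, 6)):
        out = []
        for cell_list in cells:
            g = np.zeros(shape)
            for (r, c, v) in cell_list:
                g[r, c] = v
            out.append(
                DensityGrid(grid=g, n_obs=np.ones(shape, int), period=(2003,), cell_area=2.0)
            )
        return out

    def test_disjoint_union(self):
        fp, area = niche_footprint(self.grids([(0, 0, 0.1)], [(5, 5, 0.2)]))
        assert fp.sum() == 2
        assert area == pytest.approx(4.0)

    def test_idempotent_union(self):
        fp, area = niche_footprint(self.grids([(2, 2, 0.1)], [(2, 2, 0.5)], [(2, 2, 0.9)]))
        assert fp.sum() == 1
        assert area == pytest.approx(2.0)

    def test_monotone_in_periods(self):
        grids = self.grids([(0, 0, 0.1)], [(1, 1, 0.1)], [(2, 2, 0.1)])
        areas = [niche_footprint(grids[: k + 1])[1] for k in range(3)]
        assert areas == sorted(areas)

    def test_threshold_excludes_weak_cells(self):
        fp, area = niche_footprint(self.grids([(0, 0, 0.005), (1, 1, 0.5)]), threshold=0.01)
        assert fp.sum() == 1

    def test_inconsistent_shapes_rejected(self):
        a = self.grids([(0, 0, 0.1)])[0]
        b = DensityGrid(grid=np.zeros((3, 3)), n_obs=np.ones((3, 3), int), period=(2004,))
        with pytest.raises(ValueError):
            niche_footprint([a, b])


class TestAggregateAreas:
    TABLE = [
        {"zone": 1, "fa_type": "a", "area": 1.5},
        {"zone": 1, "fa_type": "b", "area": 0.5},
        {"zone": 2, "fa_type": "a", "area": 2.0},
        {"zone": 3, "fa_type": "c", "area": 4.0},
    ]

    def test_total(self):
        assert aggregate_areas(self.TABLE) == pytest.approx(8.0)

    def test_type_filter(self):
        assert aggregate_areas(self.TABLE, fa_types=["a"]) == pytest.approx(3.5)

    def test_zone_filter(self):
        assert aggregate_areas(self.TABLE, zones=[1]) == pytest.approx(2.0)

    def test_joint_filter(self):
        assert aggregate_areas(self.TABLE, fa_types=["a"], zones=[1]) == pytest.approx(1.5)


class TestZoneConservation:
    def test_zone_sum_equals_global_when_tiling(self, rng):
        g = rng.uniform(0, 1, (8, 8))
        grid = DensityGrid(grid=g, n_obs=np.ones((8, 8), int), period=(2003,))
        zones = [
            ZoneMask(1, np.pad(np.ones((4, 8), bool), ((0, 4), (0, 0)))),
            ZoneMask(2, np.pad(np.ones((4, 8), bool), ((4, 0), (0, 0)))),
        ]
        total = sum(integrate_area(grid, z) for z in zones)
        assert total == pytest.approx(integrate_area(grid))


class TestAreaSeriesContainer:
    def test_duplicate_records_rejected(self):
        df = pd.DataFrame(
            {"year": [2003, 2003], "month": [1, 1], "fa_type": ["a", "a"],
             "zone": [1, 1], "area_km2": [1.0, 2.0]}
        )
        with pytest.raises(ValueError):
            AreaSeries(df)

    def test_negative_area_rejected(self):
        df = pd.DataFrame(
            {"year": [2003], "month": [1], "fa_type": ["a"], "zone": [1], "area_km2": [-1.0]}
        )
        with pytest.raises(ValueError):
            AreaSeries(df)

    def test_csv_round_trip(self, tmp_path):
        from floatscan.scenes import generate_area_series

        s = generate_area_series(24, 5.0, 1.0, 2.0, seed=3)
        path = tmp_path / "series.csv"
        s.to_csv(path)
        back = AreaSeries.from_csv(path)
        pd.testing.assert_frame_equal(back.frame, s.frame)

    def test_values_sums_zones_per_month(self):
        rows = []
        for z in (1, 2):
            rows.append({"year": 2003, "month": 1, "fa_type": "a", "zone": z, "area_km2": 2.0})
        s = AreaSeries(pd.DataFrame(rows))
        _, _, v = s.values(fa_type="a")
        assert v.tolist() == [4.0]

    def test_area_series_from_grids(self):
        g = DensityGrid(grid=np.full((4, 4), 0.5), n_obs=np.ones((4, 4), int), period=(2003, 1))
        series = area_series_from_grids({(2003, 1): g, (2003, 2): g})
        assert len(series) == 2
        assert set(series.frame["area_km2"]) == {8.0}
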