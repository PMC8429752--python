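"""Gridded range mapping: classification, areas, scenarios, trends."""

import numpy as np
import pandas as pd
import pytest

import coldrange as cr
from coldrange import InvalidInputError
from coldrange.range_mapper import CLASS_CODES, annual_etdd_grid


def simple_model(a=0.9, b=-0.005):
    return cr.FittedSurvivalModel(cr.ModelSpec("LTDD", "exponential"),
                                  {"a": a, "b": b}, 1.0, 0.0, 10, 0.0)


class TestClassification:
    @pytest.mark.parametrize(
        "survival,host,expected",
        [
            (0.05, 0.3, "permanent"),   # both boundaries inclusive
            (0.01, 0.9, "marginal"),
            (0.009, 0.9, "transient"),
            (0.049, 0.9, "marginal"),
            (0.2, 0.29, "masked"),      # host mask overrides climate
            (0.0, 0.0, "masked"),
        ],
    )
    def test_boundary_cases(self, survival, host, expected):
        ow = cr.classify_overwintering(np.array([[survival]]),
                                       cr.HostMask(np.array([[host]])))
        assert ow.labels()[0, 0] == expected

    def test_exhaustive_and_exclusive(self, rng):
        surv = rng.uniform(0, 1, size=(20, 20))
        host = cr.HostMask(rng.uniform(0, 1, size=(20, 20)))
        ow = cr.classify_overwintering(surv, host)
        assert set(np.unique(ow.owclass)) <= set(CLASS_CODES.values())
        # masked exactly where host < 0.3
        assert np.array_equal(ow.owclass == 9, host.presence_prob < 0.3)

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            cr.classify_overwintering(np.zeros((2, 2)), cr.HostMask(np.zeros((3, 2))))


class TestCellArea:
    def test_equator_value(self):
        assert cr.cell_area_km2(0.0) == pytest.approx(111.195**2, rel=1e-12)
        assert cr.cell_area_km2(0.0) == pytest.approx(12364.3, abs=0.5)

    def test_cos_scaling(self):
        assert cr.cell_area_km2(60.0) == pytest.approx(cr.cell_area_km2(0.0) / 2)
        assert cr.cell_area_km2(90.0) == pytest.approx(0.0, abs=1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidInputError):
            cr.cell_area_km2(91.0)


class TestArea:
    def make_map(self, surv, host=None, lats=None):
        n_lat, n_lon = surv.shape
        host = cr.HostMask(np.ones_like(surv) if host is None else host)
        return cr.classify_overwintering(
            surv, host,
            lats=np.zeros(n_lat) if lats is None else lats,
        )

    def test_empty_qualifying_set(self):
        ow = self.make_map(np.zeros((3, 3)))
        assert cr.overwinter_area(ow, 0.05) == (0, 0.0)

    def test_single_equator_cell(self):
        ow = self.make_map(np.array([[0.5]]))
        n, area = cr.overwinter_area(ow, 0.05)
        assert n == 1
        assert area == pytest.approx(12364.3, abs=0.5)

    def test_cutoff_nesting(self, rng):
        surv = rng.uniform(0, 0.2, size=(10, 10))
        host = rng.uniform(0, 1, size=(10, 10))
        ow = self.make_map(surv, host)
        n1, a1 = cr.overwinter_area(ow, 0.01)
        n5, a5 = cr.overwinter_area(ow, 0.05)
        assert n1 >= n5 and a1 >= a5

    def test_masked_cells_never_counted(self):
        surv = np.full((2, 2), 0.5)
        host = np.array([[1.0, 0.0], [1.0, 0.0]])
        ow = self.make_map(surv, host)
        assert cr.overwinter_area(ow, 0.05)[0] == 2


class TestLtddGrid:
    def test_uniform_warm_grid_is_zero(self):
        dates = pd.date_range("2000-01-01", "2001-06-30", freq="D")
        grid = cr.ClimateGrid(np.array([10.0, -10.0]), np.array([0.0]),
                              dates, np.full((2, 1, len(dates)), 20.0))
        assert np.all(cr.annual_ltdd_grid(grid, 2000) == 0.0)

    def test_matches_per_cell_scalar_oracle(self, toy_grid):
        got = cr.annual_ltdd_grid(toy_grid, 2004)
        for i in [0, 3, 7]:
            for j in [0, 4]:
                series = toy_grid.extract_series(i, j)
                window = cr.annual_window_for(series.latitude, 2004)
                expected = cr.ltdd(series, window)
                assert got[i, j] == pytest.approx(expected, abs=1e-9)

    def test_single_cell_grid_matches_site_pipeline(self):
        rng = np.random.default_rng(2)
        dates = pd.date_range("2000-01-01", "2001-06-30", freq="D")
        temps = rng.uniform(-10, 25, size=(1, 1, len(dates)))
        grid = cr.ClimateGrid(np.array([42.0]), np.array([5.0]), dates, temps)
        series = grid.extract_series(0, 0)
        site = cr.ltdd(series, cr.annual_window_for(42.0, 2000))
        assert cr.annual_ltdd_grid(grid, 2000)[0, 0] == pytest.approx(site, abs=1e-9)
        model = simple_model()
        surv = cr.survival_grid(cr.annual_ltdd_grid(grid, 2000), model)
        assert surv[0, 0] == pytest.approx(model.predict({"LTDD": site}))

    def test_etdd_grid_matches_site_oracle(self, toy_grid):
        got = annual_etdd_grid(toy_grid, 2004)
        series = toy_grid.extract_series(2, 1)
        assert got[2, 1] == pytest.approx(cr.etdd(series, 2004), abs=1e-9)


class TestScenario:
    def test_zero_delta_identical(self, toy_grid):
        warmed = cr.warming_scenario(toy_grid, 0.0)
        assert np.array_equal(warmed.tmean, toy_grid.tmean)

    def test_ltdd_monotone_in_warming(self, toy_grid):
        base = cr.annual_ltdd_grid(toy_grid, 2004)
        last = base
        for delta in (1.0, 2.0, 4.0):
            warmed = cr.annual_ltdd_grid(cr.warming_scenario(toy_grid, delta), 2004)
            assert np.all(warmed <= last + 1e-9)
            last = warmed

    def test_extreme_warming_removes_all_cold(self, toy_grid):
        warmed = cr.warming_scenario(toy_grid, 80.0)
        assert np.all(cr.annual_ltdd_grid(warmed, 2004) == 0.0)

    def test_area_nondecreasing_in_delta(self, toy_grid, toy_host):
        model = simple_model()
        areas = []
        for delta in (0.0, 2.0, 6.0):
            warmed = cr.warming_scenario(toy_grid, delta)
            surv = cr.survival_grid(cr.annual_ltdd_grid(warmed, 2004), model)
            ow = cr.classify_overwintering(surv, toy_host, lats=toy_grid.lats,
                                           lons=toy_grid.lons)
            areas.append(cr.overwinter_area(ow, 0.05)[1])
        assert areas == sorted(areas)


class TestExpansion:
    def test_baseline_versus_itself_is_zero(self, toy_grid, toy_host):
        df = cr.expansion_series(toy_grid, simple_model(), toy_host, 2001,
                                 years=[2001, 2004])
        base = df[df["year"] == 2001].iloc[0]
        assert base["delta_area_ge5_km2"] == 0.0
        assert base["delta_area_ge1_km2"] == 0.0

    def test_stationary_climate_yields_zero_changes(self):
        truth = cr.TruthParams(grid=cr.synthetic_data.GridTruth(
            warming_per_year=0.0, noise_sd=0.0))
        grid = cr.simulate_climate_grid(6, 3, 2001, 2006, truth=truth, seed=0)
        host = cr.HostMask(np.ones(grid.shape))
        df = cr.expansion_series(grid, simple_model(), host, 2001,
                                 years=[2001, 2002, 2005])
        assert np.allclose(df["delta_area_ge5_km2"], 0.0)
        assert np.allclose(df["delta_area_ge1_km2"], 0.0)

    def test_warming_trend_expands_in_expectation(self):
        truth = cr.TruthParams(grid=cr.synthetic_data.GridTruth(
            warming_per_year=0.4, noise_sd=0.5))
        grid = cr.simulate_climate_grid(10, 4, 2000, 2010, truth=truth, seed=8)
        host = cr.HostMask(np.ones(grid.shape))
        df = cr.expansion_series(grid, simple_model(), host, 2000)
        assert df["delta_area_ge5_km2"].iloc[-1] >= 0.0
        # later 5-year block mean at least matches the first
        blocks = df.groupby("block_start")["area_ge5_km2"].mean()
        assert blocks.iloc[-1] >= blocks.iloc[0]


class TestMarginalBeltTrend:
    def test_warming_gives_negative_ltdd_slope(self):
        truth = cr.TruthParams(grid=cr.synthetic_data.GridTruth(
            warming_per_year=0.3, noise_sd=0.5))
        grid = cr.simulate_climate_grid(12, 4, 2000, 2010, truth=truth, seed=4)
        host = cr.HostMask(np.ones(grid.shape))
        res = cr.marginal_belt_trend(grid, simple_model(), host, 2000)
        assert res["n_belt_cells"] >= 1
        assert res["slope_per_year"] < 0.0

    def test_single_cell_belt_equals_cell_trend(self):
        from scipy.stats import linregress

        truth = cr.TruthParams(grid=cr.synthetic_data.GridTruth(
            warming_per_year=0.2, noise_sd=0.3))
        grid = cr.simulate_climate_grid(12, 3, 2000, 2008, truth=truth, seed=9)
        host = cr.HostMask(np.ones(grid.shape))
        model = simple_model()
        res = cr.marginal_belt_trend(grid, model, host, 2000)
        surv0 = cr.survival_grid(cr.annual_ltdd_grid(grid, 2000), model)
        belt = (surv0 >= 0.01) & (surv0 < 0.05)
        if belt.sum() == 1:
            i, j = map(int, np.argwhere(belt)[0])
            ltdds = [cr.annual_ltdd_grid(grid, y)[i, j] for y in res["years"]]
            fit = linregress(res["years"], ltdds)
            assert res["slope_per_year"] == pytest.approx(fit.slope)
        else:
            # belt-mean trend equals mean of per-cell trends (OLS linearity)
            slopes = []
            for i, j in np.argwhere(belt):
                ltdds = [cr.annual_ltdd_grid(grid, y)[i, j] for y in res["years"]]
                slopes.append(linregress(res["years"], ltdds).slope)
            assert res["slope_per_year"] == pytest.approx(np.mean(slopes))


def test_grid_frame_round_trip(toy_grid):
    frame = toy_grid.to_frame()
    sub = frame[frame["date"] < "2000-03-01"]
    small = cr.ClimateGrid.from_frame(sub)
    assert small.shape == toy_grid.shape
    assert np.allclose(small.tmean, toy_grid.tmean[:, :, :60])
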