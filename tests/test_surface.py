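import dataclasses

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString

import citynox as cx
from citynox.simulate import TruthModel, simulate_concentrations
from citynox.surface import PredictionSurface, aggregate_seasons, make_grid, predict_surface

from test_features import toy_layout


class TestMakeGrid:
    def test_cell_count_arithmetic(self):
        grid = make_grid((0.0, 0.0, 1000.0, 1000.0), cell_size=50.0)
        assert (grid.nrows, grid.ncols) == (20, 20)
        assert grid.n_cells == 400
        assert not grid.has_partial_edge

    def test_partial_edge_cells_flagged(self):
        with pytest.warns(UserWarning, match="partial edge"):
            grid = make_grid((0.0, 0.0, 1010.0, 1000.0), cell_size=50.0)
        assert grid.ncols == 21
        assert grid.has_partial_edge

    def test_centers_offset_by_half_cell(self):
        grid = make_grid((0.0, 0.0, 200.0, 100.0), cell_size=50.0)
        xs, ys = grid.centers()
        assert xs[0] == 25.0 and xs[-1] == 175.0
        assert ys[0] == 75.0 and ys[-1] == 25.0  # row 0 is northernmost

    @pytest.mark.parametrize("cell", [0.0, -10.0])
    def test_invalid_cell_size(self, cell):
        with pytest.raises(ValueError):
            make_grid((0.0, 0.0, 100.0, 100.0), cell_size=cell)


def _fit_on_toy(layout, predictors, response_fn, seed=0, n_weeks=8):
    """Fit a small mixed model on samples drawn at random toy-layout sites."""
    met = cx.generate_meteorology(seed + 1, n_weeks=n_weeks)
    design = cx.SamplingDesign.generate(seed + 2, layout, list(met.index),
                                        n_fixed=6, n_rotating=30)
    truth = TruthModel.default()
    truth = TruthModel(
        no2=dataclasses.replace(truth.no2, spatial=response_fn, sd_site=1.0,
                                sd_week=1.0, sd_resid=2.0),
        no=dataclasses.replace(truth.no, spatial={}, sd_site=1.0, sd_week=1.0,
                               sd_resid=2.0),
    )
    sim = simulate_concentrations(truth, layout, design, met, seed=seed + 3)
    from citynox.pipeline import build_analysis_table
    data = build_analysis_table(sim, design)
    fit = cx.CrossedLMM.from_dataframe(data, "no2", predictors).fit()
    return fit, met


class TestPredictSurface:
    def test_uniform_layout_gives_constant_layers(self):
        """No roads, constant NDVI: predictions vary by week but not in space
        for a model whose only spatial predictor is NDVI."""
        lay = toy_layout(extent=(0.0, 0.0, 3000.0, 3000.0), ndvi_value=0.3)
        # NDVI is constant, so simulate with a wind-only model fitted on it
        fit, met = _fit_on_toy(lay, ["wind_speed"], {})
        grid = make_grid(lay.extent, cell_size=500.0)
        surf = predict_surface(fit, grid, lay, met, list(met.index))
        for k in range(len(surf.weeks)):
            layer = surf.weekly[k]
            assert layer.max() - layer.min() < 1e-8

    def test_road_raises_predictions_only_near_road(self, small_layout, met52,
                                                    analysis_data):
        """Twin layouts differing by one major road: a positive road-length
        coefficient raises predictions only within the buffer footprint."""
        fit = cx.CrossedLMM.from_dataframe(
            analysis_data, "no2", ["major_road_length_100"]
        ).fit()
        assert fit.params["major_road_length_100"] > 0
        base = toy_layout(extent=(0.0, 0.0, 2000.0, 2000.0))
        road = LineString([(500.0, 0.0), (500.0, 2000.0)])
        twin = toy_layout(
            extent=(0.0, 0.0, 2000.0, 2000.0),
            roads=[{"geometry": road, "road_class": "major"}],
        )
        grid = make_grid(base.extent, cell_size=200.0)
        week = [met52.index[0]]
        s_base = predict_surface(fit, grid, base, met52, week)
        s_twin = predict_surface(fit, grid, twin, met52, week)
        diff = s_twin.weekly_raw[0] - s_base.weekly_raw[0]
        xs, _ = grid.centers()
        near = np.abs(xs - 500.0) <= 100.0  # columns whose buffer reaches the road
        assert (diff[:, near] > 0).all()
        assert np.allclose(diff[:, ~near], 0.0, atol=1e-9)

    def test_flooring_never_increases(self, small_layout, met52, analysis_data):
        fit = cx.CrossedLMM.from_dataframe(
            analysis_data, "no2", ["major_road_length_100", "wind_speed"]
        ).fit()
        grid = make_grid((0.0, 0.0, 2000.0, 2000.0), cell_size=500.0)
        surf = predict_surface(fit, grid, small_layout, met52, list(met52.index[:4]))
        assert (surf.weekly >= surf.weekly_raw - 1e-12).all()
        assert (surf.weekly >= 0.0).all()

    def test_missing_meteorology_week_skipped(self, small_layout, met52, no2_fit):
        grid = make_grid((0.0, 0.0, 2000.0, 2000.0), cell_size=1000.0)
        with pytest.warns(UserWarning, match="skipped"):
            surf = predict_surface(
                no2_fit, grid, small_layout, met52, [met52.index[0], "2030-W01"]
            )
        assert surf.weeks == [met52.index[0]]


def synthetic_surface(values_by_week: dict[str, float], nrows=4, ncols=5) -> PredictionSurface:
    """Surface with spatially constant weekly layers (synthetic stand-in)."""
    grid = make_grid((0.0, 0.0, ncols * 50.0, nrows * 50.0), cell_size=50.0)
    weeks = list(values_by_week)
    weekly = np.stack([np.full((nrows, ncols), v) for v in values_by_week.values()])
    return PredictionSurface(grid=grid, weeks=weeks, weekly=weekly,
                             weekly_raw=weekly.copy(), n_floored=0)


class TestAggregateSeasons:
    # 2019-W02 (Jan) and 2019-W48 (Nov) are Harmattan; W24/W28 (Jun/Jul) wet
    def test_identical_layers_identical_aggregates(self):
        surf = synthetic_surface({"2019-W02": 7.0, "2019-W24": 7.0, "2019-W48": 7.0,
                                  "2019-W28": 7.0})
        summary = aggregate_seasons(surf)
        for name in ("annual", "harmattan", "non_harmattan"):
            assert np.allclose(surf.aggregates[name], 7.0)
        assert (summary["sd"] == 0).all()

    def test_weighted_mean_oracle(self):
        """Two Harmattan weeks at 50 and two wet weeks at 28: the annual mean
        is the equal-weight average 39."""
        surf = synthetic_surface(
            {"2019-W02": 50.0, "2019-W48": 50.0, "2019-W24": 28.0, "2019-W28": 28.0}
        )
        aggregate_seasons(surf)
        assert np.allclose(surf.aggregates["annual"], 39.0)
        assert np.allclose(surf.aggregates["harmattan"], 50.0)
        assert np.allclose(surf.aggregates["non_harmattan"], 28.0)

    def test_transitional_weeks_enter_annual_only(self):
        surf = synthetic_surface({"2019-W15": 100.0, "2019-W02": 10.0, "2019-W24": 20.0})
        aggregate_seasons(surf)  # W15 is April: transitional
        assert np.allclose(surf.aggregates["annual"], (100.0 + 10.0 + 20.0) / 3)
        assert np.allclose(surf.aggregates["harmattan"], 10.0)
        assert np.allclose(surf.aggregates["non_harmattan"], 20.0)

    def test_empty_season_omitted_with_note(self):
        surf = synthetic_surface({"2019-W24": 20.0, "2019-W28": 30.0})
        with pytest.warns(UserWarning, match="harmattan"):
            summary = aggregate_seasons(surf)
        assert "harmattan" not in summary.index
        assert "non_harmattan" in summary.index

    def test_aggregates_bounded_by_weekly_extremes_and_permutation_invariant(self):
        rng = np.random.default_rng(0)
        weeks = ["2019-W02", "2019-W24", "2019-W28", "2019-W48"]
        weekly = rng.uniform(0, 100, size=(4, 3, 3))
        grid = make_grid((0.0, 0.0, 150.0, 150.0), cell_size=50.0)
        surf = PredictionSurface(grid=grid, weeks=weeks, weekly=weekly,
                                 weekly_raw=weekly.copy(), n_floored=0)
        aggregate_seasons(surf)
        lo, hi = weekly.min(axis=0), weekly.max(axis=0)
        for layer in surf.aggregates.values():
            assert (layer >= lo - 1e-12).all() and (layer <= hi + 1e-12).all()
        perm = [2, 0, 3, 1]
        surf2 = PredictionSurface(grid=grid, weeks=[weeks[i] for i in perm],
                                  weekly=weekly[perm], weekly_raw=weekly[perm],
                                  n_floored=0)
        aggregate_seasons(surf2)
        for name in surf.aggregates:
            assert np.allclose(surf.aggregates[name], surf2.aggregates[name])

    def test_summary_range_is_cellwise_min_max(self):
        surf = synthetic_surface({"2019-W24": 20.0})
        surf.weekly[0, 0, 0] = 5.0
        surf.weekly[0, -1, -1] = 80.0
        summary = aggregate_seasons(surf)
        assert summary.loc["annual", "min"] == 5.0
        assert summary.loc["annual", "max"] == 80.0
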