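"""End-to-end orchestration: simulate -> select -> fit -> validate -> map -> equity.

This is the glue that runs the whole analysis on a synthetic city with one
call, mirroring how the stages chain on real inputs: extract buffered
predictors at the monitoring sites, choose buffers and run the supervised
stepwise selection per pollutant, fit the crossed mixed model, cross-validate
it, predict the 50 m weekly surface, aggregate seasons, and summarise
population exposure and the SES gradient for NO2.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .equity import ExtremeContrast, compare_extremes, overlay_exposure, population_cdf, ses_quintiles
from .features import DEFAULT_RADII, FeatureExtractor
from .layout import LANDUSE_CLASSES, POI_KINDS, CityLayout, LayoutParams, generate_layout
from .lmm import CrossedLMM, CrossedLMMResults
from .meteorology import generate_meteorology, week_sequence
from .selection import CandidateVariable, SelectionTrace, forward_stepwise, vif_prune
from .simulate import SamplingDesign, SimulationResult, TruthModel, simulate_concentrations
from .surface import PredictionSurface, aggregate_seasons, make_grid, predict_surface
from .validation import CVResult, cross_validate

MET_CANDIDATE_SIGNS = {
    "temperature": "+",
    "rh": "-",
    "wind_speed": "-",
    "mixing_depth": "-",
    "solar_radiation": "-",
    "vapor_mixing_ratio": "-",
    "rain_days": "-",
}


def default_candidates(radii=DEFAULT_RADII, include_met: bool = True) -> list[CandidateVariable]:
    """The standard candidate catalogue: traffic, land use, greenness,
    population, activity, and (optionally) weekly meteorology."""
    radii = tuple(radii)
    cands = [
        CandidateVariable("major_road_length", radii, "+", "traffic"),
        CandidateVariable("secondary_road_length", radii, "+", "traffic"),
        CandidateVariable("dist_major_road", (), "-", "traffic"),
        CandidateVariable("dist_secondary_road", (), "-", "traffic"),
        CandidateVariable("landuse_commercial", radii, "+", "land use"),
        CandidateVariable("landuse_high_density_res", radii, "+", "land use"),
        CandidateVariable("landuse_low_density_res", radii, "+", "land use"),
        CandidateVariable("landuse_periurban", radii, "-", "land use"),
        CandidateVariable("ndvi", radii, "-", "land use"),
        CandidateVariable("pop_density", radii, "+", "population"),
        CandidateVariable("biomass_share", radii, "+", "population"),
    ]
    for kind in POI_KINDS:
        cands.append(CandidateVariable(f"poi_{kind}", radii, "+", "activity"))
    if include_met:
        for name, sign in MET_CANDIDATE_SIGNS.items():
            cands.append(CandidateVariable(name, (), sign, "meteorology"))
    return cands


@dataclass
class PollutantAnalysis:
    """Everything the pipeline produced for one pollutant."""

    response: str
    trace: SelectionTrace
    selected: list[str]  # predictor columns entering the mixed model
    vif_removed: list[str]
    fit: CrossedLMMResults
    cv: CVResult


@dataclass
class PipelineResult:
    layout: CityLayout
    met: pd.DataFrame
    design: SamplingDesign
    sim: SimulationResult
    data: pd.DataFrame  # analysis table: samples + site features merged
    no2: PollutantAnalysis
    no: PollutantAnalysis
    surface_no2: PredictionSurface | None = None
    season_summary: pd.DataFrame | None = None
    ea_exposure: pd.DataFrame | None = None
    cdf: pd.DataFrame | None = None
    quintile_summary: pd.DataFrame | None = None
    contrast: ExtremeContrast | None = None


def build_analysis_table(sim: SimulationResult, design: SamplingDesign) -> pd.DataFrame:
    """Join simulated samples with the site-level predictor table."""
    feats = sim.site_features.drop(columns=["x", "y"])
    return sim.samples.merge(feats, left_on="site_id", right_index=True, how="left")


def analyse_pollutant(
    data: pd.DataFrame,
    response: str,
    candidates: list[CandidateVariable],
    gain_threshold: float = 0.01,
    vif_threshold: float = 3.0,
    cv_k: int = 10,
    cv_seed: int = 0,
) -> PollutantAnalysis:
    """Selection + VIF pruning + mixed-model fit + k-fold CV for one response."""
    trace = forward_stepwise(candidates, data, response, gain_threshold=gain_threshold)
    selected = [c for c in trace.final_columns]
    vif_removed: list[str] = []
    if len(selected) >= 2:
        pruned, vif_removed = vif_prune(data[selected], threshold=vif_threshold)
        selected = list(pruned.columns)
        trace.vif_removed = vif_removed
    model = CrossedLMM.from_dataframe(data, response, selected)
    fit = model.fit()
    cv = cross_validate(data, response, selected, k=cv_k, seed=cv_seed)
    return PollutantAnalysis(
        response=response, trace=trace, selected=selected,
        vif_removed=vif_removed, fit=fit, cv=cv,
    )


def run_pipeline(
    seed: int,
    extent=(0.0, 0.0, 6000.0, 6000.0),
    n_weeks: int = 52,
    start_date: dt.date = dt.date(2019, 4, 1),
    n_fixed: int = 10,
    n_rotating: int = 124,
    layout_params: LayoutParams | None = None,
    truth: TruthModel | None = None,
    grid_cell: float = 50.0,
    surface_max_cells: int = 10_000,
    with_surface: bool = True,
) -> PipelineResult:
    """Run the full analysis on a synthetic city.

    ``surface_max_cells`` coarsens the prediction grid if the extent at
    ``grid_cell`` resolution would exceed it, keeping the mapping stage
    tractable on a single CPU; the statistical stages always run at full
    resolution.  Sub-seeds for the layout, design and simulation stages are
    derived from ``seed``.
    """
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=4)
    layout = generate_layout(int(sub[0]), extent=extent, params=layout_params)
    met = generate_meteorology(int(sub[1]), n_weeks=n_weeks, start_date=start_date)
    weeks = list(met.index)
    design = SamplingDesign.generate(int(sub[2]), layout, weeks,
                                     n_fixed=n_fixed, n_rotating=n_rotating)
    if truth is None:
        truth = TruthModel.default()
    sim = simulate_concentrations(truth, layout, design, met, seed=int(sub[3]))
    data = build_analysis_table(sim, design)
    candidates = default_candidates()
    no2 = analyse_pollutant(data, "no2", candidates, cv_seed=int(sub[3]))
    no = analyse_pollutant(data, "no", candidates, cv_seed=int(sub[3]))
    result = PipelineResult(
        layout=layout, met=met, design=design, sim=sim, data=data, no2=no2, no=no
    )
    if with_surface:
        cell = grid_cell
        xmin, ymin, xmax, ymax = extent
        while ((xmax - xmin) / cell) * ((ymax - ymin) / cell) > surface_max_cells:
            cell *= 2.0
        grid = make_grid(extent, cell_size=cell)
        surf = predict_surface(no2.fit, grid, layout, met, weeks)
        result.surface_no2 = surf
        result.season_summary = aggregate_seasons(surf)
        result.ea_exposure = overlay_exposure(surf, layout.eas)
        result.cdf = population_cdf(result.ea_exposure)
        ea_q, qsum = ses_quintiles(result.ea_exposure)
        result.ea_exposure = ea_q
        result.quintile_summary = qsum
        low = ea_q.loc[ea_q["ses_quintile"] == 1, "annual"].to_numpy()
        high = ea_q.loc[ea_q["ses_quintile"] == 5, "annual"].to_numpy()
        result.contrast = compare_extremes(low, high)
    return result
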