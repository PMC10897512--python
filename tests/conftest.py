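import warnings

import numpy as np
import pytest

import citynox as cx
from citynox.pipeline import build_analysis_table


@pytest.fixture(scope="session")
def small_layout():
    """6 km x 6 km synthetic city used across the suite."""
    return cx.generate_layout(1, extent=(0.0, 0.0, 6000.0, 6000.0))


@pytest.fixture(scope="session")
def met52():
    return cx.generate_meteorology(2, n_weeks=52)


@pytest.fixture(scope="session")
def campaign(small_layout, met52):
    """Standard campaign: 10 fixed x 52 weeks + 124 rotating sites."""
    return cx.SamplingDesign.generate(3, small_layout, list(met52.index))


@pytest.fixture(scope="session")
def simulation(small_layout, met52, campaign):
    return cx.simulate_concentrations(
        cx.TruthModel.default(), small_layout, campaign, met52, seed=4
    )


@pytest.fixture(scope="session")
def analysis_data(simulation, campaign):
    return build_analysis_table(simulation, campaign)


@pytest.fixture(scope="session")
def no2_fit(analysis_data):
    """Mixed-model fit of NO2 on the true generating predictors."""
    model = cx.CrossedLMM.from_dataframe(
        analysis_data,
        "no2",
        ["major_road_length_100", "secondary_road_length_200", "ndvi_50", "wind_speed", "rh"],
    )
    return model.fit()


def dense_clipped_length(geoms, x, y, radius, step=0.05):
    """Numerical-integration oracle for buffered road length.

    Samples each polyline at ``step``-metre intervals (vectorised along the
    arc-length parameter) and counts samples inside the disc.  Independent of
    the shapely intersection path used by the extractor.
    """
    total = 0.0
    for g in geoms:
        coords = np.asarray(g.coords)
        seg = np.hypot(np.diff(coords[:, 0]), np.diff(coords[:, 1]))
        length = float(seg.sum())
        if length == 0:
            continue
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        # quick reject: bounding box farther than radius from the point
        if (
            coords[:, 0].max() < x - radius or coords[:, 0].min() > x + radius
            or coords[:, 1].max() < y - radius or coords[:, 1].min() > y + radius
        ):
            continue
        ts = np.arange(0.0, length, step)
        xs = np.interp(ts, cum, coords[:, 0])
        ys = np.interp(ts, cum, coords[:, 1])
        inside = int(((xs - x) ** 2 + (ys - y) ** 2 <= radius * radius).sum())
        total += inside * step
    return total


def simulate_crossed(seed, n_sites, n_weeks, beta, sd_site, sd_week, sd_resid,
                     n_covariates=None):
    """Plain crossed-design simulator independent of the city machinery.

    Fully crossed layout (every site x every week), standard-normal
    covariates, known coefficients.  Used by the model tests as a minimal,
    transparent data source.
    """
    rng = np.random.default_rng(seed)
    beta = np.asarray(beta, dtype=float)
    p = len(beta) if n_covariates is None else n_covariates
    n = n_sites * n_weeks
    X = rng.standard_normal((n, p))
    site = np.repeat(np.arange(n_sites), n_weeks)
    week = np.tile(np.arange(n_weeks), n_sites)
    b = sd_site * rng.standard_normal(n_sites)
    g = sd_week * rng.standard_normal(n_weeks)
    e = sd_resid * rng.standard_normal(n)
    y = X @ beta + b[site] + g[week] + e
    return y, X, site, week
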