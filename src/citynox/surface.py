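"""City-wide gridded weekly prediction and seasonal aggregation.

The fitted model is evaluated at every 50 m grid-cell centre for every
campaign week (site intercept 0, week intercept from the fit), then averaged
into annual, Harmattan (Nov-Feb) and non-Harmattan (May-Oct) layers.
Transitional March-April weeks contribute to the annual mean only.  Negative
weekly predictions are floored at 0 for mapping; the raw values are kept in
metadata so the flooring is auditable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FeatureExtractor
from .layout import CityLayout, Extent, Raster
from .lmm import CrossedLMMResults
from .meteorology import season_of_week


@dataclass
class Grid:
    """Regular grid of cell centres covering an extent; row 0 is northernmost."""

    extent: Extent
    cell_size: float
    nrows: int
    ncols: int
    has_partial_edge: bool

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        xmin, ymin, xmax, ymax = self.extent
        xs = xmin + (np.arange(self.ncols) + 0.5) * self.cell_size
        ys = (ymin + self.nrows * self.cell_size) - (np.arange(self.nrows) + 0.5) * self.cell_size
        return xs, ys

    def centers_table(self) -> pd.DataFrame:
        """Flat (row-major) table of cell centres with row/col indices."""
        xs, ys = self.centers()
        jj, ii = np.meshgrid(np.arange(self.ncols), np.arange(self.nrows))
        return pd.DataFrame(
            {
                "row": ii.ravel(),
                "col": jj.ravel(),
                "x": xs[jj.ravel()],
                "y": ys[ii.ravel()],
            }
        )

    @property
    def n_cells(self) -> int:
        return self.nrows * self.ncols


def make_grid(extent: Extent, cell_size: float = 50.0) -> Grid:
    """Regular prediction grid; partial edge cells are included and flagged."""
    if cell_size <= 0:
        raise ValueError(f"cell_size must be positive, got {cell_size}")
    xmin, ymin, xmax, ymax = extent
    if xmax <= xmin or ymax <= ymin:
        raise ValueError(f"degenerate extent {extent}")
    ncols = int(np.ceil((xmax - xmin) / cell_size - 1e-9))
    nrows = int(np.ceil((ymax - ymin) / cell_size - 1e-9))
    partial = not (
        np.isclose(ncols * cell_size, xmax - xmin) and np.isclose(nrows * cell_size, ymax - ymin)
    )
    if partial:
        warnings.warn(
            "extent is not a multiple of the cell size; partial edge cells included",
            stacklevel=2,
        )
    return Grid(extent=extent, cell_size=cell_size, nrows=nrows, ncols=ncols,
                has_partial_edge=partial)


@dataclass
class PredictionSurface:
    """Weekly concentration layers on a grid, plus season aggregates."""

    grid: Grid
    weeks: list[str]
    weekly: np.ndarray  # (n_weeks, nrows, ncols), floored at 0
    weekly_raw: np.ndarray  # unfloored
    n_floored: int
    aggregates: dict[str, np.ndarray] = field(default_factory=dict)

    def layer_raster(self, name: str) -> Raster:
        xmin, ymin, _, _ = self.grid.extent
        return Raster(self.aggregates[name], x_min=xmin, y_min=ymin,
                      cell_size=self.grid.cell_size)


def predict_surface(
    result: CrossedLMMResults,
    grid: Grid,
    layout: CityLayout,
    met: pd.DataFrame,
    weeks: list[str],
    cell_features: pd.DataFrame | None = None,
) -> PredictionSurface:
    """Weekly prediction layers over the grid.

    Spatial features are extracted once per cell (they are week-invariant) and
    may be passed in precomputed via ``cell_features`` to reuse across models.
    Weeks without meteorology are skipped with a warning.
    """
    if cell_features is None:
        extractor = FeatureExtractor(layout)
        cell_features = extractor.extract_table(grid.centers_table()[["x", "y"]])
    usable = [w for w in weeks if w in met.index]
    skipped = sorted(set(weeks) - set(usable))
    if skipped:
        warnings.warn(f"weeks without meteorology skipped: {skipped}", stacklevel=2)

    X_new = cell_features.copy()
    weekly_raw = np.empty((len(usable), grid.nrows, grid.ncols))
    predictors = result.model.predictor_cols or []
    met_cols = [c for c in predictors if c in met.columns]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # month fallback handled via flags if needed
        for k, w in enumerate(usable):
            for c in met_cols:
                X_new[c] = met.loc[w, c]
            pred = result.predict(X_new[predictors], iso_week=w, site_id=None)
            weekly_raw[k] = pred.reshape(grid.nrows, grid.ncols)
    weekly = np.maximum(weekly_raw, 0.0)
    n_floored = int((weekly_raw < 0).sum())
    surface = PredictionSurface(
        grid=grid, weeks=usable, weekly=weekly, weekly_raw=weekly_raw, n_floored=n_floored
    )
    return surface


SEASON_LAYERS = ("annual", "harmattan", "non_harmattan")


def aggregate_seasons(surface: PredictionSurface) -> pd.DataFrame:
    """Cell-wise season means plus a mean/SD/range summary table.

    annual = mean over all predicted weeks; harmattan = Nov-Feb weeks;
    non_harmattan = May-Oct weeks; transitional (Mar-Apr) weeks enter the
    annual layer only.  Seasons with zero weeks are omitted with a note.
    Aggregates are stored on ``surface.aggregates``; the summary table is
    returned.
    """
    seasons = np.array([season_of_week(w) for w in surface.weeks])
    members = {
        "annual": np.ones(len(surface.weeks), dtype=bool),
        "harmattan": seasons == "harmattan",
        "non_harmattan": seasons == "non_harmattan",
    }
    rows = []
    for name in SEASON_LAYERS:
        mask = members[name]
        if not mask.any():
            warnings.warn(f"season {name!r} has no predicted weeks; layer omitted",
                          stacklevel=2)
            continue
        layer = surface.weekly[mask].mean(axis=0)
        surface.aggregates[name] = layer
        rows.append(
            {
                "layer": name,
                "n_weeks": int(mask.sum()),
                "mean": float(layer.mean()),
                "sd": float(layer.std(ddof=1)),
                "min": float(layer.min()),
                "max": float(layer.max()),
            }
        )
    return pd.DataFrame(rows).set_index("layer")
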