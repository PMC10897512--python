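"""Synthetic city layout: roads, land use, greenness, POIs and census areas.

All geometry lives in a local projected plane in metres (a transverse-Mercator
style local grid), because buffer radii and road lengths are metric.  The
generated city is monocentric: a commercial core, a high-density residential
ring, low-density suburbs and a peri-urban fringe, with vegetation (NDVI)
increasing and population density decreasing away from the core, and
enumeration-area SES increasing outward.  That is the qualitative structure a
land-use-regression analysis assumes: traffic and activity sources in the
core, cleaner and greener wealthier fringes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon, box
from shapely.ops import clip_by_rect

Extent = tuple[float, float, float, float]  # xmin, ymin, xmax, ymax

ROAD_CLASSES = ("major", "secondary")
LANDUSE_CLASSES = ("commercial", "high_density_res", "low_density_res", "periurban")
POI_KINDS = ("bar", "restaurant", "school", "shop")


@dataclass
class Raster:
    """Single-band regular grid; row 0 is the northernmost row."""

    values: np.ndarray  # (nrows, ncols)
    x_min: float
    y_min: float
    cell_size: float

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def y_max(self) -> float:
        return self.y_min + self.nrows * self.cell_size

    @property
    def x_max(self) -> float:
        return self.x_min + self.ncols * self.cell_size

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate vectors of column / row cell centres."""
        xs = self.x_min + (np.arange(self.ncols) + 0.5) * self.cell_size
        ys = self.y_max - (np.arange(self.nrows) + 0.5) * self.cell_size
        return xs, ys

    def mean_in_circle(self, x: float, y: float, radius: float) -> float:
        """Mean of cells whose centres fall within the circle (x, y, radius)."""
        xs, ys = self.cell_centers()
        dx2 = (xs - x) ** 2
        dy2 = (ys - y) ** 2
        mask = dy2[:, None] + dx2[None, :] <= radius**2
        if not mask.any():
            # degenerate buffer smaller than a cell: nearest cell value
            j = int(np.argmin(np.abs(xs - x)))
            i = int(np.argmin(np.abs(ys - y)))
            return float(self.values[i, j])
        return float(self.values[mask].mean())


@dataclass
class CityLayout:
    """All spatial input layers of the pipeline, in one metric plane."""

    extent: Extent
    roads: pd.DataFrame  # columns: geometry (LineString), road_class
    landuse: pd.DataFrame  # columns: geometry (Polygon), landuse_class
    ndvi: Raster
    pois: pd.DataFrame  # columns: geometry (Point), kind
    eas: pd.DataFrame  # columns: ea_id, geometry, population, biomass_share, ses

    @property
    def extent_polygon(self) -> Polygon:
        return box(*self.extent)

    def translated(self, dx: float, dy: float) -> "CityLayout":
        """A copy of the layout rigidly shifted by (dx, dy)."""
        from shapely.affinity import translate

        def shift(df: pd.DataFrame) -> pd.DataFrame:
            out = df.copy()
            out["geometry"] = [translate(g, dx, dy) for g in df["geometry"]]
            return out

        xmin, ymin, xmax, ymax = self.extent
        ndvi = Raster(self.ndvi.values.copy(), self.ndvi.x_min + dx, self.ndvi.y_min + dy,
                      self.ndvi.cell_size)
        return CityLayout(
            extent=(xmin + dx, ymin + dy, xmax + dx, ymax + dy),
            roads=shift(self.roads),
            landuse=shift(self.landuse),
            ndvi=ndvi,
            pois=shift(self.pois),
            eas=shift(self.eas),
        )


@dataclass(frozen=True)
class LayoutParams:
    """Density knobs for the generator; defaults give a plausible mid-size city."""

    n_major_roads: int = 8
    n_secondary_roads: int = 40
    poi_rate_per_km2: float = 2.0
    n_ea_rows: int = 12
    n_ea_cols: int = 12
    ndvi_cell_size: float = 100.0
    #: fraction of the half-extent covered by the commercial core box
    core_fraction: float = 0.18
    high_density_fraction: float = 0.45
    low_density_fraction: float = 0.75
    #: EA population density at the core, persons/km2 (falls off outward)
    core_density_per_km2: float = 20000.0
    ses_center: float = 8.0  # median log equivalized consumption at the core
    ses_gradient: float = 1.0  # increase from core to edge
    ses_noise_sd: float = 0.15


def _ring_boxes(extent: Extent, params: LayoutParams) -> dict[str, Polygon]:
    xmin, ymin, xmax, ymax = extent
    cx, cy = (xmin + xmax) / 2.0, (ymin + ymax) / 2.0
    hx, hy = (xmax - xmin) / 2.0, (ymax - ymin) / 2.0

    def centered(frac: float) -> Polygon:
        return box(cx - frac * hx, cy - frac * hy, cx + frac * hx, cy + frac * hy)

    core = centered(params.core_fraction)
    high = centered(params.high_density_fraction).difference(core)
    low = centered(params.low_density_fraction).difference(centered(params.high_density_fraction))
    peri = box(*extent).difference(centered(params.low_density_fraction))
    return {
        "commercial": core,
        "high_density_res": high,
        "low_density_res": low,
        "periurban": peri,
    }


def _make_roads(rng: np.random.Generator, extent: Extent, params: LayoutParams) -> pd.DataFrame:
    xmin, ymin, xmax, ymax = extent
    cx, cy = (xmin + xmax) / 2.0, (ymin + ymax) / 2.0
    rows = []
    # major roads: long chords through a point near the centre, random bearing
    for _ in range(params.n_major_roads):
        px = cx + rng.normal(0.0, 0.15 * (xmax - xmin))
        py = cy + rng.normal(0.0, 0.15 * (ymax - ymin))
        theta = rng.uniform(0.0, np.pi)
        d = 2.0 * max(xmax - xmin, ymax - ymin)
        line = LineString(
            [
                (px - d * np.cos(theta), py - d * np.sin(theta)),
                (px + d * np.cos(theta), py + d * np.sin(theta)),
            ]
        )
        clipped = clip_by_rect(line, xmin, ymin, xmax, ymax)
        if not clipped.is_empty:
            rows.append({"geometry": clipped, "road_class": "major"})
    # secondary roads: shorter segments, denser toward the centre
    for _ in range(params.n_secondary_roads):
        px = cx + rng.normal(0.0, 0.22 * (xmax - xmin))
        py = cy + rng.normal(0.0, 0.22 * (ymax - ymin))
        theta = rng.uniform(0.0, np.pi)
        length = rng.uniform(0.08, 0.30) * (xmax - xmin)
        line = LineString(
            [
                (px - 0.5 * length * np.cos(theta), py - 0.5 * length * np.sin(theta)),
                (px + 0.5 * length * np.cos(theta), py + 0.5 * length * np.sin(theta)),
            ]
        )
        clipped = clip_by_rect(line, xmin, ymin, xmax, ymax)
        if not clipped.is_empty:
            rows.append({"geometry": clipped, "road_class": "secondary"})
    return pd.DataFrame(rows, columns=["geometry", "road_class"])


def _make_ndvi(rng: np.random.Generator, extent: Extent, params: LayoutParams) -> Raster:
    xmin, ymin, xmax, ymax = extent
    cell = params.ndvi_cell_size
    ncols = int(np.ceil((xmax - xmin) / cell))
    nrows = int(np.ceil((ymax - ymin) / cell))
    xs = xmin + (np.arange(ncols) + 0.5) * cell
    ys = (ymin + nrows * cell) - (np.arange(nrows) + 0.5) * cell
    cx, cy = (xmin + xmax) / 2.0, (ymin + ymax) / 2.0
    maxd = np.hypot((xmax - xmin) / 2.0, (ymax - ymin) / 2.0)
    d = np.hypot(ys[:, None] - cy, xs[None, :] - cx) / maxd
    values = -0.02 + 0.75 * d + rng.normal(0.0, 0.05, size=(nrows, ncols))
    return Raster(np.clip(values, -1.0, 1.0), x_min=xmin, y_min=ymin, cell_size=cell)


def _make_pois(rng: np.random.Generator, extent: Extent, params: LayoutParams) -> pd.DataFrame:
    xmin, ymin, xmax, ymax = extent
    area_km2 = (xmax - xmin) * (ymax - ymin) / 1e6
    n = rng.poisson(params.poi_rate_per_km2 * area_km2)
    rows = []
    cx, cy = (xmin + xmax) / 2.0, (ymin + ymax) / 2.0
    for _ in range(n):
        if rng.uniform() < 0.7:  # clustered in/near the core
            x = np.clip(cx + rng.normal(0.0, 0.15 * (xmax - xmin)), xmin, xmax)
            y = np.clip(cy + rng.normal(0.0, 0.15 * (ymax - ymin)), ymin, ymax)
        else:
            x = rng.uniform(xmin, xmax)
            y = rng.uniform(ymin, ymax)
        rows.append({"geometry": Point(x, y), "kind": POI_KINDS[rng.integers(len(POI_KINDS))]})
    return pd.DataFrame(rows, columns=["geometry", "kind"])


def _make_eas(rng: np.random.Generator, extent: Extent, params: LayoutParams) -> pd.DataFrame:
    """Irregular rectangular tiling: partitions the extent exactly."""
    xmin, ymin, xmax, ymax = extent
    w = rng.dirichlet(np.full(params.n_ea_cols, 8.0)) * (xmax - xmin)
    h = rng.dirichlet(np.full(params.n_ea_rows, 8.0)) * (ymax - ymin)
    xedges = np.concatenate([[xmin], xmin + np.cumsum(w)])
    yedges = np.concatenate([[ymin], ymin + np.cumsum(h)])
    xedges[-1], yedges[-1] = xmax, ymax
    cx, cy = (xmin + xmax) / 2.0, (ymin + ymax) / 2.0
    maxd = np.hypot((xmax - xmin) / 2.0, (ymax - ymin) / 2.0)
    rows = []
    k = 0
    for i in range(params.n_ea_rows):
        for j in range(params.n_ea_cols):
            poly = box(xedges[j], yedges[i], xedges[j + 1], yedges[i + 1])
            px, py = poly.centroid.x, poly.centroid.y
            rel_d = np.hypot(px - cx, py - cy) / maxd
            density = params.core_density_per_km2 * np.exp(-2.2 * rel_d) * rng.lognormal(0.0, 0.25)
            population = density * poly.area / 1e6
            biomass = float(np.clip(0.55 - 0.35 * rel_d + rng.normal(0.0, 0.08), 0.0, 1.0))
            ses = params.ses_center + params.ses_gradient * rel_d + rng.normal(
                0.0, params.ses_noise_sd
            )
            rows.append(
                {
                    "ea_id": f"EA{k:04d}",
                    "geometry": poly,
                    "population": float(population),
                    "biomass_share": biomass,
                    "ses": float(ses),
                }
            )
            k += 1
    return pd.DataFrame(rows)


def generate_layout(
    seed: int,
    extent: Extent = (0.0, 0.0, 10_000.0, 10_000.0),
    params: LayoutParams | None = None,
) -> CityLayout:
    """Seeded synthetic city layout on a metric plane.

    Reproducible: the same (seed, extent, params) yields identical layers.
    Raises ValueError on a degenerate (zero-area) extent.
    """
    xmin, ymin, xmax, ymax = extent
    if xmax <= xmin or ymax <= ymin:
        raise ValueError(f"degenerate extent {extent}: area must be positive")
    if params is None:
        params = LayoutParams()
    rng = np.random.default_rng(seed)
    roads = _make_roads(rng, extent, params)
    landuse = pd.DataFrame(
        [{"geometry": g, "landuse_class": c} for c, g in _ring_boxes(extent, params).items()
         if not g.is_empty]
    )
    ndvi = _make_ndvi(rng, extent, params)
    pois = _make_pois(rng, extent, params)
    eas = _make_eas(rng, extent, params)
    return CityLayout(extent=extent, roads=roads, landuse=landuse, ndvi=ndvi, pois=pois, eas=eas)
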