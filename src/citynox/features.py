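"""Buffer-based spatial predictor extraction.

For every location (a monitoring site or a 50 m grid-cell centre) we compute,
within circular buffers of 50/100/200/500 m: clipped road length per road
class, land-use area per class, mean NDVI over raster cells whose centres fall
in the buffer, POI counts per kind, and EA-attributed population density
(area-weighted over intersecting enumeration areas) and biomass share.
Unbuffered distances to the nearest major and secondary road complete the
predictor vector.  The same extraction is applied identically to sites and to
prediction-grid cells, which is what lets a model fitted at the sites be
evaluated city-wide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.strtree import STRtree

from .layout import LANDUSE_CLASSES, POI_KINDS, ROAD_CLASSES, CityLayout

DEFAULT_RADII = (50.0, 100.0, 200.0, 500.0)


@dataclass(frozen=True)
class BufferSpec:
    """Ordered, strictly increasing buffer radii in metres."""

    radii: tuple[float, ...] = DEFAULT_RADII

    def __post_init__(self):
        r = tuple(float(x) for x in self.radii)
        if not r or any(x <= 0 for x in r) or any(b <= a for a, b in zip(r, r[1:])):
            raise ValueError(f"radii must be positive and strictly increasing, got {self.radii}")
        object.__setattr__(self, "radii", r)


def buffered_column(variable: str, radius: float) -> str:
    return f"{variable}_{int(radius)}"


class FeatureExtractor:
    """Spatial-feature extractor bound to one layout.

    Builds STR trees once so repeated extraction (40k grid cells) stays fast.
    """

    def __init__(self, layout: CityLayout, spec: BufferSpec | None = None):
        self.layout = layout
        self.spec = spec or BufferSpec()
        self._road_geoms = {
            cls: list(layout.roads.loc[layout.roads["road_class"] == cls, "geometry"])
            for cls in ROAD_CLASSES
        }
        self._road_trees = {
            cls: STRtree(geoms) if geoms else None for cls, geoms in self._road_geoms.items()
        }
        self._landuse_geoms = {
            cls: list(layout.landuse.loc[layout.landuse["landuse_class"] == cls, "geometry"])
            for cls in LANDUSE_CLASSES
        }
        if len(layout.pois):
            self._poi_points = np.array(
                [(g.x, g.y) for g in layout.pois["geometry"]], dtype=float
            )
            self._poi_kinds = layout.pois["kind"].to_numpy()
        else:
            self._poi_points = np.empty((0, 2))
            self._poi_kinds = np.array([], dtype=object)
        self._ea_geoms = list(layout.eas["geometry"])
        self._ea_tree = STRtree(self._ea_geoms)
        self._ea_density = (
            layout.eas["population"].to_numpy() / (np.array([g.area for g in self._ea_geoms]) / 1e6)
        )
        self._ea_biomass = layout.eas["biomass_share"].to_numpy()
        self._warned_missing_class: set[str] = set()

    # -- single-location extraction -------------------------------------------------

    def extract(self, x: float, y: float) -> dict[str, float]:
        """Predictor row for one location; raises if outside the layout extent."""
        xmin, ymin, xmax, ymax = self.layout.extent
        if not (xmin <= x <= xmax and ymin <= y <= ymax):
            raise ValueError(f"location ({x}, {y}) outside layout extent {self.layout.extent}")
        pt = Point(x, y)
        row: dict[str, float] = {"x": x, "y": y}
        for radius in self.spec.radii:
            disc = pt.buffer(radius, quad_segs=32)
            for cls in ROAD_CLASSES:
                geoms, tree = self._road_geoms[cls], self._road_trees[cls]
                length = 0.0
                if tree is not None:
                    for i in tree.query(disc):
                        length += geoms[i].intersection(disc).length
                row[buffered_column(f"{cls}_road_length", radius)] = length
            for cls in LANDUSE_CLASSES:
                area = sum(g.intersection(disc).area for g in self._landuse_geoms[cls])
                row[buffered_column(f"landuse_{cls}", radius)] = area
            row[buffered_column("ndvi", radius)] = self.layout.ndvi.mean_in_circle(x, y, radius)
            if len(self._poi_points):
                d2 = ((self._poi_points - (x, y)) ** 2).sum(axis=1)
                inside = d2 <= radius**2
                for kind in POI_KINDS:
                    row[buffered_column(f"poi_{kind}", radius)] = float(
                        np.sum(inside & (self._poi_kinds == kind))
                    )
            else:
                for kind in POI_KINDS:
                    row[buffered_column(f"poi_{kind}", radius)] = 0.0
            dens, biom = self._ea_weighted(disc)
            row[buffered_column("pop_density", radius)] = dens
            row[buffered_column("biomass_share", radius)] = biom
        for cls in ROAD_CLASSES:
            row[f"dist_{cls}_road"] = self._nearest_road_distance(pt, cls)
        return row

    def _ea_weighted(self, disc) -> tuple[float, float]:
        """Area-weighted mean EA population density and biomass share in a buffer."""
        idx = self._ea_tree.query(disc)
        weights, dens, biom = [], [], []
        for i in idx:
            a = self._ea_geoms[i].intersection(disc).area
            if a > 0:
                weights.append(a)
                dens.append(self._ea_density[i])
                biom.append(self._ea_biomass[i])
        if not weights:
            # buffer in a sliver outside every EA (should not happen when EAs
            # partition the extent); fall back to nearest EA
            i = self._ea_tree.nearest(disc.centroid)
            return float(self._ea_density[i]), float(self._ea_biomass[i])
        w = np.asarray(weights)
        return (
            float(np.average(dens, weights=w)),
            float(np.average(biom, weights=w)),
        )

    def _nearest_road_distance(self, pt: Point, cls: str) -> float:
        geoms = self._road_geoms[cls]
        if not geoms:
            if cls not in self._warned_missing_class:
                warnings.warn(
                    f"no {cls} roads in layout; distance reported as +inf", stacklevel=3
                )
                self._warned_missing_class.add(cls)
            return np.inf
        tree = self._road_trees[cls]
        i = tree.nearest(pt)
        return float(pt.distance(geoms[i]))

    # -- table extraction ------------------------------------------------------------

    def extract_table(self, points: pd.DataFrame) -> pd.DataFrame:
        """Predictor table for a DataFrame with columns x, y (index preserved)."""
        rows = [self.extract(float(r.x), float(r.y)) for r in points.itertuples()]
        return pd.DataFrame(rows, index=points.index)


def extract_buffered(
    location: tuple[float, float], layout: CityLayout, spec: BufferSpec | None = None
) -> dict[str, float]:
    """One-shot predictor row; use :class:`FeatureExtractor` for many points."""
    return FeatureExtractor(layout, spec).extract(*location)
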