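"""Generate weekly NO2/NO/NOx samples from a known linear mixed model.

The data-generating process is the same model the pipeline fits:

    y_ij = a0 + b1·X_i + b2·Met_j + b3·Month(j) + site_i + week_j + eps_ij

with X_i the standardized spatial predictors at site i, Met_j the standardized
weekly meteorology, a fixed calendar-month effect, and independent Normal
random intercepts for site and week.  NO2 and NO are simulated as separate
responses sharing the same spatial predictors; NOx is their sum, which makes
NOx >= NO2 hold record-wise by construction.  All random draws are logged so
recovery tests can compare estimates against the simulated truth.

The default coefficient sets mirror the magnitude and sign structure of a
fitted urban NOx model: road length within 100 m dominating, greenness
protective for NO2, wind speed and humidity suppressing NO2, solar radiation
suppressing NO, and month effects of a few tens of µg/m³.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FeatureExtractor
from .layout import CityLayout
from .meteorology import month_of_week


@dataclass
class PollutantTruth:
    """True coefficients for one pollutant, on the standardized scale."""

    intercept: float
    spatial: dict[str, float]  # predictor-table column -> coefficient
    met: dict[str, float]  # meteorology column -> coefficient
    month: dict[int, float]  # calendar month (1..12) -> fixed effect
    sd_site: float
    sd_week: float
    sd_resid: float

    def __post_init__(self):
        if min(self.sd_site, self.sd_week, self.sd_resid) < 0:
            raise ValueError("random-effect SDs must be non-negative")


@dataclass
class TruthModel:
    """Truth for both simulated responses."""

    no2: PollutantTruth
    no: PollutantTruth

    @classmethod
    def default(cls) -> "TruthModel":
        no2 = PollutantTruth(
            intercept=40.1,
            spatial={
                "major_road_length_100": 5.6,
                "secondary_road_length_200": 10.4,
                "ndvi_50": -13.7,
            },
            met={"wind_speed": -11.0, "rh": -4.1},
            month={
                4: 0.0, 5: 12.0, 6: 17.9, 7: 28.9, 8: 27.7, 9: 22.2,
                10: 13.4, 11: 17.7, 12: 24.4, 1: 20.1, 2: 26.9, 3: 14.5,
            },
            sd_site=12.0,
            sd_week=8.0,
            sd_resid=10.0,
        )
        no = PollutantTruth(
            intercept=61.8,
            spatial={
                "major_road_length_100": 23.4,
                "secondary_road_length_50": 15.8,
                "poi_bar_500": 3.3,
            },
            met={"solar_radiation": -4.0},
            month={
                7: 0.0, 8: -4.4, 9: 9.3, 10: -1.5, 11: -9.1, 12: -12.9,
                1: -26.7, 2: -4.0, 3: -12.9, 4: -35.3, 5: -3.5, 6: 0.3,
            },
            sd_site=10.0,
            sd_week=9.0,
            sd_resid=17.0,
        )
        return cls(no2=no2, no=no)


@dataclass
class SamplingDesign:
    """Monitoring design: site locations/roles plus the (site, week) schedule."""

    sites: pd.DataFrame  # site_id, x, y, role in {fixed, rotating}
    schedule: pd.DataFrame  # site_id, iso_week

    @property
    def n_scheduled(self) -> int:
        return len(self.schedule)

    @classmethod
    def generate(
        cls,
        seed: int,
        layout: CityLayout,
        weeks: list[str],
        n_fixed: int = 10,
        n_rotating: int = 124,
    ) -> "SamplingDesign":
        """Fixed sites measured every week; each rotating site gets one week.

        Rotating sites are spread over the campaign weeks as evenly as the
        counts allow (round-robin over a shuffled week order), mirroring a
        year-long campaign with ~2-3 rotating sites deployed per week.
        """
        rng = np.random.default_rng(seed)
        xmin, ymin, xmax, ymax = layout.extent
        cx, cy = (xmin + xmax) / 2, (ymin + ymax) / 2

        def place(n: int) -> np.ndarray:
            pts = np.empty((n, 2))
            for k in range(n):
                if rng.uniform() < 0.6:  # over-represent the dense core
                    pts[k, 0] = np.clip(cx + rng.normal(0, 0.18 * (xmax - xmin)), xmin, xmax)
                    pts[k, 1] = np.clip(cy + rng.normal(0, 0.18 * (ymax - ymin)), ymin, ymax)
                else:
                    pts[k] = (rng.uniform(xmin, xmax), rng.uniform(ymin, ymax))
            return pts

        fixed_pts = place(n_fixed)
        rot_pts = place(n_rotating)
        sites = pd.DataFrame(
            {
                "site_id": [f"F{i:02d}" for i in range(n_fixed)]
                + [f"R{i:03d}" for i in range(n_rotating)],
                "x": np.concatenate([fixed_pts[:, 0], rot_pts[:, 0]]),
                "y": np.concatenate([fixed_pts[:, 1], rot_pts[:, 1]]),
                "role": ["fixed"] * n_fixed + ["rotating"] * n_rotating,
            }
        )
        rows = [
            {"site_id": f"F{i:02d}", "iso_week": w} for i in range(n_fixed) for w in weeks
        ]
        week_cycle = list(weeks)
        rng.shuffle(week_cycle)
        for i in range(n_rotating):
            rows.append({"site_id": f"R{i:03d}", "iso_week": week_cycle[i % len(week_cycle)]})
        return cls(sites=sites, schedule=pd.DataFrame(rows))


@dataclass
class SimulationResult:
    """Samples plus everything needed to check estimator recovery."""

    samples: pd.DataFrame  # site_id, iso_week, month, no2, no, nox + met columns
    site_features: pd.DataFrame  # raw (unstandardized) predictor table, by site_id
    standardization: dict[str, dict[str, tuple[float, float]]]  # pollutant -> col -> (mean, sd)
    site_effects: pd.DataFrame  # site_id x {no2, no}
    week_effects: pd.DataFrame  # iso_week x {no2, no}
    linear_predictor: pd.DataFrame  # fixed-effects part per record, per pollutant
    n_floored: dict[str, int]


def _standardize_cols(df: pd.DataFrame, cols) -> tuple[pd.DataFrame, dict]:
    out = {}
    params = {}
    for c in cols:
        mu = float(df[c].mean())
        sd = float(df[c].std(ddof=1))
        if sd == 0:
            raise ValueError(f"predictor {c!r} has zero variance across the design")
        out[c] = (df[c] - mu) / sd
        params[c] = (mu, sd)
    return pd.DataFrame(out, index=df.index), params


def simulate_concentrations(
    truth: TruthModel,
    layout: CityLayout,
    design: SamplingDesign,
    met: pd.DataFrame,
    seed: int,
    dropout: float = 0.0,
    site_features: pd.DataFrame | None = None,
) -> SimulationResult:
    """Simulate scheduled weekly samples from the truth model.

    Spatial predictors are standardized across sites and meteorology across
    the campaign weeks before the (standardized-scale) truth coefficients are
    applied.  Concentrations are floored at zero after noise; NOx = NO2 + NO.
    ``dropout`` uniformly removes scheduled records (both pollutants at once),
    emulating campaign gaps.  ``site_features`` short-circuits the (seed-free,
    layout-determined) feature extraction when simulating repeatedly on one
    layout.
    """
    missing = set(design.schedule["iso_week"]) - set(met.index)
    if missing:
        raise ValueError(f"scheduled weeks missing from meteorology: {sorted(missing)}")
    xmin, ymin, xmax, ymax = layout.extent
    bad = design.sites[
        ~design.sites["x"].between(xmin, xmax) | ~design.sites["y"].between(ymin, ymax)
    ]
    if len(bad):
        raise ValueError(f"design sites outside layout extent: {list(bad['site_id'])}")

    if site_features is None:
        extractor = FeatureExtractor(layout)
        feats = extractor.extract_table(design.sites.set_index("site_id")[["x", "y"]])
    else:
        feats = site_features

    rng = np.random.default_rng(seed)
    weeks = sorted(met.index)
    site_ids = list(design.sites["site_id"])

    standardization: dict[str, dict[str, tuple[float, float]]] = {}
    lin = {}
    for name, pol in (("no2", truth.no2), ("no", truth.no)):
        zs, sp = _standardize_cols(feats, list(pol.spatial))
        zm, mp = _standardize_cols(met, list(pol.met))
        standardization[name] = {**sp, **mp}
        spatial_part = pd.Series(0.0, index=feats.index)
        for c, b in pol.spatial.items():
            spatial_part += b * zs[c]
        met_part = pd.Series(0.0, index=met.index)
        for c, b in pol.met.items():
            met_part += b * zm[c]
        month_part = {w: pol.month[month_of_week(w)[1]] for w in weeks}
        lin[name] = {
            "spatial": spatial_part,  # by site_id
            "met": met_part,  # by iso_week
            "month": month_part,
        }

    site_eff = pd.DataFrame(
        {
            "no2": truth.no2.sd_site * rng.standard_normal(len(site_ids)),
            "no": truth.no.sd_site * rng.standard_normal(len(site_ids)),
        },
        index=pd.Index(site_ids, name="site_id"),
    )
    week_eff = pd.DataFrame(
        {
            "no2": truth.no2.sd_week * rng.standard_normal(len(weeks)),
            "no": truth.no.sd_week * rng.standard_normal(len(weeks)),
        },
        index=pd.Index(weeks, name="iso_week"),
    )

    records = []
    lp_rows = []
    n_floored = {"no2": 0, "no": 0}
    for rec in design.schedule.itertuples():
        s, w = rec.site_id, rec.iso_week
        row = {"site_id": s, "iso_week": w, "month": month_of_week(w)[1]}
        lp_row = {"site_id": s, "iso_week": w}
        for name, pol in (("no2", truth.no2), ("no", truth.no)):
            fixed = (
                pol.intercept
                + lin[name]["spatial"].loc[s]
                + lin[name]["met"].loc[w]
                + lin[name]["month"][w]
            )
            value = (
                fixed
                + site_eff.loc[s, name]
                + week_eff.loc[w, name]
                + pol.sd_resid * rng.standard_normal()
            )
            if value < 0:
                n_floored[name] += 1
                value = 0.0
            row[name] = float(value)
            lp_row[name] = float(fixed)
        row["nox"] = row["no2"] + row["no"]
        for c in met.columns:
            if c != "season":
                row[c] = met.loc[w, c]
        records.append(row)
        lp_rows.append(lp_row)

    samples = pd.DataFrame(records)
    lp = pd.DataFrame(lp_rows)
    if dropout > 0:
        keep = rng.uniform(size=len(samples)) >= dropout
        samples = samples[keep].reset_index(drop=True)
        lp = lp[keep].reset_index(drop=True)
    return SimulationResult(
        samples=samples,
        site_features=feats,
        standardization=standardization,
        site_effects=site_eff,
        week_effects=week_eff,
        linear_predictor=lp,
        n_floored=n_floored,
    )
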