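"""Weekly meteorology: calendar conventions and a seasonal synthetic generator.

The city has two marked seasons: the dry, dusty Harmattan (November–February),
with stagnant local meteorology — weak winds, few rain days, shallow mixing —
and the wet season (May–October).  March–April are transitional.  Weekly series
are indexed by ISO-8601 year-week labels; the calendar month of a week is the
month containing its Thursday, which assigns every ISO week to exactly one
month.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

HARMATTAN_MONTHS = frozenset({11, 12, 1, 2})
WET_MONTHS = frozenset({5, 6, 7, 8, 9, 10})

MET_COLUMNS = [
    "temperature",
    "rh",
    "wind_speed",
    "mixing_depth",
    "solar_radiation",
    "vapor_mixing_ratio",
    "rain_days",
]


def iso_week_label(date: dt.date) -> str:
    """ISO-8601 year-week label, e.g. ``2019-W14``."""
    y, w, _ = date.isocalendar()
    return f"{y}-W{w:02d}"


def week_thursday(label: str) -> dt.date:
    """The Thursday of an ISO week label."""
    year, week = label.split("-W")
    return dt.date.fromisocalendar(int(year), int(week), 4)


def month_of_week(label: str) -> tuple[int, int]:
    """(year, month) containing the week's Thursday."""
    d = week_thursday(label)
    return d.year, d.month


def is_harmattan(label: str) -> bool:
    return month_of_week(label)[1] in HARMATTAN_MONTHS


def season_of_week(label: str) -> str:
    """'harmattan', 'non_harmattan' (May–Oct) or 'transitional' (Mar–Apr)."""
    m = month_of_week(label)[1]
    if m in HARMATTAN_MONTHS:
        return "harmattan"
    if m in WET_MONTHS:
        return "non_harmattan"
    return "transitional"


def week_sequence(start_date: dt.date, n_weeks: int) -> list[str]:
    """Consecutive ISO week labels starting at the week containing start_date."""
    if n_weeks < 1:
        raise ValueError(f"n_weeks must be >= 1, got {n_weeks}")
    start = start_date - dt.timedelta(days=start_date.weekday())  # back to Monday
    return [iso_week_label(start + dt.timedelta(weeks=k)) for k in range(n_weeks)]


def rain_days(daily_rain_mm, threshold_mm: float = 0.0) -> int:
    """Number of days in a week with rainfall strictly above the threshold."""
    daily = np.asarray(daily_rain_mm, dtype=float)
    return int(np.sum(daily > threshold_mm))


@dataclass(frozen=True)
class MetRegime:
    """Mean weekly conditions for one season (units in column comments)."""

    temperature: float  # degC
    rh: float  # %
    wind_speed: float  # m/s
    mixing_depth: float  # m
    solar_radiation: float  # W/m2 weekly median of daily medians
    vapor_mixing_ratio: float  # g/kg
    rain_day_prob: float  # per-day probability of rain


@dataclass(frozen=True)
class MetConfig:
    """Two-regime seasonal configuration; transitional weeks use the average."""

    harmattan: MetRegime = field(
        default_factory=lambda: MetRegime(
            temperature=29.0,
            rh=65.0,
            wind_speed=1.8,
            mixing_depth=450.0,
            solar_radiation=210.0,
            vapor_mixing_ratio=14.0,
            rain_day_prob=0.04,
        )
    )
    non_harmattan: MetRegime = field(
        default_factory=lambda: MetRegime(
            temperature=27.0,
            rh=80.0,
            wind_speed=3.2,
            mixing_depth=650.0,
            solar_radiation=180.0,
            vapor_mixing_ratio=17.5,
            rain_day_prob=0.45,
        )
    )
    sd_temperature: float = 0.8
    sd_rh: float = 4.0
    sd_wind_speed: float = 0.4
    sd_mixing_depth: float = 60.0
    sd_solar_radiation: float = 25.0
    sd_vapor_mixing_ratio: float = 1.0

    def with_equal_regimes(self) -> "MetConfig":
        """Both seasons drawn from the Harmattan regime (for null checks)."""
        return replace(self, non_harmattan=self.harmattan)


def generate_meteorology(
    seed: int,
    n_weeks: int,
    start_date: dt.date = dt.date(2019, 4, 1),
    config: MetConfig | None = None,
) -> pd.DataFrame:
    """Synthetic weekly meteorology indexed by ISO week label.

    Harmattan weeks are drawn from a regime with lower wind speed and fewer
    rain days than non-Harmattan weeks (configurable); transitional weeks
    (March–April) use the midpoint of the two regimes.  RH is clipped to
    [0, 100] and all physically non-negative quantities are floored at 0.
    """
    if config is None:
        config = MetConfig()
    weeks = week_sequence(start_date, n_weeks)
    rng = np.random.default_rng(seed)
    rows = []
    for label in weeks:
        season = season_of_week(label)
        if season == "harmattan":
            reg = config.harmattan
        elif season == "non_harmattan":
            reg = config.non_harmattan
        else:
            h, w = config.harmattan, config.non_harmattan
            reg = MetRegime(
                *(0.5 * (a + b) for a, b in zip(
                    (h.temperature, h.rh, h.wind_speed, h.mixing_depth,
                     h.solar_radiation, h.vapor_mixing_ratio, h.rain_day_prob),
                    (w.temperature, w.rh, w.wind_speed, w.mixing_depth,
                     w.solar_radiation, w.vapor_mixing_ratio, w.rain_day_prob),
                ))
            )
        rows.append(
            {
                "iso_week": label,
                "season": season,
                "temperature": reg.temperature + config.sd_temperature * rng.standard_normal(),
                "rh": float(np.clip(reg.rh + config.sd_rh * rng.standard_normal(), 0.0, 100.0)),
                "wind_speed": max(0.0, reg.wind_speed + config.sd_wind_speed * rng.standard_normal()),
                "mixing_depth": max(
                    1.0, reg.mixing_depth + config.sd_mixing_depth * rng.standard_normal()
                ),
                "solar_radiation": max(
                    0.0, reg.solar_radiation + config.sd_solar_radiation * rng.standard_normal()
                ),
                "vapor_mixing_ratio": max(
                    0.0,
                    reg.vapor_mixing_ratio
                    + config.sd_vapor_mixing_ratio * rng.standard_normal(),
                ),
                "rain_days": int(rng.binomial(7, reg.rain_day_prob)),
            }
        )
    return pd.DataFrame(rows).set_index("iso_week")


def met_features(met: pd.DataFrame, iso_week: str) -> pd.Series:
    """The meteorology feature vector for one week.

    Raises KeyError naming the week if it is absent from the series.
    """
    if iso_week not in met.index:
        raise KeyError(f"week {iso_week!r} not present in the meteorology series")
    return met.loc[iso_week, MET_COLUMNS]
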