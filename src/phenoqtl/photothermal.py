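"""Photothermal-unit (PTU) accumulation over phenological intervals.

Photothermal time is a composite of temperature and photoperiod: each day
contributes the daylight fraction of the day multiplied by the excess of
the daylight mean temperature over a base temperature,

    PTU = sum_i  lambda_i * (mu_Li - mu_b)    for days with mu_Li > mu_b,

where ``lambda_i = photoperiod / 24`` and ``mu_Li`` is the mean soil/air
temperature during daylight hours.  Days at or below the base temperature
contribute nothing.  The default base temperature is 3 degC, the optimized
base for modelling the developmental rate of Arabidopsis Col-0.

Units are degC * daylight-days.  Intervals are half-open ``[start, end)``
by default: the germination day counts toward the vegetative period, the
flowering-initiation day does not, so vegetative PTU (g -> fi) plus
flowering PTU (fi -> ft) equals the total g -> ft PTU exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "EnvironmentSeries",
    "PTUConfig",
    "PTUValue",
    "daylight_mean_from_log",
    "daily_ptu",
    "accumulate_ptu",
    "ptu_for_records",
]


@dataclass(frozen=True)
class EnvironmentSeries:
    """Daily environment record: daylight mean temperature and photoperiod.

    Days are integer offsets from a run-level reference date, contiguous
    and strictly increasing.  Photoperiod is in hours in [0, 24].
    """

    day: np.ndarray
    temp: np.ndarray
    photoperiod: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        day = np.asarray(self.day, dtype=np.int64)
        temp = np.asarray(self.temp, dtype=float)
        photo = np.asarray(self.photoperiod, dtype=float)
        if not (day.shape == temp.shape == photo.shape) or day.ndim != 1:
            raise ValueError("day, temp and photoperiod must be 1-D and equal length")
        if day.size == 0:
            raise ValueError("environment series is empty")
        if not np.all(np.diff(day) == 1):
            gaps = day[np.flatnonzero(np.diff(day) != 1)]
            raise ValueError(f"days must be contiguous; gap(s) after day(s) {gaps.tolist()}")
        if np.any(photo < 0) or np.any(photo > 24):
            raise ValueError("photoperiod must lie in [0, 24] hours")
        object.__setattr__(self, "day", day)
        object.__setattr__(self, "temp", temp)
        object.__setattr__(self, "photoperiod", photo)

    @property
    def light_fraction(self) -> np.ndarray:
        """Photoperiod as a fraction of 24 h (lambda_i)."""
        return self.photoperiod / 24.0

    @property
    def start(self) -> int:
        return int(self.day[0])

    @property
    def end(self) -> int:
        """One past the last covered day."""
        return int(self.day[-1]) + 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"day": self.day, "mean_daylight_temp": self.temp, "photoperiod_hours": self.photoperiod}
        )


@dataclass(frozen=True)
class PTUConfig:
    """Parameters of the photothermal summation.

    base_temp: base temperature mu_b in degC; days whose daylight mean does
        not exceed it contribute zero.  Default 3 degC.
    interval_convention: "half_open" counts [start, end); "closed" counts
        [start, end].  Half-open is the default because it makes PTU
        additive over abutting intervals.
    """

    base_temp: float = 3.0
    interval_convention: Literal["half_open", "closed"] = "half_open"

    def __post_init__(self) -> None:
        if not np.isfinite(self.base_temp):
            raise ValueError("base_temp must be finite")
        if self.interval_convention not in ("half_open", "closed"):
            raise ValueError(f"unknown interval convention {self.interval_convention!r}")


@dataclass(frozen=True)
class PTUValue:
    """Accumulated PTU over one interval, with bookkeeping."""

    value: float
    interval: tuple[int, int]
    n_contributing_days: int


def daily_ptu(temp: float, light_fraction: float, config: PTUConfig = PTUConfig()) -> float:
    """One day's PTU contribution: lambda * (mu_L - mu_b) if mu_L > mu_b else 0.

    The inequality is strict: a day exactly at the base temperature
    contributes nothing.
    """
    lam = np.asarray(light_fraction, dtype=float)
    if np.any(lam < 0) or np.any(lam > 1):
        raise ValueError("light_fraction must lie in [0, 1]")
    t = np.asarray(temp, dtype=float)
    out = np.where(t > config.base_temp, lam * (t - config.base_temp), 0.0)
    return float(out) if out.ndim == 0 else out


def _daily_contributions(env: EnvironmentSeries, config: PTUConfig) -> np.ndarray:
    excess = env.temp - config.base_temp
    return np.where(env.temp > config.base_temp, env.light_fraction * excess, 0.0)


def accumulate_ptu(
    env: EnvironmentSeries, start: int, end: int, config: PTUConfig = PTUConfig()
) -> PTUValue:
    """Sum daily PTU contributions over [start, end) (or [start, end] if closed).

    Raises if the interval extends beyond the series coverage; missing
    environment days are never silently interpolated.
    """
    if start > end:
        raise ValueError(f"start day {start} is after end day {end}")
    last_needed = end if config.interval_convention == "closed" else end - 1
    if start < env.start or (last_needed >= env.end and end > start):
        raise ValueError(
            f"interval [{start}, {end}] not covered by environment "
            f"[{env.start}, {env.end - 1}]; uncovered range "
            f"[{max(start, env.end)}, {last_needed}]"
            if start >= env.start
            else f"interval [{start}, {end}] not covered by environment "
            f"[{env.start}, {env.end - 1}]; uncovered range [{start}, {env.start - 1}]"
        )
    if end == start and config.interval_convention == "half_open":
        return PTUValue(0.0, (start, end), 0)
    contrib = _daily_contributions(env, config)
    i0 = start - env.start
    i1 = last_needed - env.start + 1
    window = contrib[i0:i1]
    return PTUValue(float(window.sum()), (start, end), int(np.count_nonzero(window)))


def daylight_mean_from_log(
    records: pd.DataFrame,
    daylight: pd.DataFrame,
    label: str = "",
) -> tuple[EnvironmentSeries, list[int]]:
    """Aggregate sub-daily temperature-logger readings into a daily series.

    Parameters
    ----------
    records
        Columns ``day`` (integer offset), ``hour`` (fractional hour of day),
        ``temp`` (degC).  Typically one reading every 30 min.
    daylight
        Columns ``day``, ``sunrise``, ``sunset`` (hours).  The daylight
        window is half-open [sunrise, sunset); readings inside it are
        averaged without weighting.  Photoperiod = sunset - sunrise.

    Returns
    -------
    (series, gap_days)
        ``gap_days`` lists days that had no daylight reading; their
        temperature is NaN in the series rather than being interpolated.
    """
    required = {"day", "hour", "temp"}
    if not required.issubset(records.columns):
        raise ValueError(f"logger records need columns {sorted(required)}")
    if not {"day", "sunrise", "sunset"}.issubset(daylight.columns):
        raise ValueError("daylight table needs columns day, sunrise, sunset")

    daylight = daylight.sort_values("day").reset_index(drop=True)
    days = daylight["day"].to_numpy(dtype=np.int64)
    sunrise = daylight["sunrise"].to_numpy(dtype=float)
    sunset = daylight["sunset"].to_numpy(dtype=float)

    merged = records.merge(daylight, on="day", how="inner")
    in_window = (merged["hour"] >= merged["sunrise"]) & (merged["hour"] < merged["sunset"])
    day_means = merged.loc[in_window].groupby("day")["temp"].mean()

    temps = np.full(days.size, np.nan)
    present = np.isin(days, day_means.index.to_numpy())
    temps[present] = day_means.loc[days[present]].to_numpy()
    gap_days = days[~present].tolist()
    series = EnvironmentSeries(day=days, temp=temps, photoperiod=sunset - sunrise, label=label)
    return series, gap_days


def ptu_for_records(
    records: pd.DataFrame,
    env_by_regime: dict[str, EnvironmentSeries],
    config: PTUConfig = PTUConfig(),
) -> pd.DataFrame:
    """Vegetative (g -> fi) and flowering (fi -> ft) PTU for each plant.

    ``records`` is a phenology table with at least ``plant_id``, ``regime``,
    ``germination``, ``flowering_init``, ``flowering_term`` columns (day
    offsets; the last two may be NaN).  Plants missing an event get NaN PTU
    and ``flagged=True``; an unknown regime label raises.
    """
    missing_regimes = set(records["regime"]) - set(env_by_regime)
    if missing_regimes:
        raise KeyError(f"no environment series for regime(s) {sorted(missing_regimes)}")

    rows = []
    for rec in records.itertuples(index=False):
        env = env_by_regime[rec.regime]
        g = rec.germination
        fi = getattr(rec, "flowering_init", np.nan)
        ft = getattr(rec, "flowering_term", np.nan)
        veg = np.nan
        flow = np.nan
        flagged = False
        if pd.notna(fi):
            veg = accumulate_ptu(env, int(g), int(fi), config).value
        else:
            flagged = True
        if pd.notna(fi) and pd.notna(ft):
            flow = accumulate_ptu(env, int(fi), int(ft), config).value
        else:
            flagged = True
        rows.append(
            {
                "plant_id": rec.plant_id,
                "regime": rec.regime,
                "vegetative_ptu": veg,
                "flowering_ptu": flow,
                "flagged": flagged,
            }
        )
    return pd.DataFrame(rows)
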