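"""Daily weather input and synthesis.

Site simulations are driven by daily minimum/maximum temperature (degC),
rainfall (mm), incident solar radiation (MJ/m2) and vapour pressure (kPa).
Series can be read from a met CSV or synthesized from a site climatology with
a seeded stochastic generator.

Met CSV schema
--------------
Header ``date,tmin_c,tmax_c,rain_mm,rad_mj_m2,vp_kpa``, ISO-8601 dates, one
row per day.  Files use 365-day years: February 29 never appears, and the
gap check treats Feb 28 -> Mar 1 as consecutive in leap years.  Southern-
hemisphere seasonality (warmest around January, wettest in winter for the
Mediterranean sites) is the default calendar.
"""

from __future__ import annotations

import calendar
import datetime as dt
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MET_COLUMNS = ["date", "tmin_c", "tmax_c", "rain_mm", "rad_mj_m2", "vp_kpa"]

DAYS_IN_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])

SOLAR_CONSTANT = 0.0820  # MJ/m2/min


class MetSchemaError(ValueError):
    """Met CSV header does not match the declared schema."""


class MetGapError(ValueError):
    """Met series has missing or non-consecutive days."""


class MetRecordError(ValueError):
    """A met record violates a physical invariant (named by date)."""


@dataclass(frozen=True)
class DailyWeather:
    """One day of meteorological drivers."""

    date: dt.date
    tmin: float  # degC
    tmax: float  # degC
    rain: float  # mm/d
    radiation: float  # MJ/m2/d
    vapour_pressure: float  # kPa

    def __post_init__(self) -> None:
        if self.tmin > self.tmax:
            raise MetRecordError(f"{self.date}: tmin {self.tmin} > tmax {self.tmax}")
        if self.rain < 0 or self.radiation < 0 or self.vapour_pressure < 0:
            raise MetRecordError(f"{self.date}: negative rain/radiation/vapour pressure")

    @property
    def tmean(self) -> float:
        return 0.5 * (self.tmin + self.tmax)


@dataclass
class ClimateStats:
    """Monthly climatology a synthetic series is drawn from.

    ``monthly_*`` vectors run January..December.  ``rain_day_probability`` is
    the stationary wet-day probability per month; wet-day amounts are
    exponential with the mean implied by the monthly rainfall total.
    """

    monthly_tmin_mean: list[float]
    monthly_tmax_mean: list[float]
    monthly_rain_mean: list[float]
    annual_rain_target: float
    rain_day_probability: list[float]
    temp_sd: float = 2.2
    seasonality_label: str = "temperate"
    latitude: float = -35.0
    rain_autocorr: float = 0.3  # lag-1 wet-day persistence
    diurnal_min_range: float = 3.0  # floor on tmax - tmin, degC

    def __post_init__(self) -> None:
        for name in ("monthly_tmin_mean", "monthly_tmax_mean", "monthly_rain_mean",
                     "rain_day_probability"):
            if len(getattr(self, name)) != 12:
                raise ValueError(f"{name} must have 12 monthly values")
        if abs(sum(self.monthly_rain_mean) - self.annual_rain_target) > 0.01 * self.annual_rain_target:
            raise ValueError("monthly rainfall must sum to the annual target within 1%")
        if not all(0.0 <= p <= 1.0 for p in self.rain_day_probability):
            raise ValueError("rain_day_probability values must lie in [0, 1]")
        if self.temp_sd < 0:
            raise ValueError("temp_sd must be non-negative")


def _is_next_day(a: dt.date, b: dt.date) -> bool:
    if b == a + dt.timedelta(days=1):
        return True
    # 365-day convention: Feb 29 is skipped in leap years
    if a.month == 2 and a.day == 28 and calendar.isleap(a.year):
        return b == dt.date(a.year, 3, 1)
    return False


def read_met(path) -> pd.DataFrame:
    """Read and validate a met CSV.

    Returns a DataFrame with the schema columns (``date`` as ``datetime.date``
    objects), one gap-free row per day.  Raises :class:`MetSchemaError`,
    :class:`MetGapError` or :class:`MetRecordError` on contract violations.
    """
    df = pd.read_csv(path)
    if list(df.columns) != MET_COLUMNS:
        raise MetSchemaError(
            f"expected header {','.join(MET_COLUMNS)}, got {','.join(map(str, df.columns))}"
        )
    if len(df) == 0:
        raise MetGapError("met file contains no records")
    dates = [dt.date.fromisoformat(str(d)) for d in df["date"]]
    for prev, cur in zip(dates, dates[1:]):
        if not _is_next_day(prev, cur):
            raise MetGapError(f"non-consecutive dates: {prev} -> {cur}")
    for i, d in enumerate(dates):
        row = df.iloc[i]
        if row["tmin_c"] > row["tmax_c"]:
            raise MetRecordError(f"{d}: tmin {row['tmin_c']} > tmax {row['tmax_c']}")
        if row["rain_mm"] < 0:
            raise MetRecordError(f"{d}: negative rainfall {row['rain_mm']}")
        if row["rad_mj_m2"] < 0 or row["vp_kpa"] < 0:
            raise MetRecordError(f"{d}: negative radiation or vapour pressure")
    out = df.copy()
    out["date"] = dates
    return out


def write_met(df: pd.DataFrame, path) -> None:
    """Write a met DataFrame with the canonical header and float formatting."""
    out = df.copy()
    out["date"] = [d.isoformat() for d in out["date"]]
    out.to_csv(path, index=False, float_format="%.3f")


def iter_days(df: pd.DataFrame):
    """Yield :class:`DailyWeather` records from a validated met frame."""
    for row in df.itertuples(index=False):
        yield DailyWeather(row.date, row.tmin_c, row.tmax_c, row.rain_mm,
                           row.rad_mj_m2, row.vp_kpa)


def extraterrestrial_radiation(latitude_deg: float, doy: int) -> float:
    """Top-of-atmosphere solar radiation, MJ/m2/d (FAO-56 form)."""
    phi = math.radians(latitude_deg)
    dr = 1.0 + 0.033 * math.cos(2.0 * math.pi * doy / 365.0)
    delta = 0.409 * math.sin(2.0 * math.pi * doy / 365.0 - 1.39)
    x = -math.tan(phi) * math.tan(delta)
    ws = math.acos(min(1.0, max(-1.0, x)))
    ra = (24.0 * 60.0 / math.pi) * SOLAR_CONSTANT * dr * (
        ws * math.sin(phi) * math.sin(delta) + math.cos(phi) * math.cos(delta) * math.sin(ws)
    )
    return max(0.0, ra)


def saturation_vapour_pressure(t: float) -> float:
    """Saturation vapour pressure at temperature t (degC), kPa (Tetens)."""
    return 0.6108 * math.exp(17.27 * t / (t + 237.3))


def _monthly_to_daily(monthly: list[float]) -> np.ndarray:
    """Linear interpolation of mid-month values onto a 365-day year.

    Constructed so that calendar-month means of the daily curve stay close to
    the target monthly means.
    """
    mid = np.cumsum(DAYS_IN_MONTH) - DAYS_IN_MONTH / 2.0  # mid-month day-of-year
    x = np.concatenate([[mid[-1] - 365.0], mid, [mid[0] + 365.0]])
    y = np.concatenate([[monthly[-1]], monthly, [monthly[0]]])
    doy = np.arange(1, 366)
    return np.interp(doy, x, y)


_MONTH_OF_DOY = np.repeat(np.arange(12), DAYS_IN_MONTH)  # 0-based month per doy-1


def synthesize_weather(stats: ClimateStats, n_years: int, seed: int,
                       start_year: int = 1971) -> pd.DataFrame:
    """Generate a seeded synthetic daily met series matching a climatology.

    Rainfall: first-order two-state (wet/dry) occurrence chain with per-month
    stationary wet probability and persistence ``rain_autocorr``; wet-day
    amounts exponential with mean = monthly total / expected wet days.
    Temperature: interpolated monthly-mean curves plus correlated Gaussian
    noise.  Radiation: extraterrestrial radiation times a transmissivity
    reduced on rain days.  Vapour pressure: saturation at tmin (dew-point
    proxy).  Years are 365 days (no Feb 29).
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    rng = np.random.default_rng(seed)
    n = 365 * n_years
    doy = np.tile(np.arange(1, 366), n_years)
    month = _MONTH_OF_DOY[doy - 1]

    pi = np.asarray(stats.rain_day_probability)[month]
    rho = stats.rain_autocorr
    u = rng.random(n)
    wet = np.empty(n, dtype=bool)
    prev = u[0] < pi[0]
    wet[0] = prev
    for i in range(1, n):
        p = pi[i] + rho * (1.0 - pi[i]) if prev else pi[i] * (1.0 - rho)
        prev = u[i] < p
        wet[i] = prev
    exp_wet_days = np.maximum(np.asarray(stats.rain_day_probability) * DAYS_IN_MONTH, 1e-9)
    wet_mean = np.asarray(stats.monthly_rain_mean) / exp_wet_days
    rain = np.where(wet, rng.exponential(1.0, n) * wet_mean[month], 0.0)

    tmin_base = np.tile(_monthly_to_daily(stats.monthly_tmin_mean), n_years)
    tmax_base = np.tile(_monthly_to_daily(stats.monthly_tmax_mean), n_years)
    noise = rng.normal(0.0, 1.0, n)
    # shared anomaly keeps tmin/tmax coherent; rain days run cooler by day
    anom = stats.temp_sd * noise
    tmin = tmin_base + anom + np.where(wet, 0.5, 0.0)
    tmax = tmax_base + anom - np.where(wet, 1.5, 0.0)
    tmax = np.maximum(tmax, tmin + stats.diurnal_min_range)

    ra = np.array([extraterrestrial_radiation(stats.latitude, int(d)) for d in np.arange(1, 366)])
    ra = np.tile(ra, n_years)
    tau = np.where(wet, 0.40, 0.70)
    radiation = ra * tau
    vp = np.array([saturation_vapour_pressure(t) for t in tmin])

    dates = []
    d = dt.date(start_year, 1, 1)
    while len(dates) < n:
        if not (d.month == 2 and d.day == 29):
            dates.append(d)
        d += dt.timedelta(days=1)

    return pd.DataFrame({
        "date": dates,
        "tmin_c": np.round(tmin, 3),
        "tmax_c": np.round(tmax, 3),
        "rain_mm": np.round(rain, 3),
        "rad_mj_m2": np.round(radiation, 3),
        "vp_kpa": np.round(vp, 3),
    })
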