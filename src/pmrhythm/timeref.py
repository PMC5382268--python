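"""Death timestamps to circular time-of-day and time-of-year coordinates.

Each subject contributes a single (date, local clock time) of death together
with the latitude/longitude and UTC offset of the place of death.  Rhythm
models need these as angles:

- a diurnal angle on a 24-h circle, under one of three reference
  conventions: zeitgeber time (0 = sunrise on the date of death), local
  clock time (0 = midnight), or time relative to the midpoint of the dark
  period (which is season-invariant);
- a seasonal angle on a 365-day circle with 0 at January 1.

Sunrise and sunset are computed with the NOAA low-accuracy solar equations
(fractional year, equation of time, solar declination, hour angle at zenith
90.833 deg, i.e. including atmospheric refraction and the solar disc
radius).  Accuracy is a couple of minutes, well below the precision of
recorded death times.  Polar dates without a sunrise raise an error; this
module does not handle polar day/night.

The seasonal period is fixed at 365 days; February 29 is folded onto the
same day-fraction as February 28 so the angle stays in [0, 2*pi).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

TWO_PI = 2.0 * np.pi

#: zenith angle (degrees) defining official sunrise/sunset
SUN_ZENITH_DEG = 90.833

#: metadata columns required by every reader/consumer in the package
METADATA_COLUMNS = [
    "sample_id",
    "date_of_death",
    "clock_time_of_death",
    "latitude",
    "longitude",
    "utc_offset",
    "age_death",
    "sex_male",
    "pmi_hours",
    "depression",
    "ad_global_score",
    "ad_reagan_dx",
    "batch",
    "rin",
    "chip_crosscorr",
]


class PolarNightError(ValueError):
    """Raised when the sun does not rise or set on the requested date."""


@dataclass(frozen=True)
class DeathTimestamp:
    """A single subject's death time and place.

    Parameters
    ----------
    date : datetime.date
        Calendar date of death.
    clock_time : float
        Local clock time of death in decimal hours, in [0, 24).
    latitude, longitude : float
        Coordinates of the place of death, in degrees.
    utc_offset : float
        Local-time offset from UTC in hours (negative west of Greenwich).
    """

    date: _dt.date
    clock_time: float
    latitude: float
    longitude: float
    utc_offset: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.clock_time < 24.0):
            raise ValueError(f"clock_time {self.clock_time!r} not in [0, 24)")
        if not (-90.0 <= self.latitude <= 90.0):
            raise ValueError(f"latitude {self.latitude!r} out of range")
        if not (-180.0 <= self.longitude <= 180.0):
            raise ValueError(f"longitude {self.longitude!r} out of range")


@dataclass(frozen=True)
class SunEvents:
    """Sunrise, sunset and the dark-period midpoint, local clock hours."""

    sunrise: float
    sunset: float
    dark_midpoint: float


@dataclass(frozen=True)
class AngularTimes:
    """Diurnal angles under the three reference conventions, plus seasonal.

    All angles are radians in [0, 2*pi); 2*pi corresponds to 24 h for the
    diurnal angles and to 365 days for the seasonal angle.
    """

    diurnal_zt: float
    diurnal_clock: float
    diurnal_darkmid: float
    seasonal: float


def _day_of_year_365(dates: pd.Series | np.ndarray) -> np.ndarray:
    """1-based day of year on a fixed 365-day calendar (Feb 29 -> day 59)."""
    dates = pd.DatetimeIndex(pd.to_datetime(np.asarray(dates)))
    doy = np.asarray(dates.dayofyear, dtype=float)
    leap = np.asarray(dates.is_leap_year)
    # In a leap year Feb 29 has dayofyear 60; fold it (and every later day)
    # back by one so Feb 29 shares Feb 28's day-fraction on the 365-day circle.
    doy = np.where(leap & (doy > 59), doy - 1.0, doy)
    return doy


def _sun_hour_angle_deg(doy: np.ndarray, hour_utc: float, latitude: np.ndarray):
    """NOAA fractional-year solar position terms.

    Returns (equation_of_time_minutes, hour_angle_deg_at_zenith).
    """
    gamma = TWO_PI / 365.0 * (doy - 1.0 + (hour_utc - 12.0) / 24.0)
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * np.cos(gamma)
        - 0.032077 * np.sin(gamma)
        - 0.014615 * np.cos(2 * gamma)
        - 0.040849 * np.sin(2 * gamma)
    )
    decl = (
        0.006918
        - 0.399912 * np.cos(gamma)
        + 0.070257 * np.sin(gamma)
        - 0.006758 * np.cos(2 * gamma)
        + 0.000907 * np.sin(2 * gamma)
        - 0.002697 * np.cos(3 * gamma)
        + 0.00148 * np.sin(3 * gamma)
    )
    lat_rad = np.deg2rad(latitude)
    zenith = np.deg2rad(SUN_ZENITH_DEG)
    cos_ha = np.cos(zenith) / (np.cos(lat_rad) * np.cos(decl)) - np.tan(lat_rad) * np.tan(decl)
    return eqtime, decl, cos_ha


def compute_sun_events(
    date: _dt.date,
    latitude: float,
    longitude: float,
    utc_offset: float,
) -> SunEvents:
    """Sunrise, sunset and dark-period midpoint for one date and site.

    Uses the NOAA low-accuracy equations at zenith 90.833 deg.  The dark
    midpoint is the circular midpoint of the interval from sunset to the
    next day's sunrise.

    Raises
    ------
    PolarNightError
        If the sun does not rise (or set) on ``date`` at ``latitude``.
    """
    sunrise, sunset = _sunrise_sunset_arrays(
        np.array([pd.Timestamp(date)]), np.array([latitude]), np.array([longitude]), utc_offset
    )
    next_rise, _ = _sunrise_sunset_arrays(
        np.array([pd.Timestamp(date) + pd.Timedelta(days=1)]),
        np.array([latitude]),
        np.array([longitude]),
        utc_offset,
    )
    dark = (sunset + ((next_rise + 24.0 - sunset) % 24.0) / 2.0) % 24.0
    return SunEvents(float(sunrise[0]), float(sunset[0]), float(dark[0]))


def _sunrise_sunset_arrays(dates, latitude, longitude, utc_offset):
    """Vectorized sunrise/sunset in local clock hours."""
    doy = _day_of_year_365(pd.Series(dates))
    lat = np.asarray(latitude, dtype=float)
    lon = np.asarray(longitude, dtype=float)
    eqtime, _decl, cos_ha = _sun_hour_angle_deg(doy, 12.0, lat)
    bad = np.abs(cos_ha) > 1.0
    if np.any(bad):
        i = int(np.argmax(bad))
        raise PolarNightError(
            f"no sunrise/sunset on {pd.Timestamp(np.asarray(dates)[i]).date()} "
            f"at latitude {lat.flat[min(i, lat.size - 1)]:.2f}"
        )
    ha_deg = np.rad2deg(np.arccos(cos_ha))
    # minutes UTC; longitude positive east
    sunrise_utc = 720.0 - 4.0 * (lon + ha_deg) - eqtime
    sunset_utc = 720.0 - 4.0 * (lon - ha_deg) - eqtime
    off = np.asarray(utc_offset, dtype=float) * 60.0
    sunrise = ((sunrise_utc + off) / 60.0) % 24.0
    sunset = ((sunset_utc + off) / 60.0) % 24.0
    return sunrise, sunset


def to_angles(ts: DeathTimestamp, sun: SunEvents) -> AngularTimes:
    """Map one death timestamp to the three diurnal angles and the seasonal angle."""
    zt = TWO_PI * ((ts.clock_time - sun.sunrise) % 24.0) / 24.0
    clock = TWO_PI * ts.clock_time / 24.0
    darkmid = TWO_PI * ((ts.clock_time - sun.dark_midpoint) % 24.0) / 24.0
    doy = _day_of_year_365(pd.Series([pd.Timestamp(ts.date)]))[0]
    seasonal = (TWO_PI * (doy - 1.0 + ts.clock_time / 24.0) / 365.0) % TWO_PI
    return AngularTimes(zt % TWO_PI, clock % TWO_PI, darkmid % TWO_PI, seasonal)


def angle_hours(angle: float | np.ndarray, period_hours: float = 24.0):
    """Convert an angle in radians back to hours on the given period."""
    return (np.asarray(angle, dtype=float) * period_hours / TWO_PI) % period_hours


def hours_angle(hours: float | np.ndarray, period_hours: float = 24.0):
    """Convert hours on the given period to radians in [0, 2*pi)."""
    return (np.asarray(hours, dtype=float) * TWO_PI / period_hours) % TWO_PI


ANGLE_COLUMNS = ["theta_zt", "theta_clock", "theta_darkmid", "psi_season"]
SUN_COLUMNS = ["sunrise_h", "sunset_h", "darkmid_h"]


def add_time_columns(meta: pd.DataFrame) -> pd.DataFrame:
    """Append sun-event and angle columns to a sample metadata table.

    Expects the standard metadata schema (see :data:`METADATA_COLUMNS`).
    Returns a copy with columns ``sunrise_h``, ``sunset_h``, ``darkmid_h``,
    ``theta_zt``, ``theta_clock``, ``theta_darkmid``, ``psi_season``.
    """
    meta = meta.copy()
    dates = pd.to_datetime(meta["date_of_death"])
    lat = meta["latitude"].to_numpy(dtype=float)
    lon = meta["longitude"].to_numpy(dtype=float)
    off = meta["utc_offset"].to_numpy(dtype=float)
    clock = meta["clock_time_of_death"].to_numpy(dtype=float)
    if np.any((clock < 0) | (clock >= 24)):
        raise ValueError("clock_time_of_death values must lie in [0, 24)")

    sunrise, sunset = _sunrise_sunset_arrays(dates.to_numpy(), lat, lon, off)
    next_rise, _ = _sunrise_sunset_arrays(
        (dates + pd.Timedelta(days=1)).to_numpy(), lat, lon, off
    )
    darkmid = (sunset + ((next_rise + 24.0 - sunset) % 24.0) / 2.0) % 24.0

    doy = _day_of_year_365(dates)
    meta["sunrise_h"] = sunrise
    meta["sunset_h"] = sunset
    meta["darkmid_h"] = darkmid
    meta["theta_zt"] = TWO_PI * ((clock - sunrise) % 24.0) / 24.0
    meta["theta_clock"] = TWO_PI * clock / 24.0
    meta["theta_darkmid"] = TWO_PI * ((clock - darkmid) % 24.0) / 24.0
    meta["psi_season"] = (TWO_PI * (doy - 1.0 + clock / 24.0) / 365.0) % TWO_PI
    return meta
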