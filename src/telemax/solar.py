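"""NOAA solar geometry: sunrise, sunset, and solar noon in UTC.

Implements the NOAA Solar Calculation equations (fractional year, equation
of time, solar declination, and the hour angle at the standard refraction
zenith of 90.833 deg).  Accuracy is a couple of minutes, which is ample for
a +/- 1 h daylight margin filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, datetime, timedelta, timezone

ZENITH_DEG = 90.833  # official sunrise/sunset zenith incl. refraction


class PolarDayNight(ValueError):
    """The sun does not rise or set at this latitude and date."""


@dataclass(frozen=True)
class SolarDay:
    sunrise: datetime
    sunset: datetime
    solar_noon: datetime


def _fractional_year(d: date, hour: float = 12.0) -> float:
    doy = d.timetuple().tm_yday
    leap = 366 if d.year % 4 == 0 and (d.year % 100 != 0 or d.year % 400 == 0) else 365
    return 2.0 * math.pi / leap * (doy - 1 + (hour - 12.0) / 24.0)


def equation_of_time(d: date) -> float:
    """Equation of time (minutes)."""
    g = _fractional_year(d)
    return 229.18 * (
        0.000075
        + 0.001868 * math.cos(g)
        - 0.032077 * math.sin(g)
        - 0.014615 * math.cos(2 * g)
        - 0.040849 * math.sin(2 * g)
    )


def solar_declination(d: date) -> float:
    """Solar declination (radians)."""
    g = _fractional_year(d)
    return (
        0.006918
        - 0.399912 * math.cos(g)
        + 0.070257 * math.sin(g)
        - 0.006758 * math.cos(2 * g)
        + 0.000907 * math.sin(2 * g)
        - 0.002697 * math.cos(3 * g)
        + 0.00148 * math.sin(3 * g)
    )


def _day_utc(d: date, minutes: float) -> datetime:
    return datetime(d.year, d.month, d.day, tzinfo=timezone.utc) + timedelta(minutes=minutes)


def sunrise_sunset(lat: float, lon: float, d: date) -> SolarDay:
    """Sunrise, sunset, and solar noon (UTC) for a WGS84 position and date.

    Longitude is east-positive.  Raises :class:`PolarDayNight` when the sun
    never crosses the 90.833-deg zenith (polar day or night).
    """
    eqtime = equation_of_time(d)
    decl = solar_declination(d)
    phi = math.radians(lat)
    cos_ha = (
        math.cos(math.radians(ZENITH_DEG)) / (math.cos(phi) * math.cos(decl))
        - math.tan(phi) * math.tan(decl)
    )
    if cos_ha > 1.0 or cos_ha < -1.0:
        raise PolarDayNight(f"no sunrise/sunset at lat={lat} on {d.isoformat()}")
    ha_deg = math.degrees(math.acos(cos_ha))
    noon_min = 720.0 - 4.0 * lon - eqtime
    rise_min = noon_min - 4.0 * ha_deg
    set_min = noon_min + 4.0 * ha_deg
    return SolarDay(
        sunrise=_day_utc(d, rise_min),
        sunset=_day_utc(d, set_min),
        solar_noon=_day_utc(d, noon_min),
    )


def solar_noon_utc(lon: float, d: date) -> datetime:
    """Solar noon (UTC) at a longitude; latitude does not enter."""
    return _day_utc(d, 720.0 - 4.0 * lon - equation_of_time(d))


def sunrise_sunset_minutes(lat, lon, day_of_year, year_length=365.25):
    """Vectorised sunrise/sunset/solar-noon as minutes after 00:00 UTC.

    Same NOAA equations as :func:`sunrise_sunset` but over numpy arrays.
    Positions in polar day/night get NaN sunrise/sunset.
    """
    import numpy as np

    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    doy = np.asarray(day_of_year, dtype=float)
    g = 2.0 * np.pi / year_length * (doy - 1 + 0.5)
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * np.cos(g)
        - 0.032077 * np.sin(g)
        - 0.014615 * np.cos(2 * g)
        - 0.040849 * np.sin(2 * g)
    )
    decl = (
        0.006918
        - 0.399912 * np.cos(g)
        + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g)
        + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g)
        + 0.00148 * np.sin(3 * g)
    )
    phi = np.radians(lat)
    cos_ha = (
        math.cos(math.radians(ZENITH_DEG)) / (np.cos(phi) * np.cos(decl))
        - np.tan(phi) * np.tan(decl)
    )
    ha = np.degrees(np.arccos(np.clip(cos_ha, -1.0, 1.0)))
    polar = (cos_ha > 1.0) | (cos_ha < -1.0)
    noon = 720.0 - 4.0 * lon - eqtime
    rise = np.where(polar, np.nan, noon - 4.0 * ha)
    sett = np.where(polar, np.nan, noon + 4.0 * ha)
    return rise, sett, noon
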