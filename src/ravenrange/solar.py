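"""NOAA-style solar position: sunrise and sunset instants in UTC.

Implements the standard NOAA general solar-position equations (Julian
century, equation of time, solar declination, hour angle at the 90.833
degree zenith that accounts for refraction and the solar disc radius).
Accuracy is better than two minutes at mid latitudes, which is ample for
filtering GPS fixes to daylight.

Polar latitudes (|lat| >= 66.5 deg) are rejected: the daytime filter has no
meaningful behaviour during polar day/night and the study region is alpine.
"""

from __future__ import annotations

import datetime as dt

import numpy as np

#: Zenith angle of the solar centre at sunrise/sunset, degrees
#: (90 deg geometric + 50 arcmin for refraction and solar radius).
SUNRISE_ZENITH_DEG = 90.833

POLAR_LAT_LIMIT = 66.5


class PolarLatitudeError(ValueError):
    """Latitude too close to a pole for a well-defined sunrise/sunset."""


def _noaa_minutes(ordinal, lat, lon, zenith=SUNRISE_ZENITH_DEG):
    """Vectorised sunrise/sunset as minutes of UTC day.

    Parameters are broadcastable arrays: proleptic-Gregorian ordinal day
    numbers (``datetime.date.toordinal``), latitudes and longitudes in
    degrees. Returns ``(sunrise_min, sunset_min)``; NaN where the sun never
    crosses the zenith that day.
    """
    ordinal = np.asarray(ordinal, float)
    lat = np.asarray(lat, float)
    lon = np.asarray(lon, float)

    # Julian day at civil noon of the date, then Julian century.
    jd = ordinal + 1721424.5 + 0.5
    t = (jd - 2451545.0) / 36525.0

    l0 = np.mod(280.46646 + t * (36000.76983 + 0.0003032 * t), 360.0)
    m = 357.52911 + t * (35999.05029 - 0.0001537 * t)
    e = 0.016708634 - t * (0.000042037 + 0.0000001267 * t)
    mr = np.radians(m)
    c = (
        np.sin(mr) * (1.914602 - t * (0.004817 + 0.000014 * t))
        + np.sin(2 * mr) * (0.019993 - 0.000101 * t)
        + np.sin(3 * mr) * 0.000289
    )
    true_long = l0 + c
    omega = np.radians(125.04 - 1934.136 * t)
    app_long = true_long - 0.00569 - 0.00478 * np.sin(omega)

    eps0 = 23.0 + (26.0 + (21.448 - t * (46.815 + t * (0.00059 - 0.001813 * t))) / 60.0) / 60.0
    eps = np.radians(eps0 + 0.00256 * np.cos(omega))

    decl = np.arcsin(np.sin(eps) * np.sin(np.radians(app_long)))

    y = np.tan(eps / 2.0) ** 2
    l0r = np.radians(l0)
    eqtime = 4.0 * np.degrees(
        y * np.sin(2 * l0r)
        - 2.0 * e * np.sin(mr)
        + 4.0 * e * y * np.sin(mr) * np.cos(2 * l0r)
        - 0.5 * y * y * np.sin(4 * l0r)
        - 1.25 * e * e * np.sin(2 * mr)
    )

    phi = np.radians(lat)
    cos_ha = (np.cos(np.radians(zenith)) - np.sin(phi) * np.sin(decl)) / (np.cos(phi) * np.cos(decl))
    with np.errstate(invalid="ignore"):
        ha_deg = np.degrees(np.arccos(np.clip(cos_ha, -1.0, 1.0)))
    ha_deg = np.where(np.abs(cos_ha) > 1.0, np.nan, ha_deg)

    noon_min = 720.0 - 4.0 * lon - eqtime
    return noon_min - 4.0 * ha_deg, noon_min + 4.0 * ha_deg


def daylight_window(lat: float, lon: float, date: dt.date) -> tuple[dt.datetime, dt.datetime]:
    """Sunrise and sunset instants (UTC, tz-naive) for one location and date.

    Raises
    ------
    PolarLatitudeError
        If ``|lat| >= 66.5`` degrees.
    ValueError
        If the sun does not rise or set on that date (should not occur below
        the polar limit).
    """
    if abs(lat) >= POLAR_LAT_LIMIT:
        raise PolarLatitudeError(f"latitude {lat!r} is polar; sunrise/sunset undefined or unreliable")
    rise_min, set_min = _noaa_minutes(date.toordinal(), lat, lon)
    rise_min = float(rise_min)
    set_min = float(set_min)
    if not (np.isfinite(rise_min) and np.isfinite(set_min)):
        raise ValueError(f"no sunrise/sunset at lat={lat}, lon={lon} on {date}")
    midnight = dt.datetime.combine(date, dt.time())
    return (midnight + dt.timedelta(minutes=rise_min), midnight + dt.timedelta(minutes=set_min))


def daylight_minutes(ordinal, lat, lon):
    """Vectorised sunrise/sunset minutes of UTC day; see :func:`_noaa_minutes`."""
    lat = np.asarray(lat, float)
    if np.any(np.abs(lat) >= POLAR_LAT_LIMIT):
        raise PolarLatitudeError("polar latitude in input")
    return _noaa_minutes(ordinal, lat, lon)
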