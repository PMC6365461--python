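"""Independent solar-position oracle: Michalsky (1988) Astronomical Almanac
algorithm, accurate to ~0.01 degrees for 1950-2050.

Deliberately a different derivation from the package's NOAA fractional-year
series (ecliptic longitude + sidereal time here, Fourier series there), so
the two act as genuinely independent cross-checks.  No refraction applied,
matching the package convention.
"""

from __future__ import annotations

import datetime as dt
import math


def almanac_sun(when_utc: dt.datetime, latitude: float, longitude: float):
    """Solar elevation and compass azimuth (degrees), longitude east-positive."""
    # Julian date from the Unix-era formula
    year, month, day = when_utc.year, when_utc.month, when_utc.day
    hour = when_utc.hour + when_utc.minute / 60 + when_utc.second / 3600
    delta = year - 1949
    leap = int(delta / 4)
    jd = 2432916.5 + delta * 365 + leap + _doy(when_utc) + hour / 24
    time = jd - 2451545.0  # days since J2000.0

    mnlong = (280.460 + 0.9856474 * time) % 360.0
    mnanom = math.radians((357.528 + 0.9856003 * time) % 360.0)
    eclong = math.radians(
        (mnlong + 1.915 * math.sin(mnanom) + 0.020 * math.sin(2 * mnanom)) % 360.0
    )
    oblqec = math.radians(23.439 - 0.0000004 * time)

    num = math.cos(oblqec) * math.sin(eclong)
    den = math.cos(eclong)
    ra = math.atan2(num, den) % (2 * math.pi)
    dec = math.asin(math.sin(oblqec) * math.sin(eclong))

    gmst = (6.697375 + 0.0657098242 * time + hour) % 24.0
    lmst = (gmst + longitude / 15.0) % 24.0
    ha = math.radians(lmst * 15.0) - ra
    if ha < -math.pi:
        ha += 2 * math.pi
    if ha > math.pi:
        ha -= 2 * math.pi

    lat = math.radians(latitude)
    sin_el = math.sin(dec) * math.sin(lat) + math.cos(dec) * math.cos(lat) * math.cos(ha)
    el = math.asin(max(-1.0, min(1.0, sin_el)))
    az = math.atan2(
        -math.cos(dec) * math.sin(ha),
        (math.sin(dec) - math.sin(el) * math.sin(lat)) / math.cos(lat),
    )
    return math.degrees(el), math.degrees(az) % 360.0


def _doy(when: dt.datetime) -> int:
    return when.timetuple().tm_yday
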