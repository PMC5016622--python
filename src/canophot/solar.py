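"""Solar geometry: apparent sun position from site coordinates and local time.

Implements the NOAA solar-calculator algorithm (low-precision Meeus series:
geometric mean longitude/anomaly, equation of centre, obliquity of the
ecliptic, declination and equation of time), accurate to well under 0.1° for
years 1900–2100 — far inside the 0.5° the canopy simulations require.
Atmospheric refraction is ignored: the ray tracer wants the geometric beam
direction, and refraction only matters within ~0.5° of the horizon where the
direct flux is negligible anyway.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, timedelta

__all__ = ["SunPosition", "solar_position", "sun_direction"]


@dataclass(frozen=True)
class SunPosition:
    """Apparent solar position.

    ``zenith`` in degrees from the local vertical (0 = overhead), ``azimuth``
    in degrees clockwise from true north, ``above_horizon`` true iff
    zenith < 90°.
    """

    zenith: float
    azimuth: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.zenith <= 180.0:
            raise ValueError("zenith must lie in [0, 180] degrees")

    @property
    def above_horizon(self) -> bool:
        return self.zenith < 90.0

    @property
    def elevation(self) -> float:
        return 90.0 - self.zenith


def _julian_day(dt_utc: datetime) -> float:
    y, m = dt_utc.year, dt_utc.month
    d = (dt_utc.day + dt_utc.hour / 24.0 + dt_utc.minute / 1440.0
         + dt_utc.second / 86400.0 + dt_utc.microsecond / 86400e6)
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return math.floor(365.25 * (y + 4716)) + math.floor(30.6001 * (m + 1)) + d + b - 1524.5


def solar_position(latitude_deg: float, longitude_deg: float,
                   local_datetime: datetime, utc_offset_hours: float,
                   north_offset_deg: float = 0.0) -> SunPosition:
    """Sun zenith/azimuth for a site at a local civil time.

    Parameters
    ----------
    latitude_deg, longitude_deg : float
        Site coordinates; east longitude positive. Latitude must lie in
        [−90, 90].
    local_datetime : datetime
        Naive local civil time.
    utc_offset_hours : float
        Offset of local time from UTC (e.g. 9 for KST).
    north_offset_deg : float
        Rotation of the scene's y-axis away from true north (clockwise
        positive); subtracted from the returned azimuth so that azimuth is
        expressed in scene coordinates.
    """
    if not -90.0 <= latitude_deg <= 90.0:
        raise ValueError("latitude must lie in [-90, 90] degrees")
    dt_utc = local_datetime - timedelta(hours=utc_offset_hours)
    jd = _julian_day(dt_utc)
    t = (jd - 2451545.0) / 36525.0  # Julian centuries from J2000

    # Geometric mean longitude and anomaly of the sun (degrees).
    l0 = (280.46646 + t * (36000.76983 + 0.0003032 * t)) % 360.0
    m = 357.52911 + t * (35999.05029 - 0.0001537 * t)
    mr = math.radians(m)
    # Equation of centre and true/apparent longitude.
    c = (math.sin(mr) * (1.914602 - t * (0.004817 + 0.000014 * t))
         + math.sin(2 * mr) * (0.019993 - 0.000101 * t)
         + math.sin(3 * mr) * 0.000289)
    true_long = l0 + c
    omega = 125.04 - 1934.136 * t
    app_long = true_long - 0.00569 - 0.00478 * math.sin(math.radians(omega))

    # Obliquity (corrected) and declination.
    eps0 = 23.0 + (26.0 + (21.448 - t * (46.8150 + t * (0.00059 - t * 0.001813))) / 60.0) / 60.0
    eps = eps0 + 0.00256 * math.cos(math.radians(omega))
    decl = math.asin(math.sin(math.radians(eps)) * math.sin(math.radians(app_long)))

    # Equation of time (minutes).
    y = math.tan(math.radians(eps / 2.0)) ** 2
    l0r = math.radians(l0)
    ecc = 0.016708634 - t * (0.000042037 + 0.0000001267 * t)
    eot = 4.0 * math.degrees(
        y * math.sin(2 * l0r) - 2 * ecc * math.sin(mr)
        + 4 * ecc * y * math.sin(mr) * math.cos(2 * l0r)
        - 0.5 * y * y * math.sin(4 * l0r) - 1.25 * ecc * ecc * math.sin(2 * mr))

    # True solar time → hour angle (degrees; 0 at solar noon, + afternoon).
    minutes_utc = dt_utc.hour * 60.0 + dt_utc.minute + dt_utc.second / 60.0 + dt_utc.microsecond / 6e7
    tst = (minutes_utc + eot + 4.0 * longitude_deg) % 1440.0
    ha = tst / 4.0 - 180.0
    har = math.radians(ha)

    lat = math.radians(latitude_deg)
    cos_zen = (math.sin(lat) * math.sin(decl)
               + math.cos(lat) * math.cos(decl) * math.cos(har))
    cos_zen = max(-1.0, min(1.0, cos_zen))
    zenith = math.degrees(math.acos(cos_zen))

    # Azimuth clockwise from north via atan2 (stable at the poles of the
    # formula where the acos form loses the sign of the hour angle).
    sin_zen = math.sin(math.radians(zenith))
    if sin_zen < 1e-12:
        azimuth = 0.0
    else:
        az = math.degrees(math.atan2(
            -math.sin(har) * math.cos(decl),
            math.sin(decl) * math.cos(lat) - math.cos(decl) * math.sin(lat) * math.cos(har)))
        azimuth = az % 360.0
    azimuth = (azimuth - north_offset_deg) % 360.0
    return SunPosition(zenith=zenith, azimuth=azimuth)


def sun_direction(sun: SunPosition) -> tuple[float, float, float]:
    """Unit propagation vector of the direct beam in scene coordinates.

    Scene frame is right-handed, z-up, y toward (scene) north; the returned
    vector points *from* the sun *toward* the ground (negative z when the sun
    is up).
    """
    zr = math.radians(sun.zenith)
    ar = math.radians(sun.azimuth)
    # Sun located at azimuth a, elevation 90−z; beam travels opposite.
    sx = math.sin(zr) * math.sin(ar)
    sy = math.sin(zr) * math.cos(ar)
    sz = math.cos(zr)
    return (-sx, -sy, -sz)
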