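"""Low-precision solar ephemeris.

Apparent solar elevation via the NOAA implementation of Meeus' low-accuracy
solar position series, with the standard atmospheric-refraction correction.
Absolute accuracy is a few hundredths of a degree over 1900-2100 — far better
than the 0.5 deg required to bin samples into day (SE > 0 deg) and night
(SE < -12 deg) ranges.
"""

from __future__ import annotations

import numpy as np

__all__ = ["solar_elevation", "MARS_LAT", "MARS_LON"]

# Cabled observatory site in Monterey Bay (deg N, deg E).
MARS_LAT = 36.713
MARS_LON = -122.186

_UNIX_JD0 = 2440587.5  # Julian date of 1970-01-01T00:00Z


def _to_unix_seconds(times) -> np.ndarray:
    t = np.asarray(times)
    if np.issubdtype(t.dtype, np.datetime64):
        return t.astype("datetime64[s]").astype("int64").astype(float)
    return t.astype(float)


def solar_elevation(times, lat: float = MARS_LAT, lon: float = MARS_LON) -> np.ndarray:
    """Apparent solar elevation (degrees) at UTC instant(s).

    Parameters
    ----------
    times : datetime64 array-like, pandas DatetimeIndex, or unix seconds
    lat, lon : site coordinates in degrees (east-positive longitude)

    Returns
    -------
    ndarray of elevations in degrees (scalar input -> 0-d array).
    """
    if not (-90.0 <= lat <= 90.0) or not (-360.0 <= lon <= 360.0):
        raise ValueError(f"invalid coordinates lat={lat}, lon={lon}")
    unix = _to_unix_seconds(times)
    jd = unix / 86400.0 + _UNIX_JD0
    jc = (jd - 2451545.0) / 36525.0  # Julian centuries from J2000

    rad = np.deg2rad
    gmls = np.mod(280.46646 + jc * (36000.76983 + 0.0003032 * jc), 360.0)
    gmas = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    seqcent = (
        np.sin(rad(gmas)) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + np.sin(rad(2 * gmas)) * (0.019993 - 0.000101 * jc)
        + np.sin(rad(3 * gmas)) * 0.000289
    )
    struelong = gmls + seqcent
    omega = 125.04 - 1934.136 * jc
    sapplong = struelong - 0.00569 - 0.00478 * np.sin(rad(omega))
    mobliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    obliq = mobliq + 0.00256 * np.cos(rad(omega))
    declin = np.rad2deg(np.arcsin(np.sin(rad(obliq)) * np.sin(rad(sapplong))))

    vary = np.tan(rad(obliq / 2.0)) ** 2
    eqtime = 4.0 * np.rad2deg(
        vary * np.sin(2 * rad(gmls))
        - 2 * ecc * np.sin(rad(gmas))
        + 4 * ecc * vary * np.sin(rad(gmas)) * np.cos(2 * rad(gmls))
        - 0.5 * vary * vary * np.sin(4 * rad(gmls))
        - 1.25 * ecc * ecc * np.sin(2 * rad(gmas))
    )  # minutes

    minutes_utc = np.mod(unix, 86400.0) / 60.0
    tst = np.mod(minutes_utc + eqtime + 4.0 * lon, 1440.0)
    ha = tst / 4.0 - 180.0
    cos_zen = np.sin(rad(lat)) * np.sin(rad(declin)) + np.cos(rad(lat)) * np.cos(
        rad(declin)
    ) * np.cos(rad(ha))
    zen = np.rad2deg(np.arccos(np.clip(cos_zen, -1.0, 1.0)))
    elev = 90.0 - zen
    return elev + _refraction(elev)


def _refraction(elev: np.ndarray) -> np.ndarray:
    """NOAA atmospheric refraction correction (degrees), piecewise in elevation."""
    e = np.asarray(elev, dtype=float)
    te = np.tan(np.deg2rad(np.where(np.abs(e) > 1e-9, e, 1e-9)))
    high = (58.1 / te - 0.07 / te**3 + 0.000086 / te**5) / 3600.0
    mid = (1735.0 + e * (-518.2 + e * (103.4 + e * (-12.79 + 0.711 * e)))) / 3600.0
    low = (-20.772 / te) / 3600.0
    corr = np.select(
        [e > 85.0, e > 5.0, e > -0.575],
        [np.zeros_like(e), high, mid],
        default=low,
    )
    return corr
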