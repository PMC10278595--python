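"""WGS84 transverse Mercator (UTM) forward and inverse transforms.

Telemetry fixes arrive either already projected (metres) or as geographic
longitude/latitude, which must be mapped to a metric plane before any
displacement, area or density arithmetic.  The transform here is the
standard series expansion of the Gauss-Krueger projection (sixth order in
eccentricity), accurate to well under a centimetre anywhere inside a UTM
zone, with the usual UTM conventions: scale 0.9996 on the central
meridian, 500 km false easting, 10,000 km false northing on the southern
hemisphere.

CRS identifiers accepted by the pipeline look like ``"utm-9n"`` /
``"utm-33s"``, or ``"metric"`` / ``"projected"`` for data that is already
planar.
"""

from __future__ import annotations

import re

import numpy as np

# WGS84 ellipsoid
_A = 6378137.0
_F = 1.0 / 298.257223563
_E2 = _F * (2.0 - _F)
_EP2 = _E2 / (1.0 - _E2)
_K0 = 0.9996

# meridian arc series coefficients
_M0 = 1.0 - _E2 / 4.0 - 3.0 * _E2**2 / 64.0 - 5.0 * _E2**3 / 256.0
_M2 = 3.0 * _E2 / 8.0 + 3.0 * _E2**2 / 32.0 + 45.0 * _E2**3 / 1024.0
_M4 = 15.0 * _E2**2 / 256.0 + 45.0 * _E2**3 / 1024.0
_M6 = 35.0 * _E2**3 / 3072.0


class CRSError(ValueError):
    pass


def parse_utm_crs(crs: str) -> tuple[int, bool]:
    """Return (zone, northern) for identifiers like ``utm-9n``."""
    m = re.fullmatch(r"utm[-: ]?(\d{1,2})\s*([ns])", crs.strip().lower())
    if not m:
        raise CRSError(f"cannot parse UTM CRS identifier {crs!r}")
    zone = int(m.group(1))
    if not 1 <= zone <= 60:
        raise CRSError(f"UTM zone out of range in {crs!r}")
    return zone, m.group(2).lower() == "n"


def is_projected_crs(crs: str) -> bool:
    return crs.strip().lower() in {"metric", "projected", "local"}


def utm_zone_lon0(zone: int) -> float:
    """Central meridian (degrees) of a UTM zone."""
    return -183.0 + 6.0 * zone


def meridian_arc(lat_rad):
    """Distance along the meridian from the equator (metres)."""
    phi = np.asarray(lat_rad, dtype=float)
    return _A * (
        _M0 * phi
        - _M2 * np.sin(2 * phi)
        + _M4 * np.sin(4 * phi)
        - _M6 * np.sin(6 * phi)
    )


def lonlat_to_utm(lon, lat, zone: int, northern: bool = True):
    """Forward transform, degrees -> metres. Accepts scalars or arrays."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    phi = np.radians(lat)
    lam = np.radians(lon - utm_zone_lon0(zone))

    sin_phi = np.sin(phi)
    cos_phi = np.cos(phi)
    tan_phi = np.tan(phi)

    nu = _A / np.sqrt(1.0 - _E2 * sin_phi**2)
    t = tan_phi**2
    c = _EP2 * cos_phi**2
    a = cos_phi * lam

    x = _K0 * nu * (
        a
        + (1 - t + c) * a**3 / 6.0
        + (5 - 18 * t + t**2 + 72 * c - 58 * _EP2) * a**5 / 120.0
    ) + 500000.0
    y = _K0 * (
        meridian_arc(phi)
        + nu * tan_phi * (
            a**2 / 2.0
            + (5 - t + 9 * c + 4 * c**2) * a**4 / 24.0
            + (61 - 58 * t + t**2 + 600 * c - 330 * _EP2) * a**6 / 720.0
        )
    )
    if not northern:
        y = y + 10000000.0
    return x, y


def utm_to_lonlat(x, y, zone: int, northern: bool = True):
    """Inverse transform, metres -> degrees. Accepts scalars or arrays."""
    x = np.asarray(x, dtype=float) - 500000.0
    y = np.asarray(y, dtype=float)
    if not northern:
        y = y - 10000000.0

    m = y / _K0
    mu = m / (_A * _M0)
    e1 = (1.0 - np.sqrt(1.0 - _E2)) / (1.0 + np.sqrt(1.0 - _E2))
    # footpoint latitude
    phi1 = (
        mu
        + (3 * e1 / 2 - 27 * e1**3 / 32) * np.sin(2 * mu)
        + (21 * e1**2 / 16 - 55 * e1**4 / 32) * np.sin(4 * mu)
        + (151 * e1**3 / 96) * np.sin(6 * mu)
        + (1097 * e1**4 / 512) * np.sin(8 * mu)
    )

    sin1 = np.sin(phi1)
    cos1 = np.cos(phi1)
    tan1 = np.tan(phi1)
    c1 = _EP2 * cos1**2
    t1 = tan1**2
    n1 = _A / np.sqrt(1.0 - _E2 * sin1**2)
    r1 = _A * (1.0 - _E2) / (1.0 - _E2 * sin1**2) ** 1.5
    d = x / (n1 * _K0)

    phi = phi1 - (n1 * tan1 / r1) * (
        d**2 / 2.0
        - (5 + 3 * t1 + 10 * c1 - 4 * c1**2 - 9 * _EP2) * d**4 / 24.0
        + (61 + 90 * t1 + 298 * c1 + 45 * t1**2 - 252 * _EP2 - 3 * c1**2)
        * d**6 / 720.0
    )
    lam = (
        d
        - (1 + 2 * t1 + c1) * d**3 / 6.0
        + (5 - 2 * c1 + 28 * t1 - 3 * c1**2 + 8 * _EP2 + 24 * t1**2)
        * d**5 / 120.0
    ) / cos1

    lon = utm_zone_lon0(zone) + np.degrees(lam)
    lat = np.degrees(phi)
    return lon, lat


def project(lon, lat, crs: str):
    """Project geographic coordinates into the metric CRS named ``crs``."""
    zone, northern = parse_utm_crs(crs)
    return lonlat_to_utm(lon, lat, zone, northern)


def unproject(x, y, crs: str):
    zone, northern = parse_utm_crs(crs)
    return utm_to_lonlat(x, y, zone, northern)
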