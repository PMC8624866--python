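"""WGS84 transverse Mercator (UTM) forward and inverse projection.

Implements the Krüger flattening series (4th order in the third flattening
n), which is accurate to well under a millimetre anywhere inside a UTM
zone — far below the GPS uncertainty of the survey coordinates this package
consumes.  Planar easting/northing in metres is what every interpolator in
this package works in.
"""

from __future__ import annotations

import numpy as np

# WGS84 ellipsoid
_A = 6378137.0
_F = 1.0 / 298.257223563
_K0 = 0.9996
_FALSE_EASTING = 500000.0
_FALSE_NORTHING_S = 10000000.0

_N3 = _F / (2.0 - _F)  # third flattening
_E = np.sqrt(_F * (2.0 - _F))  # eccentricity

# rectifying radius and Krüger alpha/beta series (4th order in n)
_RECT_A = _A / (1 + _N3) * (1 + _N3**2 / 4 + _N3**4 / 64)
_ALPHA = np.array([
    _N3 / 2 - 2 * _N3**2 / 3 + 5 * _N3**3 / 16 + 41 * _N3**4 / 180,
    13 * _N3**2 / 48 - 3 * _N3**3 / 5 + 557 * _N3**4 / 1440,
    61 * _N3**3 / 240 - 103 * _N3**4 / 140,
    49561 * _N3**4 / 161280,
])
_BETA = np.array([
    _N3 / 2 - 2 * _N3**2 / 3 + 37 * _N3**3 / 96 - _N3**4 / 360,
    _N3**2 / 48 + _N3**3 / 15 - 437 * _N3**4 / 1440,
    17 * _N3**3 / 480 - 37 * _N3**4 / 840,
    4397 * _N3**4 / 161280,
])


def utm_central_meridian(zone: int) -> float:
    """Central meridian (degrees east) of a UTM zone."""
    if not 1 <= zone <= 60:
        raise ValueError(f"UTM zone must be in 1..60, got {zone}")
    return zone * 6.0 - 183.0


def geographic_to_utm(lon, lat, zone: int = 51, hemisphere: str = "N"):
    """Project WGS84 lon/lat (degrees) to UTM easting/northing (metres).

    Parameters
    ----------
    lon, lat : array-like, decimal degrees.
    zone : UTM zone number (default 51, covering Marinduque at 122°E).
    hemisphere : "N" or "S" (controls the false northing).

    Returns
    -------
    (easting, northing) arrays in metres.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if np.any(np.abs(lat) > 84.0):
        raise ValueError("transverse Mercator undefined beyond |lat| = 84°")
    if hemisphere not in ("N", "S"):
        raise ValueError("hemisphere must be 'N' or 'S'")

    lam = np.radians(lon - utm_central_meridian(zone))
    phi = np.radians(lat)

    # conformal latitude
    s = np.sin(phi)
    t = np.sinh(np.arctanh(s) - _E * np.arctanh(_E * s))

    xi_p = np.arctan2(t, np.cos(lam))
    eta_p = np.arcsinh(np.sin(lam) / np.hypot(t, np.cos(lam)))

    j = np.arange(1, 5)
    xi = xi_p + np.sum(
        _ALPHA * np.sin(2 * j * xi_p[..., None]) * np.cosh(2 * j * eta_p[..., None]),
        axis=-1,
    )
    eta = eta_p + np.sum(
        _ALPHA * np.cos(2 * j * xi_p[..., None]) * np.sinh(2 * j * eta_p[..., None]),
        axis=-1,
    )

    easting = _FALSE_EASTING + _K0 * _RECT_A * eta
    northing = _K0 * _RECT_A * xi
    if hemisphere == "S":
        northing = northing + _FALSE_NORTHING_S
    return easting, northing


def utm_to_geographic(easting, northing, zone: int = 51, hemisphere: str = "N"):
    """Inverse of :func:`geographic_to_utm`; returns (lon, lat) in degrees."""
    easting = np.asarray(easting, dtype=float)
    northing = np.asarray(northing, dtype=float)
    if hemisphere == "S":
        northing = northing - _FALSE_NORTHING_S

    xi = northing / (_K0 * _RECT_A)
    eta = (easting - _FALSE_EASTING) / (_K0 * _RECT_A)

    j = np.arange(1, 5)
    xi_p = xi - np.sum(
        _BETA * np.sin(2 * j * xi[..., None]) * np.cosh(2 * j * eta[..., None]),
        axis=-1,
    )
    eta_p = eta - np.sum(
        _BETA * np.cos(2 * j * xi[..., None]) * np.sinh(2 * j * eta[..., None]),
        axis=-1,
    )

    lam = np.arctan2(np.sinh(eta_p), np.cos(xi_p))
    # conformal -> geodetic latitude via the isometric-latitude fixed point
    tau_p = np.sin(xi_p) / np.hypot(np.sinh(eta_p), np.cos(xi_p))
    psi = np.arcsinh(tau_p)
    sin_phi = np.tanh(psi)
    for _ in range(8):
        sin_phi = np.tanh(psi + _E * np.arctanh(_E * sin_phi))

    lon = np.degrees(lam) + utm_central_meridian(zone)
    lat = np.degrees(np.arcsin(sin_phi))
    return lon, lat
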