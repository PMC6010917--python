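"""Planar projection and geodesic distance primitives.

Coordinates follow the conventions of North American rangeland telemetry
work: geographic coordinates are signed decimal degrees (N/E positive),
planar coordinates are UTM Zone 13N metres on the NAD83 datum (GRS80
ellipsoid), and between-fix distances are ellipsoidal geodesics on WGS84.
The NAD83/WGS84 distinction is negligible (< 2 m absolute, ~0 relative)
at pasture scale but both datums are kept explicit.

The transverse-Mercator forward/inverse uses the 6th-order Krüger series
(exact to well below 1 mm inside a UTM zone); the geodesic uses Vincenty's
inverse formula, which converges in a handful of iterations for the
sub-kilometre separations this package deals with.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Ellipsoid",
    "GRS80",
    "WGS84",
    "UTM_ZONE_13N",
    "TransverseMercator",
    "utm13n_forward",
    "utm13n_inverse",
    "geodesic_distance_m",
    "planar_distance_m",
]


@dataclass(frozen=True)
class Ellipsoid:
    name: str
    a: float  # semi-major axis, m
    f: float  # flattening


GRS80 = Ellipsoid("GRS80", 6378137.0, 1.0 / 298.257222101)
WGS84 = Ellipsoid("WGS84", 6378137.0, 1.0 / 298.257223563)


class TransverseMercator:
    """Krüger-series transverse Mercator, UTM parameterisation.

    Forward maps (lat, lon) in degrees to (easting, northing) in metres;
    inverse undoes it. Series truncated at n^6: round-trip error is far
    below 1e-8 degrees anywhere in the zone.
    """

    def __init__(self, ellipsoid: Ellipsoid, lon0_deg: float,
                 k0: float = 0.9996,
                 false_easting: float = 500_000.0,
                 false_northing: float = 0.0):
        self.ellipsoid = ellipsoid
        self.lon0 = math.radians(lon0_deg)
        self.k0 = k0
        self.fe = false_easting
        self.fn = false_northing

        f = ellipsoid.f
        n = f / (2.0 - f)
        self._n = n
        self._A = ellipsoid.a / (1 + n) * (1 + n**2 / 4 + n**4 / 64 + n**6 / 256)
        self._alpha = np.array([
            n / 2 - 2 * n**2 / 3 + 5 * n**3 / 16 + 41 * n**4 / 180
            - 127 * n**5 / 288 + 7891 * n**6 / 37800,
            13 * n**2 / 48 - 3 * n**3 / 5 + 557 * n**4 / 1440
            + 281 * n**5 / 630 - 1983433 * n**6 / 1935360,
            61 * n**3 / 240 - 103 * n**4 / 140 + 15061 * n**5 / 26880
            + 167603 * n**6 / 181440,
            49561 * n**4 / 161280 - 179 * n**5 / 168 + 6601661 * n**6 / 7257600,
            34729 * n**5 / 80640 - 3418889 * n**6 / 1995840,
            212378941 * n**6 / 319334400,
        ])
        self._beta = np.array([
            n / 2 - 2 * n**2 / 3 + 37 * n**3 / 96 - n**4 / 360
            - 81 * n**5 / 512 + 96199 * n**6 / 604800,
            n**2 / 48 + n**3 / 15 - 437 * n**4 / 1440 + 46 * n**5 / 105
            - 1118711 * n**6 / 3870720,
            17 * n**3 / 480 - 37 * n**4 / 840 - 209 * n**5 / 4480
            + 5569 * n**6 / 90720,
            4397 * n**4 / 161280 - 11 * n**5 / 504 - 830251 * n**6 / 7257600,
            4583 * n**5 / 161280 - 108847 * n**6 / 3991680,
            20648693 * n**6 / 638668800,
        ])
        self._delta = np.array([
            2 * n - 2 * n**2 / 3 - 2 * n**3 + 116 * n**4 / 45
            + 26 * n**5 / 45 - 2854 * n**6 / 675,
            7 * n**2 / 3 - 8 * n**3 / 5 - 227 * n**4 / 45
            + 2704 * n**5 / 315 + 2323 * n**6 / 945,
            56 * n**3 / 15 - 136 * n**4 / 35 - 1262 * n**5 / 105
            + 73814 * n**6 / 2835,
            4279 * n**4 / 630 - 332 * n**5 / 35 - 399572 * n**6 / 14175,
            4174 * n**5 / 315 - 144838 * n**6 / 6237,
            601676 * n**6 / 22275,
        ])

    def forward(self, lat_dd, lon_dd):
        lat = np.radians(np.asarray(lat_dd, dtype=float))
        lon = np.radians(np.asarray(lon_dd, dtype=float))
        n = self._n
        dlon = lon - self.lon0

        e2n = 2 * math.sqrt(n) / (1 + n)
        t = np.sinh(np.arctanh(np.sin(lat)) - e2n * np.arctanh(e2n * np.sin(lat)))
        xi_p = np.arctan2(t, np.cos(dlon))
        eta_p = np.arcsinh(np.sin(dlon) / np.hypot(t, np.cos(dlon)))

        j = np.arange(1, 7)
        xi = xi_p + np.sum(self._alpha * np.sin(2 * j * xi_p[..., None])
                           * np.cosh(2 * j * eta_p[..., None]), axis=-1)
        eta = eta_p + np.sum(self._alpha * np.cos(2 * j * xi_p[..., None])
                             * np.sinh(2 * j * eta_p[..., None]), axis=-1)
        easting = self.fe + self.k0 * self._A * eta
        northing = self.fn + self.k0 * self._A * xi
        return easting, northing

    def inverse(self, easting_m, northing_m):
        easting = np.asarray(easting_m, dtype=float)
        northing = np.asarray(northing_m, dtype=float)
        xi = (northing - self.fn) / (self.k0 * self._A)
        eta = (easting - self.fe) / (self.k0 * self._A)

        j = np.arange(1, 7)
        xi_p = xi - np.sum(self._beta * np.sin(2 * j * xi[..., None])
                           * np.cosh(2 * j * eta[..., None]), axis=-1)
        eta_p = eta - np.sum(self._beta * np.cos(2 * j * xi[..., None])
                             * np.sinh(2 * j * eta[..., None]), axis=-1)
        chi = np.arcsin(np.sin(xi_p) / np.cosh(eta_p))
        lat = chi + np.sum(self._delta * np.sin(2 * j * chi[..., None]), axis=-1)
        lon = self.lon0 + np.arctan2(np.sinh(eta_p), np.cos(xi_p))
        return np.degrees(lat), np.degrees(lon)


# UTM Zone 13N (central meridian 105°W) on NAD83, the pipeline's working CRS.
UTM_ZONE_13N = TransverseMercator(GRS80, lon0_deg=-105.0)

#: Longitude band of UTM zone 13 (degrees east); fixes outside only warrant
#: a warning, the projection is still applied.
ZONE_13_LON_RANGE = (-108.0, -102.0)


def utm13n_forward(lat_dd, lon_dd):
    """(lat, lon) decimal degrees -> UTM Zone 13N (easting, northing) metres."""
    return UTM_ZONE_13N.forward(lat_dd, lon_dd)


def utm13n_inverse(easting_m, northing_m):
    """UTM Zone 13N metres -> (lat, lon) decimal degrees."""
    return UTM_ZONE_13N.inverse(easting_m, northing_m)


def geodesic_distance_m(lat1, lon1, lat2, lon2,
                        ellipsoid: Ellipsoid = WGS84,
                        max_iter: int = 200, tol: float = 1e-12):
    """Vincenty inverse geodesic distance in metres (vectorised).

    Symmetric, zero iff the points coincide. The rare non-convergent
    near-antipodal geometry falls back to extra damped iterations; it
    cannot occur for pasture-scale separations but the contract holds.
    """
    lat1 = np.radians(np.asarray(lat1, dtype=float))
    lon1 = np.radians(np.asarray(lon1, dtype=float))
    lat2 = np.radians(np.asarray(lat2, dtype=float))
    lon2 = np.radians(np.asarray(lon2, dtype=float))

    a, f = ellipsoid.a, ellipsoid.f
    b = a * (1 - f)

    U1 = np.arctan((1 - f) * np.tan(lat1))
    U2 = np.arctan((1 - f) * np.tan(lat2))
    L = lon2 - lon1
    sinU1, cosU1 = np.sin(U1), np.cos(U1)
    sinU2, cosU2 = np.sin(U2), np.cos(U2)

    lam = L.copy()
    sin_sigma = np.zeros_like(lam)
    cos_sigma = np.ones_like(lam)
    sigma = np.zeros_like(lam)
    cos_sq_alpha = np.ones_like(lam)
    cos2sm = np.zeros_like(lam)

    active = np.ones(lam.shape, dtype=bool)
    for _ in range(max_iter):
        sin_lam, cos_lam = np.sin(lam), np.cos(lam)
        t1 = cosU2 * sin_lam
        t2 = cosU1 * sinU2 - sinU1 * cosU2 * cos_lam
        sin_sigma = np.where(active, np.hypot(t1, t2), sin_sigma)
        cos_sigma = np.where(active, sinU1 * sinU2 + cosU1 * cosU2 * cos_lam,
                             cos_sigma)
        sigma = np.where(active, np.arctan2(sin_sigma, cos_sigma), sigma)
        with np.errstate(divide="ignore", invalid="ignore"):
            sin_alpha = np.where(sin_sigma != 0,
                                 cosU1 * cosU2 * sin_lam / sin_sigma, 0.0)
        csa = 1 - sin_alpha**2
        cos_sq_alpha = np.where(active, csa, cos_sq_alpha)
        with np.errstate(divide="ignore", invalid="ignore"):
            c2 = np.where(csa != 0,
                          cos_sigma - 2 * sinU1 * sinU2 / np.where(csa == 0, 1, csa),
                          0.0)
        cos2sm = np.where(active, c2, cos2sm)
        C = f / 16 * csa * (4 + f * (4 - 3 * csa))
        lam_new = L + (1 - C) * f * sin_alpha * (
            sigma + C * sin_sigma * (c2 + C * cos_sigma * (-1 + 2 * c2**2)))
        delta = np.abs(lam_new - lam)
        lam = np.where(active, lam_new, lam)
        active = active & (delta > tol)
        if not active.any():
            break

    u_sq = cos_sq_alpha * (a**2 - b**2) / b**2
    A = 1 + u_sq / 16384 * (4096 + u_sq * (-768 + u_sq * (320 - 175 * u_sq)))
    B = u_sq / 1024 * (256 + u_sq * (-128 + u_sq * (74 - 47 * u_sq)))
    delta_sigma = B * sin_sigma * (
        cos2sm + B / 4 * (cos_sigma * (-1 + 2 * cos2sm**2)
                          - B / 6 * cos2sm * (-3 + 4 * sin_sigma**2)
                          * (-3 + 4 * cos2sm**2)))
    dist = b * A * (sigma - delta_sigma)
    # coincident points short-circuit to an exact zero
    same = (lat1 == lat2) & (lon1 == lon2)
    dist = np.where(same, 0.0, dist)
    if dist.ndim == 0:
        return float(dist)
    return dist


def planar_distance_m(easting1, northing1, easting2, northing2):
    """Euclidean distance in UTM metres (the herd-dispersion metric)."""
    return np.hypot(np.asarray(easting2) - np.asarray(easting1),
                    np.asarray(northing2) - np.asarray(northing1))
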