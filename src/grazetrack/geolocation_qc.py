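"""Geolocation precision/accuracy QC via 95% circular error probability.

A unit's *precision* is the 95% quantile of geodesic distances from its
fixes to their own centroid (how tightly the unit clusters); *accuracy*
is the same quantile measured against a surveyed georeference point.
Units are benchmarked by logging at a fixed cadence over a known point
and summarised as mean ± SE across units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import geo

__all__ = [
    "CepReport",
    "geodesic_distance_m",
    "fixes_centroid",
    "cep95",
    "run_qc_protocol",
]


@dataclass
class CepReport:
    unit_id: str
    n_fixes: int
    precision_cep95_m: float
    accuracy_cep95_m: float
    centroid: tuple[float, float]  # (lat_dd, lon_dd)


def geodesic_distance_m(p1: Sequence[float], p2: Sequence[float]) -> float:
    """Ellipsoidal geodesic distance in metres between two
    (lat_dd, lon_dd) points."""
    return float(geo.geodesic_distance_m(p1[0], p1[1], p2[0], p2[1]))


def _latlon(fixes) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(fixes, pd.DataFrame):
        return fixes["lat_dd"].to_numpy(float), fixes["lon_dd"].to_numpy(float)
    arr = np.asarray(fixes, dtype=float)
    return arr[:, 0], arr[:, 1]


def fixes_centroid(fixes) -> tuple[float, float]:
    """Arithmetic-mean centroid of fix coordinates in decimal degrees
    (adequate at pasture scale; errors are O(metres/earth-radius))."""
    lat, lon = _latlon(fixes)
    if lat.size == 0:
        raise ValueError("cannot compute the centroid of zero fixes")
    return float(lat.mean()), float(lon.mean())


def cep95(fixes, reference: Sequence[float], q: float = 0.95,
          method: str = "linear") -> float:
    """Empirical ``q`` quantile (default 95%) of geodesic distances from
    each fix to ``reference`` — the circular error probability radius.

    ``method`` is any quantile interpolation accepted by ``numpy.quantile``
    (linear interpolation between order statistics by default).
    """
    lat, lon = _latlon(fixes)
    if lat.size == 0:
        raise ValueError("cep95 requires at least one fix")
    if lat.size < 20:
        warnings.warn(f"cep95 on only {lat.size} fixes; the quantile "
                      "estimate will be unstable", stacklevel=2)
    d = geo.geodesic_distance_m(lat, lon,
                                np.full_like(lat, reference[0]),
                                np.full_like(lon, reference[1]))
    return float(np.quantile(np.atleast_1d(d), q, method=method))


def run_qc_protocol(units: Mapping[str, object],
                    reference: Sequence[float], q: float = 0.95,
                    ) -> tuple[list[CepReport], dict[str, float]]:
    """Per-unit precision (vs own centroid) and accuracy (vs the known
    georeference) CEP, plus across-unit mean and standard error of each.

    Units with fewer than two fixes are excluded with a warning.
    SE = sample SD / sqrt(number of units).
    """
    if not units:
        raise ValueError("run_qc_protocol requires at least one unit")
    reports = []
    for unit_id, fixes in units.items():
        lat, _ = _latlon(fixes)
        if lat.size < 2:
            warnings.warn(f"unit {unit_id}: fewer than 2 fixes, excluded",
                          stacklevel=2)
            continue
        centroid = fixes_centroid(fixes)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reports.append(CepReport(
                unit_id=str(unit_id),
                n_fixes=int(lat.size),
                precision_cep95_m=cep95(fixes, centroid, q=q),
                accuracy_cep95_m=cep95(fixes, reference, q=q),
                centroid=centroid,
            ))
    prec = np.array([r.precision_cep95_m for r in reports])
    acc = np.array([r.accuracy_cep95_m for r in reports])

    def _se(x: np.ndarray) -> float:
        return float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else float("nan")

    summary = {
        "n_units": len(reports),
        "precision_mean_m": float(prec.mean()) if prec.size else float("nan"),
        "precision_se_m": _se(prec),
        "accuracy_mean_m": float(acc.mean()) if acc.size else float("nan"),
        "accuracy_se_m": _se(acc),
    }
    return reports, summary
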