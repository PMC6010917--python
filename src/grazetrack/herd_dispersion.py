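"""Per-minute herd dispersion: mean pairwise distance among collared
animals in a pasture.

To damp sensitivity to where within a minute each logger lands its 20-s
cadence, only the first fix per local calendar minute per logger enters
the calculation. A minute contributes a value only when at least two
loggers have a valid fix in it: with three, the mean of the three pairwise
planar (UTM) distances; with two, their distance; with fewer, nothing.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

from .geo import planar_distance_m

__all__ = [
    "first_fix_per_minute",
    "minute_dispersion",
    "dispersion_summary",
]


def first_fix_per_minute(fixes: pd.DataFrame, time_col: str = "time_local",
                         ) -> pd.DataFrame:
    """At most one fix per local calendar minute: the earliest."""
    if fixes.empty:
        return fixes.reset_index(drop=True)
    minute = pd.to_datetime(fixes[time_col]).dt.floor("min")
    keep = ~minute.duplicated(keep="first")
    return fixes.loc[keep].reset_index(drop=True)


def minute_dispersion(per_logger: Mapping[str, pd.DataFrame],
                      pasture_id: str = "", time_col: str = "time_local",
                      ) -> pd.DataFrame:
    """Per-minute mean pairwise planar distance across loggers.

    ``per_logger`` maps logger id to its (cleaned, daytime-filtered) fixes.
    Returns a frame with columns ``minute, n_loggers, mean_pairwise_m``
    containing only minutes with >= 2 valid loggers; symmetric under
    logger relabelling and invariant to a common translation.
    """
    if not per_logger:
        raise ValueError("minute_dispersion requires at least one logger")
    cols = {}
    for logger_id, fixes in per_logger.items():
        ff = first_fix_per_minute(fixes, time_col)
        if ff.empty:
            continue
        minute = pd.to_datetime(ff[time_col]).dt.floor("min")
        cols[logger_id] = pd.DataFrame({
            "easting_m": ff["easting_m"].to_numpy(float),
            "northing_m": ff["northing_m"].to_numpy(float),
        }, index=minute)
    if not cols:
        return pd.DataFrame(columns=["minute", "n_loggers", "mean_pairwise_m"])

    ids = sorted(cols)
    east = pd.DataFrame({k: cols[k]["easting_m"] for k in ids})
    north = pd.DataFrame({k: cols[k]["northing_m"] for k in ids})
    valid = east.notna().to_numpy()
    n_valid = valid.sum(axis=1)

    e = east.to_numpy(float)
    n = north.to_numpy(float)
    total = np.zeros(len(east))
    npairs = np.zeros(len(east))
    for i, j in combinations(range(len(ids)), 2):
        ok = valid[:, i] & valid[:, j]
        d = planar_distance_m(e[ok, i], n[ok, i], e[ok, j], n[ok, j])
        total[ok] += d
        npairs[ok] += 1
    has = n_valid >= 2
    out = pd.DataFrame({
        "minute": east.index[has],
        "n_loggers": n_valid[has].astype(int),
        "mean_pairwise_m": total[has] / npairs[has],
    }).sort_values("minute", kind="stable").reset_index(drop=True)
    if pasture_id:
        out.insert(0, "pasture_id", pasture_id)
    return out


def dispersion_summary(series: pd.DataFrame | pd.Series) -> dict[str, float]:
    """Mean, median and 75th percentile of the per-minute dispersion
    values (the cohesion quantiles reported for a herd)."""
    values = (series["mean_pairwise_m"]
              if isinstance(series, pd.DataFrame) else series)
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("dispersion_summary on an empty series")
    return {
        "n_minutes": int(values.size),
        "mean_m": float(values.mean()),
        "p50_m": float(np.quantile(values, 0.50)),
        "p75_m": float(np.quantile(values, 0.75)),
    }
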