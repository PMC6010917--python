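"""Raw logger ingest: NMEA coordinate conversion, timestamp localisation,
and the track-cleaning rules (dedup, pasture cropping, nighttime exclusion,
minimum-fix deployment validation).

The raw dialect is the header-less ASCII CSV written by the collar firmware,
one row per fix::

    ddmmyy,hhmmss.sss,fix_quality,ddmm.mmmm,N|S,dddmm.mmmm,E|W,satellites

Latitude/longitude use the NMEA GPGLL convention of whole degrees
concatenated with decimal minutes plus a hemisphere letter; e.g. 49 degrees
16.46 minutes North is stored as ``4916.46,N`` and converts to
49.2743333 decimal degrees. Malformed rows (field loggers truncate rows at
power loss) are counted and skipped, never fatal.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape as shapely_shape
from shapely.geometry.base import BaseGeometry

from .geo import ZONE_13_LON_RANGE, utm13n_forward

logger = logging.getLogger(__name__)

__all__ = [
    "RAW_COLUMNS",
    "Pasture",
    "Deployment",
    "nmea_to_decimal",
    "decimal_to_nmea",
    "parse_logger_file",
    "to_utm",
    "localize_timestamp",
    "records_to_fixes",
    "dedupe",
    "load_pastures",
    "crop_and_assign",
    "daytime_filter",
    "validate_deployment",
    "clean_deployment",
]

RAW_COLUMNS = ["utc_date", "utc_time", "fix_quality",
               "lat_field", "lat_hemisphere",
               "lon_field", "lon_hemisphere", "satellites"]

MIN_VALID_FIXES = 1000  # deployments below this are excluded from analysis
DEFAULT_UTC_OFFSET_HOURS = -6
DEFAULT_DAYTIME_WINDOW = (4.0, 22.0)  # local hours, half-open


@dataclass
class Pasture:
    id: str
    species: str                    # "cattle" | "sheep"
    boundary: BaseGeometry          # simple polygon, UTM 13N metres
    area_ha: float = 0.0

    def __post_init__(self):
        if not self.boundary.is_valid or self.boundary.area <= 0:
            raise ValueError(f"pasture {self.id}: degenerate boundary polygon")
        if not self.area_ha:
            self.area_ha = self.boundary.area / 10_000.0


@dataclass
class Deployment:
    """All fixes from one logger on one animal in one pasture trial."""

    logger_id: str
    animal_id: str
    pasture_id: str
    trial_month: str
    fixes: pd.DataFrame
    valid: bool = False
    removal_counts: dict[str, int] = field(default_factory=dict)


def nmea_to_decimal(fld: str, hemisphere: str) -> float:
    """Convert an NMEA ``ddmm.mmmm`` (or ``dddmm.mmmm``) field plus
    hemisphere letter into signed decimal degrees (S and W negative).

    >>> round(nmea_to_decimal("4916.46", "N"), 7)
    49.2743333
    """
    fld = fld.strip()
    hemisphere = hemisphere.strip().upper()
    if hemisphere not in "NSEW" or len(hemisphere) != 1:
        raise ValueError(f"invalid hemisphere flag {hemisphere!r}")
    dot = fld.find(".")
    head = fld[:dot] if dot >= 0 else fld
    if len(head) < 3 or not head.lstrip("0123456789") == "":
        raise ValueError(f"malformed NMEA coordinate field {fld!r}")
    try:
        minutes = float(fld[len(head) - 2:])
        degrees = int(head[:-2])
    except ValueError as exc:
        raise ValueError(f"non-numeric NMEA coordinate field {fld!r}") from exc
    if minutes >= 60.0:
        raise ValueError(f"minutes >= 60 in NMEA field {fld!r}")
    value = degrees + minutes / 60.0
    if hemisphere in "SW":
        value = -value
    return value


def decimal_to_nmea(dd: float, is_latitude: bool, minute_decimals: int = 4,
                    ) -> tuple[str, str]:
    """Inverse of :func:`nmea_to_decimal`: signed decimal degrees to the
    NMEA field and hemisphere letter, minutes rounded to
    ``minute_decimals`` places (round-trip error < 1e-6 degrees at 4)."""
    if is_latitude:
        hemisphere = "N" if dd >= 0 else "S"
        deg_width = 2
        if abs(dd) > 90:
            raise ValueError(f"latitude out of range: {dd}")
    else:
        hemisphere = "E" if dd >= 0 else "W"
        deg_width = 3
        if abs(dd) > 180:
            raise ValueError(f"longitude out of range: {dd}")
    mag = abs(dd)
    degrees = int(mag)
    minutes = round((mag - degrees) * 60.0, minute_decimals)
    if minutes >= 60.0:  # rounding carried into the next degree
        minutes = 0.0
        degrees += 1
    m_width = 3 + minute_decimals  # "mm." + decimals
    fld = f"{degrees:0{deg_width}d}{minutes:0{m_width}.{minute_decimals}f}"
    return fld, hemisphere


def parse_logger_file(path: str | Path) -> pd.DataFrame:
    """Parse one raw logger file into a frame of raw records
    (columns :data:`RAW_COLUMNS`), skipping and counting malformed rows.

    The skip count is available as ``df.attrs["n_malformed"]`` and logged
    as a warning when non-zero. A missing file raises ``FileNotFoundError``.
    """
    path = Path(path)
    rows, n_malformed = [], 0
    with open(path, "r", encoding="ascii", errors="replace") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 8:
                n_malformed += 1
                continue
            try:
                rec = _parse_row(parts)
            except (ValueError, IndexError):
                n_malformed += 1
                continue
            rows.append(rec)
    df = pd.DataFrame(rows, columns=RAW_COLUMNS)
    df.attrs["n_malformed"] = n_malformed
    if n_malformed:
        logger.warning("%s: skipped %d malformed row(s)", path.name, n_malformed)
    if df.empty:
        logger.warning("%s: no well-formed rows", path.name)
    return df


def _parse_row(parts: list[str]) -> dict:
    d, t = parts[0], parts[1]
    if len(d) != 6 or not d.isdigit():
        raise ValueError(f"bad date field {d!r}")
    hh, mm, ss = t[0:2], t[2:4], t[4:]
    utc_time = f"{int(hh):02d}:{int(mm):02d}:{float(ss):06.3f}"
    utc_date = f"20{d[4:6]}-{d[2:4]}-{d[0:2]}"
    # validate coordinates eagerly so malformed rows are caught here
    nmea_to_decimal(parts[3], parts[4])
    nmea_to_decimal(parts[5], parts[6])
    return {
        "utc_date": utc_date,
        "utc_time": utc_time,
        "fix_quality": int(parts[2]),
        "lat_field": parts[3],
        "lat_hemisphere": parts[4].strip().upper(),
        "lon_field": parts[5],
        "lon_hemisphere": parts[6].strip().upper(),
        "satellites": int(parts[7]),
    }


def to_utm(lat_dd, lon_dd) -> tuple[np.ndarray, np.ndarray]:
    """Project decimal degrees to UTM Zone 13N (NAD83) metres; coordinates
    outside the zone's longitude band trigger a warning but are projected."""
    lon = np.asarray(lon_dd, dtype=float)
    lo, hi = ZONE_13_LON_RANGE
    if np.any((lon < lo) | (lon > hi)):
        warnings.warn("coordinates outside UTM zone 13 longitude band; "
                      "projection applied anyway", stacklevel=2)
    return utm13n_forward(lat_dd, lon_dd)


def localize_timestamp(time_utc, offset_hours: float):
    """UTC -> local time by a fixed offset (handles date rollover)."""
    return pd.to_datetime(time_utc) + pd.Timedelta(hours=offset_hours)


def dedupe(records: pd.DataFrame) -> pd.DataFrame:
    """Drop rows identical in all fields (stale microSD data from earlier
    deployments), keeping the first occurrence in file order."""
    return records.drop_duplicates(keep="first").reset_index(drop=True)


def records_to_fixes(records: pd.DataFrame,
                     offset_hours: float = DEFAULT_UTC_OFFSET_HOURS,
                     ) -> pd.DataFrame:
    """Convert parsed raw records to analysis fixes: decimal degrees, UTM
    metres, UTC and local timestamps."""
    if records.empty:
        return pd.DataFrame(columns=[
            "time_utc", "time_local", "lat_dd", "lon_dd",
            "easting_m", "northing_m", "fix_quality", "satellites"])
    lat = np.array([nmea_to_decimal(f, h) for f, h in
                    zip(records["lat_field"], records["lat_hemisphere"])])
    lon = np.array([nmea_to_decimal(f, h) for f, h in
                    zip(records["lon_field"], records["lon_hemisphere"])])
    easting, northing = to_utm(lat, lon)
    time_utc = pd.to_datetime(records["utc_date"] + " " + records["utc_time"],
                              format="%Y-%m-%d %H:%M:%S.%f")
    return pd.DataFrame({
        "time_utc": time_utc.values,
        "time_local": localize_timestamp(time_utc, offset_hours).values,
        "lat_dd": lat,
        "lon_dd": lon,
        "easting_m": np.asarray(easting, dtype=float),
        "northing_m": np.asarray(northing, dtype=float),
        "fix_quality": records["fix_quality"].to_numpy(),
        "satellites": records["satellites"].to_numpy(),
    })


def load_pastures(path: str | Path) -> dict[str, Pasture]:
    """Load pasture boundary polygons from GeoJSON (coordinates in UTM 13N
    metres, feature properties ``id`` and ``species``)."""
    with open(path) as fh:
        gj = json.load(fh)
    out = {}
    for feat in gj["features"]:
        props = feat.get("properties", {})
        p = Pasture(id=str(props["id"]), species=props.get("species", ""),
                    boundary=shapely_shape(feat["geometry"]))
        out[p.id] = p
    return out


def crop_and_assign(fixes: pd.DataFrame, pastures: dict[str, Pasture],
                    assigned_pasture_id: str, fence_buffer_m: float = 0.0,
                    ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep only fixes inside the assigned pasture; discard and count
    fixes that fall inside another pasture (``wrong_pasture`` — GPS error
    pushing a track across a shared fence, or true fence crossings) or
    outside every boundary (``out_of_bounds`` — transport legs and gross
    satellite outliers). ``fence_buffer_m > 0`` expands the assigned
    boundary to tolerate fence-line jitter."""
    if assigned_pasture_id not in pastures:
        raise KeyError(f"unknown pasture id {assigned_pasture_id!r}")
    pts = shapely.points(fixes["easting_m"].to_numpy(),
                         fixes["northing_m"].to_numpy())
    target = pastures[assigned_pasture_id].boundary
    if fence_buffer_m > 0:
        target = target.buffer(fence_buffer_m)
    inside = shapely.covers(target, pts)
    in_other = np.zeros(len(fixes), dtype=bool)
    for pid, p in pastures.items():
        if pid == assigned_pasture_id:
            continue
        in_other |= shapely.covers(p.boundary, pts)
    wrong = ~inside & in_other
    oob = ~inside & ~in_other
    counts = {"wrong_pasture": int(wrong.sum()),
              "out_of_bounds": int(oob.sum())}
    return fixes.loc[inside].reset_index(drop=True), counts


def daytime_filter(fixes: pd.DataFrame,
                   window: tuple[float, float] = DEFAULT_DAYTIME_WINDOW,
                   ) -> pd.DataFrame:
    """Retain fixes whose local time-of-day falls in the half-open daytime
    window [start, end) hours — the default drops the low-activity
    22:00-04:00 night period."""
    t = pd.to_datetime(fixes["time_local"])
    secs = (t.dt.hour * 3600 + t.dt.minute * 60 + t.dt.second
            + t.dt.microsecond / 1e6)
    lo, hi = window
    keep = (secs >= lo * 3600.0) & (secs < hi * 3600.0)
    return fixes.loc[keep].reset_index(drop=True)


def validate_deployment(deployment: Deployment,
                        min_fixes: int = MIN_VALID_FIXES) -> Deployment:
    """Flag a deployment valid iff it retained at least ``min_fixes``
    cleaned fixes (default 1,000); invalid deployments stay in the QC
    report but are excluded from analysis."""
    deployment.valid = len(deployment.fixes) >= min_fixes
    return deployment


def clean_deployment(raw_records: pd.DataFrame, pastures: dict[str, Pasture],
                     assigned_pasture_id: str, *,
                     logger_id: str = "", animal_id: str = "",
                     trial_month: str = "",
                     offset_hours: float = DEFAULT_UTC_OFFSET_HOURS,
                     daytime: tuple[float, float] | None = None,
                     min_fixes: int = MIN_VALID_FIXES,
                     fence_buffer_m: float = 0.0) -> Deployment:
    """Run the full cleaning pipeline on parsed raw records.

    Steps: exact-duplicate removal -> coordinate/time conversion -> crop to
    the assigned pasture (counting wrong-pasture and out-of-bounds drops)
    -> optional daytime filter -> minimum-fix validation. Removal counts
    per reason are recorded and always sum to input minus output.
    """
    counts: dict[str, int] = {
        "malformed": int(raw_records.attrs.get("n_malformed", 0))}
    n_in = len(raw_records)
    deduped = dedupe(raw_records)
    counts["duplicate"] = n_in - len(deduped)
    fixes = records_to_fixes(deduped, offset_hours=offset_hours)
    fixes = fixes.sort_values("time_utc", kind="stable").reset_index(drop=True)
    fixes, crop_counts = crop_and_assign(fixes, pastures, assigned_pasture_id,
                                         fence_buffer_m=fence_buffer_m)
    counts.update(crop_counts)
    if daytime is not None:
        n_before = len(fixes)
        fixes = daytime_filter(fixes, daytime)
        counts["nighttime"] = n_before - len(fixes)
    dep = Deployment(logger_id=logger_id, animal_id=animal_id,
                     pasture_id=assigned_pasture_id, trial_month=trial_month,
                     fixes=fixes, removal_counts=counts)
    return validate_deployment(dep, min_fixes=min_fixes)
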