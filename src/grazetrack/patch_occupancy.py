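"""Patch-occupancy estimation on pasture grids and scheme comparison.

Pastures are tiled into equal patches at two levels: *quarter* patches
(the ~64 ha square pasture split 2 × 2 into ~16 ha cells) and a *1-ha*
grid of 100 × 100 m cells. A deployment's occupancy is the fraction of
its daytime fixes falling in each cell; a reduced logging scheme is
scored by the per-cell absolute difference of its occupancy from the
constant-logging occupancy of the same deployment, summarised
conservatively by the maximum across cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import box

from .ingest import Pasture
from .sampling_schemes import LoggingScheme

__all__ = [
    "PatchGrid",
    "OccupancyComparison",
    "build_grid",
    "occupancy_proportions",
    "occupancy_difference",
    "compare_schemes",
]

LEVELS = ("quarter_16ha", "grid_1ha")


@dataclass
class PatchGrid:
    """Axis-aligned tiling of a pasture bounding box, clipped to the
    boundary; cells are ordered row-major from the SW corner and cell
    membership is half-open [x0, x0+w) × [y0, y0+h) so every fix lands
    in exactly one cell (the outer max edges are closed)."""

    pasture_id: str
    level: str
    minx: float
    miny: float
    cell_w: float
    cell_h: float
    n_cols: int
    n_rows: int
    cells: list = field(repr=False, default_factory=list)  # clipped polygons

    @property
    def n_cells(self) -> int:
        return self.n_cols * self.n_rows

    def cell_areas_ha(self) -> np.ndarray:
        return np.array([c.area for c in self.cells]) / 10_000.0

    def cell_index(self, easting_m, northing_m) -> np.ndarray:
        """Row-major cell index for each point (must lie in the bbox)."""
        e = np.asarray(easting_m, dtype=float)
        n = np.asarray(northing_m, dtype=float)
        ci = np.floor((e - self.minx) / self.cell_w).astype(int)
        ri = np.floor((n - self.miny) / self.cell_h).astype(int)
        # points exactly on the outer max edge belong to the last cell
        ci = np.where((ci == self.n_cols)
                      & np.isclose(e, self.minx + self.n_cols * self.cell_w),
                      self.n_cols - 1, ci)
        ri = np.where((ri == self.n_rows)
                      & np.isclose(n, self.miny + self.n_rows * self.cell_h),
                      self.n_rows - 1, ri)
        if (ci < 0).any() or (ci >= self.n_cols).any() \
                or (ri < 0).any() or (ri >= self.n_rows).any():
            raise ValueError("fix outside the grid bounding box")
        return ri * self.n_cols + ci


def build_grid(pasture: Pasture, level: str) -> PatchGrid:
    """Tile a pasture at ``quarter_16ha`` (2 × 2) or ``grid_1ha``
    (100 × 100 m) level, anchored at the bounding-box minimum corner."""
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}, got {level!r}")
    minx, miny, maxx, maxy = pasture.boundary.bounds
    w, h = maxx - minx, maxy - miny
    if w <= 0 or h <= 0:
        raise ValueError("degenerate pasture polygon")
    if level == "quarter_16ha":
        n_cols, n_rows = 2, 2
        cell_w, cell_h = w / 2.0, h / 2.0
    else:
        cell_w = cell_h = 100.0
        n_cols = int(np.ceil(w / cell_w - 1e-9))
        n_rows = int(np.ceil(h / cell_h - 1e-9))
    cells = []
    for r in range(n_rows):
        for c in range(n_cols):
            cell = box(minx + c * cell_w, miny + r * cell_h,
                       min(minx + (c + 1) * cell_w, maxx),
                       min(miny + (r + 1) * cell_h, maxy))
            cells.append(cell.intersection(pasture.boundary))
    return PatchGrid(pasture_id=pasture.id, level=level, minx=minx, miny=miny,
                     cell_w=cell_w, cell_h=cell_h, n_cols=n_cols,
                     n_rows=n_rows, cells=cells)


def occupancy_proportions(fixes: pd.DataFrame, grid: PatchGrid) -> np.ndarray:
    """Fraction of fixes in each grid cell (row-major); sums to 1, empty
    cells report 0. Raises on zero fixes."""
    if len(fixes) == 0:
        raise ValueError("occupancy_proportions on zero fixes")
    idx = grid.cell_index(fixes["easting_m"].to_numpy(),
                          fixes["northing_m"].to_numpy())
    counts = np.bincount(idx, minlength=grid.n_cells).astype(float)
    return counts / counts.sum()


@dataclass
class OccupancyComparison:
    deployment_id: str
    scheme: LoggingScheme
    level: str
    abs_diff: np.ndarray       # per-cell |Δ proportion|, in [0, 1]
    max_abs_diff: float
    mean_abs_diff: float

    @property
    def max_abs_diff_pct(self) -> float:
        return 100.0 * self.max_abs_diff

    @property
    def mean_abs_diff_pct(self) -> float:
        return 100.0 * self.mean_abs_diff


def occupancy_difference(constant_props: np.ndarray,
                         scheme_props: np.ndarray,
                         scheme: LoggingScheme | None = None,
                         level: str = "", deployment_id: str = "",
                         ) -> OccupancyComparison:
    """Per-cell absolute occupancy difference between a reduced scheme
    and the constant-logging baseline on the same grid, with the
    conservative max-across-cells summary and the mean."""
    constant_props = np.asarray(constant_props, dtype=float)
    scheme_props = np.asarray(scheme_props, dtype=float)
    if constant_props.shape != scheme_props.shape:
        raise ValueError("occupancy_difference: grids differ "
                         f"({constant_props.shape} vs {scheme_props.shape})")
    diff = np.abs(constant_props - scheme_props)
    return OccupancyComparison(
        deployment_id=deployment_id,
        scheme=scheme or LoggingScheme("constant"),
        level=level,
        abs_diff=diff,
        max_abs_diff=float(diff.max()),
        mean_abs_diff=float(diff.mean()),
    )


def compare_schemes(fixes: pd.DataFrame, grid: PatchGrid,
                    schemes=None, deployment_id: str = "",
                    time_col: str = "time_local") -> pd.DataFrame:
    """Score each reduced scheme against constant logging for one
    deployment on one grid; returns a tidy frame with the per-scheme
    max/mean absolute differences (as percentages)."""
    from .sampling_schemes import STANDARD_SCHEMES
    schemes = [s for s in (schemes or STANDARD_SCHEMES)
               if s.pattern != "constant"]
    base = occupancy_proportions(fixes, grid)
    rows = []
    for scheme in schemes:
        sub = scheme.apply(fixes, time_col)
        props = occupancy_proportions(sub, grid)
        cmp_ = occupancy_difference(base, props, scheme, grid.level,
                                    deployment_id)
        rows.append({
            "deployment_id": deployment_id,
            "scheme": scheme.name,
            "level": grid.level,
            "max_abs_diff_pct": cmp_.max_abs_diff_pct,
            "mean_abs_diff_pct": cmp_.mean_abs_diff_pct,
            "n_fixes_scheme": len(sub),
        })
    return pd.DataFrame(rows)
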