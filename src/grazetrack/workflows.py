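"""End-to-end simulation studies built from the pipeline stages.

These helpers wire the synthetic herd generator into the analysis modules
without a file round-trip: simulate a deployment, convert observed fixes
into analysis frames (UTM + local time), and run the scheme-comparison
studies (daily-distance correction fitting/validation across trials, and
patch-occupancy scoring) that mirror the field workflow.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from shapely.geometry import box

from .geo import utm13n_forward
from .ingest import (DEFAULT_DAYTIME_WINDOW, Pasture, crop_and_assign,
                     daytime_filter, localize_timestamp)
from .patch_occupancy import build_grid, compare_schemes
from .sampling_schemes import STANDARD_SCHEMES, LoggingScheme
from .synthetic_herd import HerdSimConfig, observe_fixes, simulate_herd
from .travel_correction import (CorrectionModel, ValidationResult,
                                daily_distance, fit_correction,
                                validate_correction)

__all__ = [
    "analysis_fixes",
    "simulate_deployment",
    "pasture_from_config",
    "scheme_daily_table",
    "correction_study",
    "occupancy_study",
]


def analysis_fixes(raw_fixes: pd.DataFrame, config: HerdSimConfig,
                   ) -> pd.DataFrame:
    """Add the analysis columns (UTM metres, local time) to the raw
    lat/lon fixes produced by the observation model."""
    out = raw_fixes.copy()
    e, n = utm13n_forward(out["lat_dd"].to_numpy(), out["lon_dd"].to_numpy())
    out["easting_m"] = np.asarray(e, float)
    out["northing_m"] = np.asarray(n, float)
    out["time_local"] = localize_timestamp(out["time_utc"],
                                           config.local_offset_hours)
    return out


def simulate_deployment(config: HerdSimConfig, daytime: bool = True,
                        crop: bool = True) -> dict[str, pd.DataFrame]:
    """Simulate a herd and return analysis-ready fixes per animal,
    cropped to the pasture (dropping observation outliers, as the field
    cleaning does) and daytime-filtered by default."""
    out = {}
    pasture = pasture_from_config(config) if crop else None
    for traj in simulate_herd(config):
        fixes = analysis_fixes(observe_fixes(traj), config)
        if crop:
            fixes, _ = crop_and_assign(fixes, {pasture.id: pasture},
                                       pasture.id)
        if daytime:
            fixes = daytime_filter(fixes, DEFAULT_DAYTIME_WINDOW)
        out[traj.animal_id] = fixes
    return out


def pasture_from_config(config: HerdSimConfig, pasture_id: str = "P1",
                        species: str = "sheep") -> Pasture:
    """Square pasture polygon (UTM metres) matching a simulation config."""
    e0, n0 = config.origin_utm()
    side = config.pasture_side_m
    return Pasture(id=pasture_id, species=species,
                   boundary=box(e0, n0, e0 + side, n0 + side))


def scheme_daily_table(fixes: pd.DataFrame, schemes=STANDARD_SCHEMES,
                       animal_id: str = "") -> pd.DataFrame:
    """Per-day travel distance under each scheme for one animal's
    (daytime-filtered) fixes; tidy long frame."""
    frames = []
    for scheme in schemes:
        sub = scheme.apply(fixes)
        dd = daily_distance(sub, scheme_name=scheme.name)
        dd["animal_id"] = animal_id
        frames.append(dd)
    return pd.concat(frames, ignore_index=True)


def _derived_seeds(seed: int, n: int) -> list[int]:
    # independent sub-stream seeds, kept below 2**31
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s & 0x7FFFFFFF) for s in state]


def _trial_daily(config: HerdSimConfig, schemes) -> pd.DataFrame:
    per_animal = simulate_deployment(config, daytime=True)
    frames = [scheme_daily_table(fixes, schemes, animal_id=aid)
              for aid, fixes in per_animal.items()]
    df = pd.concat(frames, ignore_index=True)
    df["trial"] = config.start_local.strftime("%Y-%m")
    return df


def correction_study(seed: int = 1, *, n_pastures: int = 2,
                     n_animals: int = 3, days_per_trial: int = 5,
                     fine_step_s: int = 5, aggregate_herd: bool = True,
                     schemes=None, config_kwargs: dict | None = None,
                     ) -> dict[str, tuple[CorrectionModel, ValidationResult]]:
    """Fit per-scheme correction factors on three simulated monthly
    trials and validate on a held-out fourth trial.

    Mirrors the field design: each month fields ``n_pastures``
    independent herds of ``n_animals`` collared animals for
    ``days_per_trial`` days; the held-out trial (June) plays no part in
    fitting; beta fitted on the July-September daily pairs is applied to
    June estimates and the corrected slope refitted.

    Because herd-mates share the herd path, their daily distances are
    strongly correlated; by default each herd-day is therefore averaged
    to a single regression observation (the herd is the independent
    unit), which keeps the regression intervals honestly calibrated.
    Returns ``{scheme_name: (CorrectionModel, ValidationResult)}``.
    """
    schemes = [s for s in (schemes or STANDARD_SCHEMES)
               if s.pattern != "constant"]
    months = ["2017-06-01", "2017-07-01", "2017-08-01", "2017-09-01"]
    sub_seeds = _derived_seeds(seed, len(months) * n_pastures)
    tables = []
    for i, start in enumerate(months):
        for p in range(n_pastures):
            cfg = HerdSimConfig(n_animals=n_animals,
                                duration_days=days_per_trial,
                                fine_step_s=fine_step_s,
                                seed=sub_seeds[i * n_pastures + p],
                                start_local=pd.Timestamp(f"{start} 00:00:00"),
                                **(config_kwargs or {}))
            t = _trial_daily(cfg, list(schemes) + [LoggingScheme("constant")])
            t["pasture"] = f"P{p + 1}"
            tables.append(t)
    daily = pd.concat(tables, ignore_index=True)

    wide = daily.pivot_table(index=["trial", "pasture", "animal_id", "date"],
                             columns="scheme", values="distance_m")
    if aggregate_herd:
        wide = wide.groupby(["trial", "pasture", "date"]).mean()
    wide = wide[wide["constant"] > 0].reset_index()
    holdout_trial = pd.Timestamp(months[0]).strftime("%Y-%m")
    train = wide[wide["trial"] != holdout_trial]
    hold = wide[wide["trial"] == holdout_trial]

    results = {}
    for scheme in schemes:
        model = fit_correction(train[scheme.name], train["constant"],
                               scheme=scheme.name)
        result = validate_correction(model, hold[scheme.name],
                                     hold["constant"])
        results[scheme.name] = (model, result)
    return results


def occupancy_study(config: HerdSimConfig,
                    levels=("quarter_16ha", "grid_1ha"),
                    schemes=None) -> pd.DataFrame:
    """Per-scheme occupancy error for each simulated deployment at each
    grid level, plus the across-deployment mean of the per-deployment
    maxima (the conservative herd-level summary)."""
    pasture = pasture_from_config(config)
    per_animal = simulate_deployment(config, daytime=True)
    rows = []
    for level in levels:
        grid = build_grid(pasture, level)
        for aid, fixes in per_animal.items():
            rows.append(compare_schemes(fixes, grid, schemes,
                                        deployment_id=aid))
    detail = pd.concat(rows, ignore_index=True)
    summary = (detail.groupby(["scheme", "level"], as_index=False)
               .agg(mean_max_abs_diff_pct=("max_abs_diff_pct", "mean"),
                    mean_mean_abs_diff_pct=("mean_abs_diff_pct", "mean")))
    summary.attrs["detail"] = detail
    return summary
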