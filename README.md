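# grazetrack

A telemetry pipeline for GPS collars on grazing livestock. It takes the raw
comma-separated NMEA rows that low-cost collar loggers write to their memory
cards and turns them into herd-level statistics: how tightly a herd clusters,
which patches of a pasture it occupies, and how far each animal travels per
day — together with the tooling needed to choose a logging duty cycle that
preserves those answers while extending battery life.

## The problem

A collar that logs a fix every 20 s ("constant" logging) gives an excellent
picture of animal movement but drains its battery in about a week. Two
reduced patterns stretch that budget:

* **regular** logging — one fix per clock-aligned 5- or 10-min window;
* **burst** logging — the full 20-s stream during the first 5 or 10 minutes
  of each hour, then a sleep period (a power-timer duty cycle).

Reduced logging barely affects *space-use* estimates, but it systematically
underestimates *daily travel distance*: a subsampled track cuts the corners
of a tortuous grazing path, so by the triangle inequality its summed length
can only shrink. The package quantifies both effects and corrects the
second.

## Methods at the core

* **Ingest** — NMEA `ddmm.mmmm` + hemisphere fields are converted to signed
  decimal degrees (`4916.46,N` → 49.2743333°) and projected to UTM Zone 13N
  (NAD83); timestamps are localized from UTC; exact duplicate rows are
  dropped; fixes are cropped to the assigned pasture polygon (wrong-pasture
  and out-of-bounds drops counted separately); deployments retaining fewer
  than 1,000 fixes are flagged invalid; nighttime fixes (22:00–04:00 local)
  are excluded from analysis.
* **Geolocation QC** — 95% circular error probability (CEP95): the 95%
  empirical quantile of ellipsoidal geodesic distances from a unit's fixes
  to its own centroid (*precision*) or to a surveyed reference (*accuracy*).
* **Herd dispersion** — per local minute, the mean pairwise planar (UTM)
  distance among collared animals, using only each logger's first fix per
  minute and only minutes with ≥ 2 valid loggers; summarized by mean,
  median and 75th percentile.
* **Patch occupancy** — pastures tiled into four ~16-ha quarters and a
  1-ha (100 × 100 m) grid; a scheme is scored by the per-cell absolute
  difference of its fix proportions from constant logging, summarized
  conservatively by the maximum across cells per deployment.
* **Travel correction** — daily distance is the sum of geodesics between
  consecutive daytime fixes; each scheme's underestimation is corrected by a
  multiplicative factor β from the through-origin Gaussian maximum
  likelihood regression `constant = β · estimated`, fitted on training
  trials and validated on a held-out trial, where the corrected slope's 95%
  CI should contain 1.
* **Synthetic herd** — a simulator with known ground truth: the herd
  centroid follows a correlated random walk with a bimodal diel activity
  schedule, each animal an Ornstein–Uhlenbeck excursion about the centroid
  (stationary spread *s* ⇒ mean pairwise distance *s*√π), observed through
  a GPS model with isotropic per-axis error, dropped fixes and rare
  outliers, and serialized in the exact raw logger dialect.

## Worked example

Fit correction factors on three simulated monthly trials (two herds of
three collars, five days each) and validate them on a held-out trial, then
score occupancy error for the default one-week deployment:

```python
from grazetrack.workflows import correction_study, occupancy_study
from grazetrack.synthetic_herd import HerdSimConfig

results = correction_study(seed=1)
for name, (model, val) in results.items():
    lo, hi = val.slope_ci95
    print(f"{name:<11} beta={model.beta:5.2f}   corrected slope={val.slope:.3f} "
          f"(95% CI {lo:.3f}-{hi:.3f})  contains 1: {val.contains_one}")

summary = occupancy_study(HerdSimConfig(n_animals=3, duration_days=7,
                                        fine_step_s=5, seed=1))
print(summary.to_string(index=False))
```

prints

```
regular_5   beta= 4.22   corrected slope=0.974 (95% CI 0.932-1.017)  contains 1: True
regular_10  beta= 5.99   corrected slope=0.965 (95% CI 0.929-1.001)  contains 1: True
burst_5     beta= 7.13   corrected slope=0.984 (95% CI 0.922-1.046)  contains 1: True
burst_10    beta= 4.56   corrected slope=0.987 (95% CI 0.944-1.029)  contains 1: True
    scheme        level  mean_max_abs_diff_pct  mean_mean_abs_diff_pct
  burst_10     grid_1ha               1.205663                0.213228
  burst_10 quarter_16ha               0.605403                0.341265
   burst_5     grid_1ha               1.431739                0.256367
   burst_5 quarter_16ha               0.811929                0.446674
regular_10     grid_1ha               0.698723                0.076664
regular_10 quarter_16ha               0.435345                0.276868
 regular_5     grid_1ha               0.367429                0.044177
 regular_5 quarter_16ha               0.286355                0.159373
```

Every reduced scheme underestimates travel (β > 1; the simulator's
uncorrelated per-fix GPS noise makes the constant-logging baseline longer,
and hence β larger, than field collars with autocorrelated error would
show), and multiplying held-out estimates by β restores slopes whose CIs
contain 1. Occupancy error stays under ~1.5% everywhere, with regular
logging closer to constant than burst — space use is far more robust to
duty cycling than distance is.

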