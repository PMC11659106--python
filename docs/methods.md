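# Methods

This note documents the models, estimators, numerical choices, and known
limitations of the package.  Units throughout: μm, minutes; depth is
measured from the apical surface (0 = apical, increasing basally); speeds
are reported in μm/hr because that is the unit under which the cohort
distances and durations are mutually consistent (≈42 μm in ≈96 min is
≈27 μm/hr).

## Synthetic neuroepithelium generator

The generator is the package's replacement for the unreleased imaging
data: every analysis consumes its output, and every parameter it plants is
returned as ground truth so recovery can be tested quantitatively.  All
generators are deterministic functions of `(params, seed)`.

### Apical runs

A run is modeled kinematically: the nucleus holds its onset depth for a
few pre-onset frames, then descends at constant speed v = S/T_move to the
apical surface, where it holds for two post-arrival frames.  The paper-gap
choices, and why:

* **Moment-matched gamma draws.**  Planted positive quantities (distance
  S, moving time, per-pause duration) are gamma-distributed with exactly
  the requested mean and sd.  A truncated normal at any physical floor
  shifts the planted mean (≈ +2–3 min for a duration floor of ~40 min),
  which alone would consume the 2-SE recovery budget of the cohort tests;
  the gamma needs no truncation.  sd = 0 degenerates to the constant.
* **Compound duration.**  Total duration = moving time + realized pause
  time.  The moving-time moments are chosen by compound-Poisson
  decomposition (mean_move = mean_duration − rate·pause_mean; var_move =
  sd_duration² − rate·(pause_sd² + pause_mean²)) so the *total* duration
  has the requested mean and sd without rejecting draws.  Rejection-based
  alternatives ("redraw until the pauses fit") select against paused or
  fast runs and measurably bias both the planted duration and the pause
  rate.
* **Poisson pause counts, drawn once.**  The per-run pause count and the
  pause durations are never redrawn, so their planted distributions are
  exactly Poisson/gamma; only the moving time is redrawn (rarely) when the
  pauses cannot physically fit inside the run.
* **Grid-aligned full stops.**  Pauses occupy whole sampling-grid frames:
  durations round to multiples of the 10-min sampling interval and starts
  snap to the grid, at depths drawn uniformly from `pause_depth_range`
  (default 20–30 μm, where pausing is observed).  A 10-min movie cannot
  resolve sub-frame pause structure, and an off-grid pause produces a
  mixed frame that is neither "paused" nor "moving" — roughly a fifth of
  slow-stage pauses would then be invisible to any frame-based detector.
  Grid alignment makes pause detection well-posed by construction: during
  a pause the frame displacement is essentially zero, far below 10% of the
  run's maximum frame displacement.
* **Localization jitter σ = 0.3 μm** per axis on moving samples.  Path
  length summed over noisy frames is inflated by ≈2σ²/Δz per frame; at
  σ = 0.3 the inflation over an E11 run (≈ +0.4 μm) approximately cancels
  the arrival-tolerance deficit (≈ −0.4 μm), keeping the measured cohort
  distance centered on the planted mean.  Larger jitter (σ = 0.5) biases
  the measured distance by ≈ +1 μm, more than 2 SE of a 500-run cohort.
* Pre-onset samples hold the onset depth exactly (lateral jitter would not
  affect onset detection, which uses the depth-decreasing speed); this
  makes the planted onset recoverable to the frame.

Stage presets (`APICAL_RUN_PRESETS`): E11 distance 42.3 ± 9.6 μm, duration
95.7 ± 41.9 min, pause rate 0.2; E12 44.9 ± 10.5, 154.6 ± 62.5, 0.7; E13
46.5 ± 11.3, 180.9 ± 90.9, 1.0; per-pause mean durations 18.5/20.0/21.5
min.  The per-pause sd is not published per event; 6 min is used as a
plausible spread.

### Lateral drift

2D Gaussian random walks, per-step per-axis variance 2·D·Δt, Δt = 6 min,
starting uniformly in the 100×100 μm window and running 6 hr (the tracking
duration of the drift movies; only the first hour of *lags* enters the
fit).  The window bounds the starting positions only: the tracker follows
nuclei wherever they go.  Mirror-reflecting walls are available
(`boundary="reflect"`) but are not the default — reflected Brownian motion
in a 100-μm box measurably depresses the MSD at 1-hr lags (a fitted D of
≈0.144 for a planted 0.175), so a reflecting generator cannot be recovered
by an MSD estimator that assumes free diffusion.

### Nuclear fields

Nuclei are placed slab-by-slab: each 2-μm slab receives a Poisson count
with mean `density × area/10⁴`, uniform positions, gamma radii
(default 3.0 ± 0.4 μm).  The preset depth profiles anchor the published
20- and 30-μm densities exactly (flat across each measured slab, so the
2-μm counting window sees the anchored value) and interpolate a plausible
bell shape elsewhere.  With `allow_overlap=False`, placement is hard-sphere
rejection sampling with a bounded attempt budget; unplaceable nuclei are
reported per slab in `field.shortfall`, never silently dropped.  With
`target_occupancy=(depth, fraction)` the radii are rescaled by a common
factor, found by bisection against an exact-geometry oracle (shapely union
of the cross-section disks, clipped to the window), until the realized
union coverage at that depth equals the target to ~1e-4; the measuring
stage (`section_occupancy`) is a completely independent rasterization.

### Mitosis patterns and pulse-chase cohorts

CSR is a homogeneous Poisson process.  The clustered alternative is a
Thomas process (Poisson parents on a 4σ-padded window, Poisson offspring,
isotropic Gaussian σ displacement).  The regular alternative is simple
sequential inhibition: uniform candidates accepted only at ≥ the hard-core
radius from all accepted events, targeting a Poisson count; when the
target exceeds the packing bound, fewer events are placed.  Event times
are uniform on the cumulation span.

Pulse-chase cohorts are two-component Gaussian mixtures over depth
(S-like basal component; G2-like apical component), clipped to the
epithelium thickness.  The control preset has mixture mean 56.7 μm
(g2_fraction 0.33, G2 at 28 ± 8, S at 70.9 ± 12, thickness 92.6); the
overproliferation preset has mean 62.4 μm with the G2 component suppressed
(fraction 0.20) and the S component shifted basally in a 126.7-μm
epithelium.  Component labels are retained.

## Trajectory metrics

* **Arrival** is the first sample with depth ≤ 2 μm (one nuclear radius);
  the endpoint "reached the apical surface" needs a tolerance because
  sampled depth rarely hits 0 exactly.
* **Onset** is the start of the first frame interval whose apicalward
  (depth-decreasing) speed reaches `threshold_fraction` (default 0.1) of
  the trajectory's maximum apicalward frame speed, with commitment: the
  nucleus must subsequently reach the apical surface without rising above
  the onset depth.  First-crossing-with-commitment is one of several
  readings of "acceleration up to 10% of the maximum velocity"; sustained-
  crossing variants differ only on pathological tracks.
* **Pauses** are maximal blocks of frame intervals with 3D frame speed
  below 10% of the run's own maximum frame speed — per-trajectory, not per
  cohort.  Eligible intervals lie strictly between the onset interval and
  the interval ending at the arrival sample, so partial first/last frames
  cannot register as spurious pauses.  One sub-threshold frame is a pause
  (the minimum observable pause is one sampling interval).  Raising the
  threshold can in principle merge two pauses separated by a single slow
  frame; on generator output (pauses separated by full-speed frames) the
  count is monotone in the threshold over any practical range.
* **Distance** is the 3D path length summed over frames from onset to
  arrival (≥ net displacement, with equality for monotone jitter-free
  descent); average speed = distance/duration.  "Average speed" could also
  be read as the mean of frame speeds; the two differ under jitter by
  O(σ²/Δz) and path/duration is used throughout.

## MSD and diffusion

`compute_msd` is the time-averaged estimator with 1/(n−τ) normalization
per trajectory, pooled across trajectories by pair counts (the double-sum
reading; an unweighted per-track average is provided as
`compute_msd_per_track`).  `fit_diffusion` is OLS of MSD on τ over
0 < τ ≤ 60 min with a free intercept — localization noise adds a constant
offset, so forcing the origin would bias the slope; τ = 0 is excluded.
D = slope/(2d), lateral d = 2 by default.

The reported `stderr_D` is a delete-one-trajectory jackknife, not the OLS
residual standard error: MSD values at successive lags share displacement
pairs, so OLS residuals understate the sampling variability of the slope
by roughly an order of magnitude (measured 0.0005 vs a replicate sd of
0.0052 at D = 0.175 with 200 six-hour tracks).  The jackknife SE matches
the replicate sd.  A negative fitted slope is reported as-is with a
warning.  The curvature diagnostic mean[MSD(2τ)/MSD(τ)] flags superlinear
(ballistic-like) input: ≈2 for diffusion, ≈4 for ballistic motion;
`superlinear` is set above 3.

## Ripley's K and classification

The default estimator is the literal uncorrected form
K̂(r) = (A/n²)·Σᵢ Σⱼ≠ᵢ 1(dᵢⱼ ≤ r).  Its null mean carries a first-order
edge deficit πr² − (8/3)r³/L in an L×L window (≈8.5% at r = 10, L = 100);
the deficit cancels in classification because observed and simulated
patterns share the estimator.  A translation-corrected variant
(weights A/((Lx−|dx|)(Ly−|dy|))) is available and is unbiased within ~2%.

Envelopes come from 99 CSR simulations conditioned on the observed n
(binomial, holding sample size fixed).  Two constructions are provided:

* **global** (default): the pointwise min/max of the simulated curves.
  Read across the whole radius grid, exceeding this band anywhere is rare
  under the null: measured 94–97% "random" calls on CSR patterns.
* **pointwise**: the 3rd-lowest/3rd-highest of 99 at each radius — the
  band that contains 95% of the simulated lines per radius.  Against the
  whole grid it misclassifies ~20% of CSR patterns (multiplicity), so it
  is not the classification default.

Classification requires an excursion of ≥2 contiguous radii (guarding
against single-radius blips); double excursions resolve to the larger
integrated deviation and are flagged as ties.  The default radius grid is
1–25 μm in 1-μm steps (a quarter of the window side).  Measured
calibration at these defaults: CSR → "random" 94–97/100; Thomas clusters
(σ = 2 μm, 5 offspring/parent) → "clustered" 100/100; hard-core (r = 8 μm)
→ "regular" 100/100.

Cumulative registration keeps events with t ∈ (t₀ − span, t₀] (span
default 180 min), deduplicated by event id, shifted to pattern-local time.

## Pulse-chase comparison

Histograms use half-open 10-μm bins from the apical surface; a depth
exactly at the basal boundary joins the last bin.  Per-bin comparison is a
2×2 Pearson χ² on raw counts (in-bin vs out-of-bin × group), 1 df,
two-tailed, no continuity correction; bins empty in both groups are
reported as χ² = 0, p = 1.  Raw per-bin p-values are reported by default
(Bonferroni behind a flag), matching the per-bin reporting convention of
the source analyses.

## Statistical battery

Mann–Whitney U uses exact enumeration when the combined sample is ≤12 and
tie-free (the regime where enumeration is instant), otherwise the
tie-corrected normal approximation with continuity correction.
Steel–Dwass ranks each pair jointly on its own, computes the tie-corrected
standardized rank-sum statistic, and refers √2·|z| to the Studentized
range distribution with k groups and ∞ df; measured family-wise type-I
error is 0.038 at nominal 0.05 over 2000 null replicates (3 groups,
n = 20).  All tests are two-tailed with α = 0.05.

## Pipeline and reproducibility

A single global seed fans out to per-stage child seeds via
`SeedSequence([seed, crc32(stage)])` (all < 2³¹), so adding or reordering
stages never perturbs another stage's stream.  Every output directory
carries a manifest (config hash, seed, package version, per-stage record
counts) and repeated runs are byte-identical.  Depth bins are half-open
throughout; phase proportions for an empty slab are reported as undefined
(None), never 0.

## Problem sizes and test design

The test suite and the acceptance script use cohorts of 500 runs, 200
drift tracks, 20 fields, and 100 classification replicates — large enough
that the 2–3-SE recovery bands are a few percent of the planted values,
small enough that the whole suite runs in about a minute on one CPU.
Recovery tests compare measured cohort statistics against the planted
parameters at 2–3 standard errors, so individual seeded checks carry the
usual ~5% tail risk by construction.

## Limitations

* The trajectory model is kinematic (piecewise-constant velocity, full
  stops, Gaussian jitter); it does not model crowding forces, cell-cycle
  progression, or the observational correlation between pause frequency
  and local density — only the printed marginal distributions.
* Pauses shorter than one sampling interval are unrepresentable and
  undetectable by design; real sub-frame slowdowns would appear as reduced
  frame speeds, not pauses.
* Nuclei are isotropic spheres; measured nuclear aspect ratios are not
  modeled, so occupancy calibration compensates with slightly smaller
  radii than physical nuclei.
* The Thomas/hard-core/CSR triplet spans the hypothesis space of the
  classification, not the mechanistic space of real mitosis placement.
* Passing recovery tests shows the estimators are correct and calibrated
  on data matching their assumptions; it cannot validate the assumptions
  against real tissue.
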