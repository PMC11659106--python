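# iknm — quantitative analysis of interkinetic nuclear migration

In the pseudostratified neuroepithelium of the embryonic brain, neural
progenitor nuclei shuttle along the apicobasal axis with the cell cycle
(interkinetic nuclear migration, IKNM): basalward in G1, back to the apical
surface in G2, where mitosis occurs.  This package implements the
quantitative toolkit used to characterize that collective behavior from
post-segmentation tracking data:

* **Trajectory metrics** for apical (G2) nucleokinesis — onset detection,
  total 3D path length, duration, average and maximum frame speed, and
  *pause* detection: a pause is a maximal block of frame intervals whose
  speed falls below 10% of that run's own maximum frame speed.
* **Depth-resolved nuclear density and sectional occupancy** — centroid
  counts per 2-μm horizontal slab normalized to 100×100 μm, the fraction of
  the sectional area covered by the union of nuclear cross-sections
  (rasterized, overlaps counted once), and G1-like vs S/G2-like composition.
* **Tissue fluidity by MSD** — the time- and ensemble-averaged mean square
  displacement of laterally drifting nuclei,
  MSD(τ) = ⟨(x(t+τ) − x(t))²⟩, fitted over the first hour of lags by OLS;
  for normal diffusion MSD(τ) = 2 d D τ, so the lateral (d = 2) diffusion
  coefficient is D = m/2d from the slope m.
* **Ripley's K classification of mitosis patterns** —
  K̂(r) = (1/nρ̂) Σᵢ (events within r of event i) for 3-hr cumulative
  mitosis positions, compared against an envelope from 99 simulations of
  complete spatial randomness (CSR, K(r) = πr²) conditioned on the observed
  n: above the envelope → *clustered*, below → *regular*, inside → *random*.
* **Pulse-chase depth histograms** — labeled-cohort depth distributions in
  10-μm bins (percent of total) with per-bin 2×2 χ² comparisons.
* **The nonparametric battery** — two-tailed Mann–Whitney U (exact at small
  n), Steel–Dwass all-pairs comparison on the Studentized range, Pearson χ².

The raw live-imaging data behind these analyses are not public, so the
package is driven by a first-class synthetic neuroepithelium generator that
plants every parameter the pipeline is supposed to recover (run
distance/duration distributions, Poisson pause counts, diffusion
coefficients, depth-density profiles, sectional coverage, point-process
structure, labeled-cohort mixtures) and returns the ground truth alongside
the data.  Stage presets encode the embryonic-day E11–E13 parameter sets.

## Worked example

```python
import iknm
from iknm import synthetic as syn
from iknm.trajectory import cohort_metrics
from iknm.msd import compute_msd, fit_diffusion

# 200 synthetic apical runs at the E11 preset, sampled every 10 min
sim = syn.simulate_apical_runs(syn.APICAL_RUN_PRESETS["E11"], n=200, seed=0)
m = cohort_metrics(sim.trajectories)
print(f"distance  {m.total_distance_um.mean():.1f} ± {m.total_distance_um.std(ddof=1):.1f} um")
print(f"duration  {m.duration_min.mean():.1f} ± {m.duration_min.std(ddof=1):.1f} min")
print(f"pauses    {m.n_pauses.mean():.2f} per run")

# lateral tissue fluidity from 200 drifting nuclei (Δt = 6 min)
drift = syn.simulate_lateral_drift(
    syn.DriftParams(diffusion_coefficient=0.175, n_tracks=200), seed=0)
est = fit_diffusion(compute_msd(drift.trajectories, max_lag=60.0), fit_window=60.0)
print(f"D = {est.D:.3f} ± {est.stderr_D:.3f} um2/min")
```

prints

```
distance  42.0 ± 9.8 um
duration  95.7 ± 40.2 min
pauses    0.21 per run
D = 0.180 ± 0.006 um2/min
```

i.e. the measured cohort recovers the planted E11 distance (42.3 ± 9.6 μm),
duration (95.7 ± 41.9 min) and pause rate (0.2 per run), and the MSD fit
recovers the planted diffusion coefficient 0.175 μm²/min within its
(jackknife) standard error.

The same stages are available from the shell:

```bash
iknm simulate runs --preset E11 --n 200 --seed 0 --out runs.csv
iknm trajectories --in runs.csv --out results/
iknm simulate pattern --kind csr --seed 0 --out events.csv
iknm ripley --in events.csv --out results/        # -> "random"
iknm run --out demo/ --seed 7                      # full demo pipeline
```

Every simulated CSV carries a `.truth.json` sidecar with the planted
parameters; every pipeline output directory carries a `manifest.json` with
the config hash, seed, and per-stage record counts, and repeated runs with
the same seed are byte-identical.

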