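"""Synthetic neuroepithelium data generator.

Produces all inputs the analysis stages consume, with planted and fully
recoverable ground truth:

* apical G2-phase nucleokinesis runs with planted distance/duration
  distributions and Poisson-count pauses,
* lateral 2D Brownian nuclear drift with a planted diffusion coefficient,
* static 3D nuclear packings with a depth-dependent density profile and an
  optional target sectional occupancy,
* spatial point processes of mitoses (complete spatial randomness, Thomas
  cluster, hard-core/regular),
* pulse-chase cohorts of labeled nuclei drawn from a two-component
  (S-like / G2-like) depth mixture.

Every generator is deterministic given (params, seed).

Modeling notes
--------------
Positive planted quantities (run distance, run duration, pause duration)
are drawn from moment-matched gamma distributions: the gamma has exactly
the requested mean and standard deviation while remaining strictly
positive, so no truncation bias is introduced into the planted moments.
With sd = 0 the draw degenerates to the constant mean.

Pauses are planted as complete stops occupying whole sampling-grid frames
(duration rounded to a multiple of the sampling interval, onset snapped to
the grid).  The observable in a 10-min movie is the frame displacement;
sub-frame pause structure is not identifiable, and off-grid pauses would
produce mixed frames whose displacement is neither "paused" nor "moving".
Grid alignment guarantees the documented well-posedness property: during a
pause the frame-to-frame displacement is far below 10% of the run's
maximum frame displacement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (
    EventPattern,
    LabeledCohort,
    NuclearField,
    NuclearTrajectory,
    PHASE_G1,
    PHASE_SG2,
    ValidationError,
)

__all__ = [
    "ApicalRunParams",
    "DriftParams",
    "FieldParams",
    "PointProcessParams",
    "PulseChaseParams",
    "PlantedPause",
    "ApicalRunTruth",
    "ApicalRunSimulation",
    "DriftSimulation",
    "PulseChaseSimulation",
    "simulate_apical_runs",
    "simulate_lateral_drift",
    "simulate_nuclear_field",
    "simulate_mitosis_pattern",
    "simulate_pulse_chase",
    "APICAL_RUN_PRESETS",
    "DRIFT_D_PRESETS",
    "DENSITY_PROFILE_PRESETS",
    "PULSE_CHASE_PRESETS",
]


# ---------------------------------------------------------------------------
# random draws

def _draw_positive(rng, mean: float, sd: float, size=None):
    """Moment-matched gamma draw (degenerate constant when sd == 0)."""
    if mean <= 0:
        raise ValidationError(f"mean must be positive, got {mean}")
    if sd < 0:
        raise ValidationError(f"sd must be non-negative, got {sd}")
    if sd == 0:
        return mean if size is None else np.full(size, float(mean))
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return rng.gamma(shape, scale, size)


# ---------------------------------------------------------------------------
# apical G2 runs


@dataclass
class ApicalRunParams:
    """Planted distributions for apical (G2-phase) nucleokinesis runs.

    Distances are in μm, durations in minutes.  ``pause_rate`` is the
    Poisson mean of the per-run pause count; ``pause_depth_range`` is the
    depth interval (μm from the apical surface) within which pauses are
    inserted.  ``jitter_sd`` is the positional localization noise added to
    moving samples (per axis).
    """

    mean_distance: float = 42.3
    sd_distance: float = 9.6
    mean_duration: float = 95.7
    sd_duration: float = 41.9
    pause_rate: float = 0.2
    pause_mean_duration: float = 18.5
    pause_sd_duration: float = 6.0
    onset_depth_jitter: float = 0.0
    sampling_interval: float = 10.0
    pause_depth_range: Tuple[float, float] = (20.0, 30.0)
    jitter_sd: float = 0.3
    n_pre_frames: int = 3
    n_post_frames: int = 2

    def validate(self) -> None:
        if self.mean_distance <= 0:
            raise ValidationError("mean_distance must be positive")
        if self.sampling_interval <= 0:
            raise ValidationError("sampling_interval must be positive")
        if self.sd_distance < 0 or self.sd_duration < 0 or self.pause_sd_duration < 0:
            raise ValidationError("standard deviations must be non-negative")
        if self.pause_rate < 0:
            raise ValidationError("pause_rate must be non-negative")
        expected_pause = self.pause_rate * self.pause_mean_duration
        if expected_pause >= self.mean_duration:
            raise ValidationError(
                "impossible parameters: expected pause time "
                f"({expected_pause:.1f} min) >= mean run duration "
                f"({self.mean_duration:.1f} min)"
            )
        lo, hi = self.pause_depth_range
        if not (0 <= lo < hi):
            raise ValidationError("pause_depth_range must satisfy 0 <= lo < hi")
        if self.jitter_sd < 0 or self.onset_depth_jitter < 0:
            raise ValidationError("jitter parameters must be non-negative")


@dataclass
class PlantedPause:
    start: float
    end: float
    duration: float
    nominal_duration: float
    depth: float


@dataclass
class ApicalRunTruth:
    """Per-run planted ground truth."""

    track_id: str
    distance: float
    duration: float
    onset_time: float
    arrival_time: float
    speed_um_min: float
    pauses: List[PlantedPause]

    @property
    def n_pauses(self) -> int:
        return len(self.pauses)


@dataclass
class ApicalRunSimulation:
    trajectories: List[NuclearTrajectory]
    truth: List[ApicalRunTruth]
    params: ApicalRunParams
    seed: int

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for tr in self.truth:
            rows.append(
                {
                    "track_id": tr.track_id,
                    "distance_um": tr.distance,
                    "duration_min": tr.duration,
                    "onset_time_min": tr.onset_time,
                    "arrival_time_min": tr.arrival_time,
                    "speed_um_min": tr.speed_um_min,
                    "n_pauses": tr.n_pauses,
                    "total_pause_min": sum(p.duration for p in tr.pauses),
                }
            )
        return pd.DataFrame(rows)


def _place_pauses(
    rng,
    distance: float,
    duration: float,
    quantized: np.ndarray,
    v: float,
    t0: float,
    dt: float,
    depth_range: Tuple[float, float],
) -> List[PlantedPause]:
    """Snap pauses to the sampling grid at depths drawn from depth_range.

    Starts are clamped so every pause lies strictly inside the run with at
    least one moving frame before, between and after pauses; placement is
    guaranteed to succeed when the caller has ensured
    duration >= sum(quantized) + (2k+1)·dt.
    """
    k = quantized.size
    if k == 0:
        return []
    lo = max(depth_range[0], 2.0)
    hi = min(depth_range[1], distance - v * dt)
    if hi <= lo:  # run too short for the configured range: use its middle
        lo, hi = 0.3 * distance, 0.7 * distance
    depths = np.sort(rng.uniform(lo, hi, k))[::-1]
    arrival = t0 + duration
    remaining = np.concatenate([np.cumsum(quantized[::-1])[::-1], [0.0]])
    pauses: List[PlantedPause] = []
    prev_end = t0
    elapsed_pause = 0.0
    for j, (d_target, dur) in enumerate(zip(depths, quantized)):
        wall = t0 + (distance - d_target) / v + elapsed_pause
        start = dt * math.ceil(wall / dt - 1e-9)
        # backward feasibility: leave room (with 1-frame gaps) for the
        # remaining pauses and one moving frame before arrival
        latest = dt * math.floor(
            (arrival - dt - remaining[j] - (k - 1 - j) * dt) / dt + 1e-9
        )
        start = min(max(start, prev_end + dt), latest)
        if start < prev_end + dt:
            raise ValidationError(
                "internal: pause placement infeasible despite fit check"
            )
        depth_real = distance - v * ((start - t0) - elapsed_pause)
        pauses.append(
            PlantedPause(
                start=start,
                end=start + dur,
                duration=dur,
                nominal_duration=float("nan"),
                depth=depth_real,
            )
        )
        prev_end = start + dur
        elapsed_pause += dur
    return pauses


def simulate_apical_runs(
    params: ApicalRunParams, n: int, seed: int
) -> ApicalRunSimulation:
    """Simulate ``n`` apical nucleokinesis runs sampled every 10 min.

    Kinematics: piecewise-constant apicalward velocity from the planted
    onset depth (= planted distance) to the apical surface, interrupted by
    planted full-stop pauses; Gaussian positional jitter on moving samples.
    The trajectory holds its start position for a few frames before onset
    and its apical position for a few frames after arrival, so onset and
    arrival detection are exercised.
    """
    params.validate()
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    dt = params.sampling_interval
    t0 = params.n_pre_frames * dt

    trajectories: List[NuclearTrajectory] = []
    truths: List[ApicalRunTruth] = []
    for i in range(n):
        distance = float(_draw_positive(rng, params.mean_distance, params.sd_distance))
        if params.onset_depth_jitter > 0:
            distance = max(distance + rng.normal(0.0, params.onset_depth_jitter), 2 * dt)

        # pause count and durations are drawn once and never redrawn, so
        # their planted distributions stay exactly Poisson/gamma; only the
        # run duration is redrawn until the pauses physically fit inside it
        k = int(rng.poisson(params.pause_rate))
        nominal = np.atleast_1d(
            _draw_positive(rng, params.pause_mean_duration,
                           params.pause_sd_duration, size=k)
        ) if k else np.empty(0)
        quantized = dt * np.maximum(1, np.round(nominal / dt)) if k else np.empty(0)
        # total duration = moving time + realized pause time, with the
        # moving-time moments chosen so the cohort's total-duration mean
        # and variance match the requested mean_duration/sd_duration
        # (compound-Poisson decomposition)
        mean_move = params.mean_duration - params.pause_rate * params.pause_mean_duration
        var_move = params.sd_duration ** 2 - params.pause_rate * (
            params.pause_sd_duration ** 2 + params.pause_mean_duration ** 2
        )
        sd_move = math.sqrt(max(var_move, 0.0))
        floor = max((2 * k + 1) * dt, dt)
        t_move = None
        for _attempt in range(1000):
            cand = float(_draw_positive(rng, mean_move, sd_move))
            if cand >= floor:
                t_move = cand
                break
        if t_move is None:
            raise ValidationError(
                "could not realize a run under these parameters; expected "
                "pause time is too close to the run duration"
            )
        duration = t_move + float(quantized.sum())
        v = distance / t_move
        pauses = _place_pauses(
            rng, distance, duration, quantized, v, t0, dt,
            params.pause_depth_range,
        )
        for p, nom in zip(pauses, nominal):
            p.nominal_duration = float(nom)

        arrival = t0 + duration
        t_end = dt * math.ceil(arrival / dt - 1e-9) + params.n_post_frames * dt
        t_grid = np.arange(0.0, t_end + dt / 2, dt)

        # piecewise depth: constant before onset and after arrival, moving
        # at v in between except during planted full stops
        pause_before = np.zeros_like(t_grid)
        in_pause = np.zeros(t_grid.size, dtype=bool)
        for p in pauses:
            pause_before += np.clip(t_grid - p.start, 0.0, p.duration)
            in_pause |= (t_grid >= p.start - 1e-9) & (t_grid <= p.end + 1e-9)
        moving = np.clip(t_grid - t0, 0.0, None) - pause_before
        depth = np.where(t_grid <= t0, distance, distance - v * moving)
        depth = np.where(t_grid >= arrival, 0.0, depth)

        x0, y0 = rng.uniform(0.0, 100.0, 2)
        x = np.full(t_grid.size, x0)
        y = np.full(t_grid.size, y0)
        if params.jitter_sd > 0:
            mask = (t_grid > t0 + 1e-9) & (t_grid < arrival - 1e-9) & ~in_pause
            m = int(mask.sum())
            x[mask] += rng.normal(0.0, params.jitter_sd, m)
            y[mask] += rng.normal(0.0, params.jitter_sd, m)
            depth[mask] += rng.normal(0.0, params.jitter_sd, m)
        depth = np.maximum(depth, 0.0)

        track_id = f"run{i:04d}"
        trajectories.append(
            NuclearTrajectory(track_id, t_grid, x, y, depth, phase="G2")
        )
        truths.append(
            ApicalRunTruth(
                track_id=track_id,
                distance=distance,
                duration=duration,
                onset_time=t0,
                arrival_time=arrival,
                speed_um_min=v,
                pauses=pauses,
            )
        )
    return ApicalRunSimulation(trajectories, truths, params, seed)


# ---------------------------------------------------------------------------
# lateral Brownian drift


@dataclass
class DriftParams:
    """Planted lateral diffusion of apicobasally stationary nuclei."""

    diffusion_coefficient: float = 0.175  # μm²/min
    n_tracks: int = 200
    track_duration: float = 360.0  # min (6-hr tracking movies)
    sampling_interval: float = 6.0  # min
    window: Tuple[float, float] = (100.0, 100.0)
    #: "none": the window is the observation area only and the tracker
    #: follows nuclei beyond it (free diffusion, MSD exactly 4Dτ);
    #: "reflect": hard walls at the window edges.  Reflection measurably
    #: depresses the MSD at 1-hr lags in a 100-μm window, so free motion
    #: is the default for fluidity calibration.
    boundary: str = "none"

    def validate(self) -> None:
        if self.boundary not in ("none", "reflect"):
            raise ValidationError(f"unknown boundary mode {self.boundary!r}")
        if self.diffusion_coefficient < 0:
            raise ValidationError("diffusion coefficient must be >= 0")
        if self.n_tracks < 1:
            raise ValidationError("n_tracks must be >= 1")
        if self.track_duration <= 0 or self.sampling_interval <= 0:
            raise ValidationError("durations must be positive")
        if any(v <= 0 for v in self.window):
            raise ValidationError("window dimensions must be positive")


@dataclass
class DriftSimulation:
    trajectories: List[NuclearTrajectory]
    params: DriftParams
    seed: int

    @property
    def planted_d(self) -> float:
        return self.params.diffusion_coefficient


def _reflect(values: np.ndarray, upper: float) -> np.ndarray:
    """Fold coordinates into [0, upper] by mirror reflection."""
    period = 2.0 * upper
    v = np.mod(values, period)
    return np.where(v > upper, period - v, v)


def simulate_lateral_drift(params: DriftParams, seed: int) -> DriftSimulation:
    """2D Gaussian random walks with per-step per-axis variance 2·D·Δt.

    Tracks start uniformly in the window.  By default the walk is free
    (the window bounds only the starting positions); with
    ``boundary="reflect"`` tracks are mirror-reflected at the window
    edges, which keeps the density uniform but depresses the MSD at long
    lags.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    dt = params.sampling_interval
    n_steps = int(round(params.track_duration / dt))
    if n_steps < 1:
        raise ValidationError("track_duration shorter than one sampling interval")
    t_grid = np.arange(n_steps + 1) * dt
    step_sd = math.sqrt(2.0 * params.diffusion_coefficient * dt)
    w, h = params.window

    trajectories = []
    for i in range(params.n_tracks):
        start = rng.uniform([0.0, 0.0], [w, h])
        steps = rng.normal(0.0, step_sd, (n_steps, 2)) if step_sd > 0 else np.zeros((n_steps, 2))
        raw = start + np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        if params.boundary == "reflect":
            x = _reflect(raw[:, 0], w)
            y = _reflect(raw[:, 1], h)
        else:
            x, y = raw[:, 0], raw[:, 1]
        depth = np.full(t_grid.size, 30.0)  # nominal section depth
        trajectories.append(
            NuclearTrajectory(f"drift{i:04d}", t_grid, x, y, depth)
        )
    return DriftSimulation(trajectories, params, seed)


# ---------------------------------------------------------------------------
# static nuclear field


@dataclass
class FieldParams:
    """3D nuclear packing with a depth-dependent density profile.

    ``density_profile`` lists ``(depth_lo, depth_hi, count_per_100x100um)``
    slabs: the expected number of nuclear centroids per 100×100 μm of
    section area per slab.  ``phase_proportions_by_depth`` lists
    ``(depth_lo, depth_hi, fraction_g1)``; the complementary fraction is
    S/G2-like.  ``target_occupancy`` optionally requests calibration of the
    nuclear radii so the realized union coverage of nuclear cross-sections
    at ``(depth, fraction)`` matches the target exactly (verified during
    generation with an exact-geometry oracle).
    """

    box: Tuple[float, float, float] = (100.0, 100.0, 100.0)
    density_profile: Sequence[Tuple[float, float, float]] = ()
    radius_mean: float = 3.0
    radius_sd: float = 0.4
    phase_proportions_by_depth: Sequence[Tuple[float, float, float]] = ()
    allow_overlap: bool = True
    target_occupancy: Optional[Tuple[float, float]] = None
    max_attempts_per_nucleus: int = 200

    def validate(self) -> None:
        if any(v <= 0 for v in self.box):
            raise ValidationError("box dimensions must be positive")
        for lo, hi, dens in self.density_profile:
            if dens < 0:
                raise ValidationError("densities must be non-negative")
            if not (0 <= lo < hi <= self.box[2] + 1e-9):
                raise ValidationError(f"bad slab [{lo}, {hi})")
        for lo, hi, frac in self.phase_proportions_by_depth:
            if not (0.0 <= frac <= 1.0):
                raise ValidationError("phase fractions must lie in [0, 1]")
        if self.radius_mean <= 0 or self.radius_sd < 0:
            raise ValidationError("invalid radius distribution")
        if self.target_occupancy is not None:
            d, f = self.target_occupancy
            if not (0 < f < 1) or not (0 <= d <= self.box[2]):
                raise ValidationError("invalid target_occupancy")


def _g1_fraction(params: FieldParams, depth: float) -> float:
    for lo, hi, frac in params.phase_proportions_by_depth:
        if lo <= depth < hi:
            return frac
    return 1.0


def _union_coverage_exact(
    centers: np.ndarray, radii: np.ndarray, depth: float, box
) -> float:
    """Exact-geometry oracle: union area of nuclear cross-sections at a
    horizontal plane, via shapely polygon union, clipped to the section."""
    from shapely.geometry import Point, box as shapely_box
    from shapely.ops import unary_union

    dz = centers[:, 2] - depth
    hit = np.abs(dz) < radii
    if not hit.any():
        return 0.0
    rc = np.sqrt(radii[hit] ** 2 - dz[hit] ** 2)
    disks = [
        Point(cx, cy).buffer(r, quad_segs=64)
        for (cx, cy), r in zip(centers[hit, :2], rc)
    ]
    section = shapely_box(0.0, 0.0, box[0], box[1])
    return unary_union(disks).intersection(section).area / (box[0] * box[1])


def simulate_nuclear_field(params: FieldParams, seed: int) -> NuclearField:
    """Place nuclei slab-by-slab to match the density profile in expectation.

    Slab counts are Poisson with mean ``density × area/10⁴``; centroids are
    uniform within each slab.  With ``allow_overlap=False`` placement uses
    hard-sphere rejection sampling with a bounded number of attempts per
    nucleus; unplaceable nuclei are reported in ``field.shortfall`` (never
    silently truncated).  With ``target_occupancy`` set, all radii are
    rescaled by a common factor found by bisection against an
    exact-geometry union-area oracle so the realized sectional coverage at
    the stated depth equals the target.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    lx, ly, _dmax = params.box
    area_factor = lx * ly / 1.0e4

    xs, ys, zs, rs, phases = [], [], [], [], []
    shortfall: dict = {}
    placed_x = np.empty(0)
    placed_y = np.empty(0)
    placed_z = np.empty(0)
    placed_r = np.empty(0)

    for slab_idx, (lo, hi, dens) in enumerate(params.density_profile):
        expected = dens * area_factor * 1.0  # density is per slab as listed
        n_slab = int(rng.poisson(expected)) if expected > 0 else 0
        missed = 0
        for _ in range(n_slab):
            r = float(_draw_positive(rng, params.radius_mean, params.radius_sd))
            ok = False
            for _attempt in range(params.max_attempts_per_nucleus):
                cx = rng.uniform(0.0, lx)
                cy = rng.uniform(0.0, ly)
                cz = rng.uniform(lo, min(hi, params.box[2]))
                if params.allow_overlap or placed_x.size == 0:
                    ok = True
                else:
                    d2 = (
                        (placed_x - cx) ** 2
                        + (placed_y - cy) ** 2
                        + (placed_z - cz) ** 2
                    )
                    ok = bool(np.all(d2 >= (placed_r + r) ** 2))
                if ok:
                    break
            if not ok:
                missed += 1
                continue
            xs.append(cx)
            ys.append(cy)
            zs.append(cz)
            rs.append(r)
            frac = _g1_fraction(params, cz)
            phases.append(PHASE_G1 if rng.random() < frac else PHASE_SG2)
            if not params.allow_overlap:
                placed_x = np.append(placed_x, cx)
                placed_y = np.append(placed_y, cy)
                placed_z = np.append(placed_z, cz)
                placed_r = np.append(placed_r, r)
        if missed:
            shortfall[slab_idx] = missed

    centers = np.column_stack([xs, ys, zs]) if xs else np.empty((0, 3))
    radii = np.asarray(rs, dtype=float)

    if params.target_occupancy is not None and centers.size:
        depth_cal, target = params.target_occupancy

        def coverage(scale: float) -> float:
            return _union_coverage_exact(centers, radii * scale, depth_cal, params.box)

        s_lo, s_hi = 0.05, 1.0
        while coverage(s_hi) < target:
            s_hi *= 1.5
            if s_hi > 20:
                raise ValidationError("target occupancy unreachable")
        for _ in range(40):
            mid = 0.5 * (s_lo + s_hi)
            if coverage(mid) < target:
                s_lo = mid
            else:
                s_hi = mid
            if s_hi - s_lo < 1e-4:
                break
        radii = radii * 0.5 * (s_lo + s_hi)

    df = pd.DataFrame(
        {
            "nucleus_id": [f"nuc{i:05d}" for i in range(len(radii))],
            "x_um": centers[:, 0] if len(radii) else [],
            "y_um": centers[:, 1] if len(radii) else [],
            "depth_um": centers[:, 2] if len(radii) else [],
            "radius_um": radii,
            "phase": phases,
        }
    )
    return NuclearField(df, params.box, shortfall)


# ---------------------------------------------------------------------------
# mitosis point patterns


@dataclass
class PointProcessParams:
    """Spatial point process of apical mitoses in a rectangular window."""

    kind: str = "csr"  # csr | cluster | regular
    intensity: float = 0.005  # events per μm²
    window: Tuple[float, float] = (100.0, 100.0)
    cluster_parent_intensity: float = 0.001
    cluster_mean_offspring: float = 5.0
    cluster_sigma: float = 2.0
    hardcore_radius: float = 8.0
    duration: float = 180.0
    max_placement_attempts: int = 10_000

    def validate(self) -> None:
        if self.kind not in {"csr", "cluster", "regular"}:
            raise ValidationError(f"unknown point-process kind {self.kind!r}")
        if self.intensity <= 0:
            raise ValidationError("intensity must be positive")
        if self.hardcore_radius < 0:
            raise ValidationError("hardcore_radius must be >= 0")
        if self.cluster_sigma < 0 or self.cluster_parent_intensity < 0:
            raise ValidationError("cluster parameters must be non-negative")
        if any(v <= 0 for v in self.window) or self.duration <= 0:
            raise ValidationError("window and duration must be positive")


def _simulate_points(params: PointProcessParams, rng) -> np.ndarray:
    w, h = params.window
    area = w * h
    if params.kind == "csr":
        n = int(rng.poisson(params.intensity * area))
        return rng.uniform([0.0, 0.0], [w, h], (n, 2)) if n else np.empty((0, 2))
    if params.kind == "cluster":
        # Thomas process: Poisson parents on a 4σ-extended window, Poisson
        # offspring with isotropic Gaussian displacement, clipped to window
        pad = 4.0 * params.cluster_sigma
        ext_area = (w + 2 * pad) * (h + 2 * pad)
        n_parents = int(rng.poisson(params.cluster_parent_intensity * ext_area))
        pts = []
        for _ in range(n_parents):
            px = rng.uniform(-pad, w + pad)
            py = rng.uniform(-pad, h + pad)
            n_off = int(rng.poisson(params.cluster_mean_offspring))
            if n_off:
                off = rng.normal([px, py], params.cluster_sigma, (n_off, 2))
                inside = (
                    (off[:, 0] >= 0) & (off[:, 0] <= w)
                    & (off[:, 1] >= 0) & (off[:, 1] <= h)
                )
                pts.append(off[inside])
        return np.vstack(pts) if pts else np.empty((0, 2))
    # regular: simple sequential inhibition targeting a Poisson count
    n_target = int(rng.poisson(params.intensity * area))
    r2 = params.hardcore_radius ** 2
    accepted: List[np.ndarray] = []
    attempts = 0
    while len(accepted) < n_target and attempts < params.max_placement_attempts:
        attempts += 1
        cand = rng.uniform([0.0, 0.0], [w, h])
        if accepted and r2 > 0:
            arr = np.asarray(accepted)
            if np.any(((arr - cand) ** 2).sum(axis=1) < r2):
                continue
        accepted.append(cand)
    return np.asarray(accepted) if accepted else np.empty((0, 2))


def simulate_mitosis_pattern(params: PointProcessParams, seed: int) -> EventPattern:
    """Simulate mitoses as a marked planar point process.

    ``csr`` is a homogeneous Poisson process; ``cluster`` a Thomas
    parent/offspring process; ``regular`` a hard-core pattern built by
    sequential inhibition (no two events closer than ``hardcore_radius``;
    if the target count cannot be packed, fewer events are placed).  Event
    times are uniform on [0, duration].
    """
    params.validate()
    rng = np.random.default_rng(seed)
    pts = _simulate_points(params, rng)
    times = rng.uniform(0.0, params.duration, len(pts))
    df = pd.DataFrame(
        {
            "event_id": [f"ev{i:05d}" for i in range(len(pts))],
            "x_um": pts[:, 0] if len(pts) else [],
            "y_um": pts[:, 1] if len(pts) else [],
            "t_min": times,
        }
    )
    return EventPattern(df, window=params.window, cumulation_span=params.duration)


# ---------------------------------------------------------------------------
# pulse-chase cohort


@dataclass
class PulseChaseParams:
    """Two-component depth mixture of labeled nuclei.

    A pulse label marks S-phase nuclei; after a short chase a fraction
    (``g2_fraction``) has exited S and migrated apically (G2-like
    component), the remainder is still in S (S-like component).  Depths are
    Gaussian per component, clipped to [0, ne_thickness].
    """

    n_cells: int = 1000
    s_phase_depth: Tuple[float, float] = (70.9, 12.0)  # (mean, sd) μm
    g2_fraction: float = 0.33
    g2_depth: Tuple[float, float] = (28.0, 8.0)
    ne_thickness: float = 92.6

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ValidationError("n_cells must be >= 1")
        if not (0.0 <= self.g2_fraction <= 1.0):
            raise ValidationError("g2_fraction must lie in [0, 1]")
        if self.ne_thickness <= 0:
            raise ValidationError("ne_thickness must be positive")
        for mean, sd in (self.s_phase_depth, self.g2_depth):
            if sd < 0:
                raise ValidationError("depth sd must be non-negative")

    @property
    def mixture_mean(self) -> float:
        """Planted mixture mean depth, ignoring boundary clipping."""
        return (
            self.g2_fraction * self.g2_depth[0]
            + (1.0 - self.g2_fraction) * self.s_phase_depth[0]
        )


@dataclass
class PulseChaseSimulation:
    cohort: LabeledCohort
    component: np.ndarray  # "S" or "G2" per cell
    params: PulseChaseParams
    seed: int


def simulate_pulse_chase(
    params: PulseChaseParams, seed: int, group: str = "cohort"
) -> PulseChaseSimulation:
    params.validate()
    rng = np.random.default_rng(seed)
    n = params.n_cells
    is_g2 = rng.random(n) < params.g2_fraction
    depths = np.where(
        is_g2,
        rng.normal(params.g2_depth[0], params.g2_depth[1], n),
        rng.normal(params.s_phase_depth[0], params.s_phase_depth[1], n),
    )
    depths = np.clip(depths, 0.0, params.ne_thickness)
    cohort = LabeledCohort(depths, group, params.ne_thickness)
    component = np.where(is_g2, "G2", "S")
    return PulseChaseSimulation(cohort, component, params, seed)


# ---------------------------------------------------------------------------
# presets: the study conditions at E11–E13

#: Apical-run parameters per embryonic day (distances/durations/pause
#: statistics as printed for each stage; per-pause sd is not reported per
#: event and is set to a plausible 6 min spread).
APICAL_RUN_PRESETS = {
    "E11": ApicalRunParams(
        mean_distance=42.3, sd_distance=9.6,
        mean_duration=95.7, sd_duration=41.9,
        pause_rate=0.2, pause_mean_duration=18.5,
        pause_depth_range=(18.0, 28.0),
    ),
    "E12": ApicalRunParams(
        mean_distance=44.9, sd_distance=10.5,
        mean_duration=154.6, sd_duration=62.5,
        pause_rate=0.7, pause_mean_duration=20.0,
        pause_depth_range=(18.0, 28.0),
    ),
    "E13": ApicalRunParams(
        mean_distance=46.5, sd_distance=11.3,
        mean_duration=180.9, sd_duration=90.9,
        pause_rate=1.0, pause_mean_duration=21.5,
        pause_depth_range=(22.0, 33.0),
    ),
}

#: Lateral diffusion coefficients (μm²/min) by stage and section depth.
DRIFT_D_PRESETS = {
    "E11_30um": 0.175,
    "E12_30um": 0.093,
    "E13_30um": 0.065,
    "E11_60um": 0.129,
    "E12_60um": 0.081,
    "E13_60um": 0.065,
}


def _bell_profile(anchors, dmax: float = 100.0, slab: float = 2.0):
    """Piecewise-linear density profile through (depth, density) anchors."""
    depths = np.arange(0.0, dmax, slab)
    ad = np.array([a[0] for a in anchors])
    av = np.array([a[1] for a in anchors])
    centers = depths + slab / 2
    dens = np.interp(centers, ad, av)
    return [(float(lo), float(lo + slab), float(d)) for lo, d in zip(depths, dens)]


#: Depth-density profiles (nuclei per 100×100 μm per 2-μm slab).  The 20-
#: and 30-μm anchors are the measured stage values; the rest of the bell
#: shape is illustrative of a pseudostratified depth profile.
DENSITY_PROFILE_PRESETS = {
    "E11": _bell_profile(
        [(0, 90), (10, 130), (17, 155.3), (23, 155.3), (27, 179.0), (33, 179.0),
         (45, 165), (65, 130), (99, 80)]
    ),
    "E13": _bell_profile(
        [(0, 95), (10, 160), (17, 204.7), (23, 204.7), (27, 219.2), (33, 219.2),
         (45, 195), (65, 150), (99, 90)]
    ),
}

#: Phase composition by depth: fraction of G1-like nuclei per depth band
#: (the 30-μm band carries the measured stage value).
PHASE_PROPORTION_PRESETS = {
    "E11": [(0.0, 10.0, 0.15), (10.0, 20.0, 0.5), (20.0, 40.0, 0.84),
            (40.0, 100.0, 0.9)],
    "E13": [(0.0, 10.0, 0.15), (10.0, 20.0, 0.5), (20.0, 40.0, 0.796),
            (40.0, 100.0, 0.9)],
}

#: Pulse-chase mixtures: the control mixture mean is 56.7 μm; the
#: overproliferation (Shh-OE-like) mixture mean is 62.4 μm with the G2-like
#: component suppressed and the S-like component shifted basally in a
#: thicker neuroepithelium.
PULSE_CHASE_PRESETS = {
    "control": PulseChaseParams(
        n_cells=1000, s_phase_depth=(70.9, 12.0), g2_fraction=0.33,
        g2_depth=(28.0, 8.0), ne_thickness=92.6,
    ),
    "shh_oe": PulseChaseParams(
        n_cells=1000, s_phase_depth=(70.5, 20.0), g2_fraction=0.20,
        g2_depth=(30.0, 9.0), ne_thickness=126.7,
    ),
}
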