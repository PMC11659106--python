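"""Per-run apical-nucleokinesis metrics and pause detection.

A "run" is the G2-phase movement of a nucleus from its onset depth to the
apical surface (depth 0).  Onset is recognized as the first frame interval
whose apicalward (depth-decreasing) speed reaches 10% of the trajectory's
maximum apicalward frame speed, with commitment: the nucleus subsequently
reaches the apical surface without returning above its onset depth.
Arrival is the first sample within ``arrival_tolerance`` (default 2 μm,
about one nuclear radius) of the apical surface.

A pause is a maximal block of consecutive frame intervals, strictly
between onset and arrival, whose 3D frame speed falls below 10% of the
run's own maximum frame speed.  The threshold is per-trajectory, not per
cohort, and the minimum observable pause is one sampling interval.

Internal speed unit is μm/hr throughout: distances and durations are the
primary quantities, and μm/hr is the unit under which the cohort means are
mutually consistent (e.g. ~42 μm in ~96 min ≈ 27 μm/hr).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .core import NuclearTrajectory, ValidationError

__all__ = [
    "PauseEvent",
    "ApicalRunMetrics",
    "NoRunError",
    "frame_speeds",
    "detect_onset",
    "detect_pauses",
    "compute_run_metrics",
    "cohort_metrics",
    "cohort_summary",
]

DEFAULT_THRESHOLD_FRACTION = 0.1
DEFAULT_ARRIVAL_TOLERANCE = 2.0  # μm


class NoRunError(ValidationError):
    """The trajectory contains no detectable apical run."""


@dataclass
class PauseEvent:
    start: float  # min
    end: float  # min
    depth: float  # mean depth over the pause samples, μm

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class ApicalRunMetrics:
    track_id: str
    onset_time: float
    arrival_time: float
    total_distance: float  # μm, 3D path length over frames
    average_speed: float  # μm/hr
    max_speed: float  # μm/hr over one sampling interval
    pauses: List[PauseEvent] = field(default_factory=list)

    @property
    def duration(self) -> float:
        return self.arrival_time - self.onset_time

    @property
    def n_pauses(self) -> int:
        return len(self.pauses)

    @property
    def total_pause_time(self) -> float:
        return sum(p.duration for p in self.pauses)


def frame_speeds(traj: NuclearTrajectory) -> np.ndarray:
    """3D frame-to-frame speeds in μm/hr, timestamped at the interval end.

    Returns an (n_samples − 1, 2) array of ``(t_end, speed)`` rows.
    """
    if traj.n_samples < 2:
        raise ValidationError(
            f"track {traj.track_id!r}: need >= 2 samples for frame speeds"
        )
    pos = traj.positions("xyz")
    disp = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    dt = traj.sampling_interval
    return np.column_stack([traj.t[1:], disp / dt * 60.0])


def _apicalward_speeds(traj: NuclearTrajectory) -> np.ndarray:
    """Depth-decreasing speed per frame interval, μm/min (positive = apical)."""
    return -np.diff(traj.depth) / traj.sampling_interval


def detect_onset(
    traj: NuclearTrajectory,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    arrival_tolerance: float = DEFAULT_ARRIVAL_TOLERANCE,
) -> float:
    """Return the onset time of the apical run (min).

    Raises :class:`NoRunError` when the nucleus never reaches the apical
    surface or no frame satisfies the criterion.
    """
    idx = _onset_index(traj, threshold_fraction, arrival_tolerance)
    return float(traj.t[idx])


def _arrival_index(traj: NuclearTrajectory, arrival_tolerance: float) -> int:
    hits = np.nonzero(traj.depth <= arrival_tolerance)[0]
    if hits.size == 0:
        raise NoRunError(
            f"track {traj.track_id!r}: nucleus never reaches the apical "
            f"surface (min depth {traj.depth.min():.2f} μm)"
        )
    return int(hits[0])


def _onset_index(
    traj: NuclearTrajectory,
    threshold_fraction: float,
    arrival_tolerance: float,
) -> int:
    if traj.n_samples < 2:
        raise NoRunError(f"track {traj.track_id!r}: too short")
    ia = _arrival_index(traj, arrival_tolerance)
    if ia == 0:
        raise NoRunError(
            f"track {traj.track_id!r}: already apical at the first sample"
        )
    apical = _apicalward_speeds(traj)[:ia]
    vmax = apical.max()
    if vmax <= 0:
        raise NoRunError(f"track {traj.track_id!r}: no apicalward motion")
    threshold = threshold_fraction * vmax
    depth = traj.depth
    for i in np.nonzero(apical >= threshold)[0]:
        # commitment: never return above the onset depth before arrival
        if np.all(depth[i + 1 : ia + 1] <= depth[i] + 1e-9):
            return int(i)
    raise NoRunError(f"track {traj.track_id!r}: no committed onset frame")


def detect_pauses(
    traj: NuclearTrajectory,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    arrival_tolerance: float = DEFAULT_ARRIVAL_TOLERANCE,
) -> List[PauseEvent]:
    """Detect pauses as maximal sub-threshold frame blocks within the run.

    Frame intervals eligible for pausing lie strictly between onset and
    arrival: the onset interval itself and the interval ending at the
    arrival sample are excluded, so partial first/last frames cannot
    register as spurious pauses.
    """
    i0 = _onset_index(traj, threshold_fraction, arrival_tolerance)
    ia = _arrival_index(traj, arrival_tolerance)
    return _pauses_between(traj, i0, ia, threshold_fraction)


def _pauses_between(
    traj: NuclearTrajectory, i0: int, ia: int, threshold_fraction: float
) -> List[PauseEvent]:
    speeds = frame_speeds(traj)[:, 1]
    run_speeds = speeds[i0:ia]
    if run_speeds.size == 0:
        return []
    threshold = threshold_fraction * run_speeds.max()
    pauses: List[PauseEvent] = []
    start: Optional[int] = None
    # eligible frame intervals: strictly after the onset interval, strictly
    # before the interval that ends at the arrival sample
    for i in range(i0 + 1, ia - 1):
        if speeds[i] < threshold:
            if start is None:
                start = i
        elif start is not None:
            pauses.append(_make_pause(traj, start, i))
            start = None
    if start is not None:
        pauses.append(_make_pause(traj, start, ia - 1))
    return pauses


def _make_pause(traj: NuclearTrajectory, first: int, stop: int) -> PauseEvent:
    """Build a PauseEvent from frame intervals [first, stop)."""
    return PauseEvent(
        start=float(traj.t[first]),
        end=float(traj.t[stop]),
        depth=float(traj.depth[first : stop + 1].mean()),
    )


def compute_run_metrics(
    traj: NuclearTrajectory,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    arrival_tolerance: float = DEFAULT_ARRIVAL_TOLERANCE,
) -> ApicalRunMetrics:
    """Compute the per-run metric set.

    ``total_distance`` is the 3D path length summed over frames from onset
    to arrival (≥ the net apicobasal displacement); ``average_speed`` is
    total distance over duration, in μm/hr; ``max_speed`` is the largest
    single-frame speed of the run.
    """
    i0 = _onset_index(traj, threshold_fraction, arrival_tolerance)
    ia = _arrival_index(traj, arrival_tolerance)
    pos = traj.positions("xyz")
    disp = np.linalg.norm(np.diff(pos[i0 : ia + 1], axis=0), axis=1)
    total_distance = float(disp.sum())
    duration = float(traj.t[ia] - traj.t[i0])
    speeds = frame_speeds(traj)[i0:ia, 1]
    return ApicalRunMetrics(
        track_id=traj.track_id,
        onset_time=float(traj.t[i0]),
        arrival_time=float(traj.t[ia]),
        total_distance=total_distance,
        average_speed=total_distance / duration * 60.0,
        max_speed=float(speeds.max()),
        pauses=_pauses_between(traj, i0, ia, threshold_fraction),
    )


def cohort_metrics(
    trajectories: Sequence[NuclearTrajectory],
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    arrival_tolerance: float = DEFAULT_ARRIVAL_TOLERANCE,
) -> pd.DataFrame:
    """Per-run metrics table for a cohort; no-run trajectories are excluded
    and recorded with their reason in the ``excluded`` attribute."""
    rows = []
    excluded = []
    for traj in trajectories:
        try:
            m = compute_run_metrics(traj, threshold_fraction, arrival_tolerance)
        except NoRunError as err:
            excluded.append({"track_id": traj.track_id, "reason": str(err)})
            continue
        rows.append(
            {
                "track_id": m.track_id,
                "onset_time_min": m.onset_time,
                "arrival_time_min": m.arrival_time,
                "total_distance_um": m.total_distance,
                "duration_min": m.duration,
                "average_speed_um_hr": m.average_speed,
                "max_speed_um_hr": m.max_speed,
                "n_pauses": m.n_pauses,
                "total_pause_min": m.total_pause_time,
                "mean_pause_depth_um": (
                    float(np.mean([p.depth for p in m.pauses])) if m.pauses else np.nan
                ),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "track_id", "onset_time_min", "arrival_time_min",
            "total_distance_um", "duration_min", "average_speed_um_hr",
            "max_speed_um_hr", "n_pauses", "total_pause_min",
            "mean_pause_depth_um",
        ],
    )
    df.attrs["excluded"] = excluded
    return df


def cohort_summary(metrics: pd.DataFrame) -> pd.DataFrame:
    """Mean/sd/se/n summary over the numeric per-run metrics."""
    numeric = metrics.drop(columns=["track_id"], errors="ignore")
    n = len(numeric)
    out = pd.DataFrame(
        {
            "mean": numeric.mean(),
            "sd": numeric.std(ddof=1),
            "se": numeric.std(ddof=1) / np.sqrt(max(n, 1)),
            "n": n,
        }
    )
    out.index.name = "metric"
    return out
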