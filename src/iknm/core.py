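"""Shared data containers for the IKNM analysis pipeline.

Coordinate conventions, enforced at every boundary:

* ``depth`` is measured in μm from the apical surface, apical→basal,
  so 0 is the apical (ventricular) surface and larger values are more basal.
* Lateral ``x``/``y`` are in μm with the origin at the observation-window
  corner.
* All times are in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "LoadError",
    "NuclearTrajectory",
    "NuclearField",
    "EventPattern",
    "LabeledCohort",
    "PHASE_G1",
    "PHASE_SG2",
]

#: phase labels used for static nuclear fields (Fucci-style dichotomy:
#: G1-like vs S/G2-like)
PHASE_G1 = "G1"
PHASE_SG2 = "SG2"

_TIME_TOL = 1e-6


class ValidationError(ValueError):
    """Raised when inputs violate a documented invariant or precondition."""


class LoadError(ValidationError):
    """Raised when an input file cannot be parsed into a valid container."""


@dataclass
class NuclearTrajectory:
    """Time-ordered centroid samples of a single nucleus.

    Samples must be strictly increasing in time and uniformly spaced
    (within 1e-6 min); depth is non-negative.
    """

    track_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    depth: np.ndarray
    phase: Optional[str] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        n = self.t.size
        if n < 1:
            raise ValidationError(f"track {self.track_id!r}: no samples")
        if not (self.x.size == self.y.size == self.depth.size == n):
            raise ValidationError(
                f"track {self.track_id!r}: coordinate arrays have unequal length"
            )
        if n >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValidationError(
                    f"track {self.track_id!r}: time not strictly increasing"
                )
            if np.max(np.abs(dt - dt[0])) > _TIME_TOL * max(1.0, dt[0]):
                raise ValidationError(
                    f"track {self.track_id!r}: non-uniform sampling interval"
                )
        if np.any(self.depth < -_TIME_TOL):
            raise ValidationError(f"track {self.track_id!r}: negative depth")
        self.depth = np.maximum(self.depth, 0.0)

    @property
    def n_samples(self) -> int:
        return int(self.t.size)

    @property
    def sampling_interval(self) -> float:
        """Sampling interval in minutes (requires ≥ 2 samples)."""
        if self.t.size < 2:
            raise ValidationError(
                f"track {self.track_id!r}: sampling interval undefined for "
                "a single sample"
            )
        return float(self.t[1] - self.t[0])

    def positions(self, dims: str = "xyz") -> np.ndarray:
        """Sample positions as an (n, d) array.

        ``dims`` is ``"xy"`` (lateral only) or ``"xyz"`` (lateral + depth).
        """
        if dims == "xy":
            return np.column_stack([self.x, self.y])
        if dims == "xyz":
            return np.column_stack([self.x, self.y, self.depth])
        raise ValidationError(f"unknown dims {dims!r}")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "track_id": self.track_id,
                "t_min": self.t,
                "x_um": self.x,
                "y_um": self.y,
                "depth_um": self.depth,
            }
        )
        df["phase"] = self.phase if self.phase is not None else ""
        return df


@dataclass
class NuclearField:
    """Static set of spherical nuclei inside a rectangular box.

    ``nuclei`` is a DataFrame with columns ``nucleus_id, x_um, y_um,
    depth_um, radius_um, phase``; ``box`` is (Lx, Ly, depth_max) in μm.
    ``shortfall`` maps slab index -> number of nuclei that could not be
    placed under the hard-sphere constraint (empty when overlap is allowed).
    """

    nuclei: pd.DataFrame
    box: tuple
    shortfall: dict = field(default_factory=dict)

    _COLUMNS = ["nucleus_id", "x_um", "y_um", "depth_um", "radius_um", "phase"]

    def __post_init__(self) -> None:
        if len(self.box) != 3 or any(v <= 0 for v in self.box):
            raise ValidationError(f"invalid box {self.box!r}")
        missing = [c for c in self._COLUMNS if c not in self.nuclei.columns]
        if missing:
            raise ValidationError(f"field missing columns {missing}")
        lx, ly, dmax = self.box
        n = self.nuclei
        if len(n):
            if (n["radius_um"] <= 0).any():
                raise ValidationError("non-positive nuclear radius")
            inside = (
                n["x_um"].between(0, lx)
                & n["y_um"].between(0, ly)
                & n["depth_um"].between(0, dmax)
            )
            if not inside.all():
                raise ValidationError("nuclear centroid outside box")

    @property
    def n_nuclei(self) -> int:
        return int(len(self.nuclei))

    @property
    def section_area_um2(self) -> float:
        return float(self.box[0] * self.box[1])


@dataclass
class EventPattern:
    """Marked 2D point pattern of mitoses in a rectangular window.

    ``events`` is a DataFrame with columns ``event_id, x_um, y_um, t_min``.
    """

    events: pd.DataFrame
    window: tuple = (100.0, 100.0)
    cumulation_span: float = 180.0
    section_depth: float = 5.0

    _COLUMNS = ["event_id", "x_um", "y_um", "t_min"]

    def __post_init__(self) -> None:
        if len(self.window) != 2 or any(v <= 0 for v in self.window):
            raise ValidationError(f"invalid window {self.window!r}")
        missing = [c for c in self._COLUMNS if c not in self.events.columns]
        if missing:
            raise ValidationError(f"event table missing columns {missing}")
        w, h = self.window
        e = self.events
        if len(e):
            if not (e["x_um"].between(0, w) & e["y_um"].between(0, h)).all():
                raise ValidationError("event outside window")
            if ((e["t_min"] < 0) | (e["t_min"] > self.cumulation_span)).any():
                raise ValidationError("event time outside cumulation span")

    @property
    def n_events(self) -> int:
        return int(len(self.events))

    @property
    def area(self) -> float:
        return float(self.window[0] * self.window[1])

    def coordinates(self) -> np.ndarray:
        return self.events[["x_um", "y_um"]].to_numpy(dtype=float)


@dataclass
class LabeledCohort:
    """Depths of labeled (e.g. BrdU+) nuclei for one experimental group."""

    depths: np.ndarray
    group: str
    ne_thickness: float

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        if self.ne_thickness <= 0:
            raise ValidationError("ne_thickness must be positive")
        if self.depths.size and (
            np.any(self.depths < 0) or np.any(self.depths > self.ne_thickness)
        ):
            raise ValidationError(
                f"group {self.group!r}: depth outside [0, ne_thickness]"
            )

    @property
    def n_cells(self) -> int:
        return int(self.depths.size)


def as_trajectory_table(trajectories: Sequence[NuclearTrajectory]) -> pd.DataFrame:
    """Concatenate trajectories into the canonical long-format table."""
    if not trajectories:
        return pd.DataFrame(
            columns=["track_id", "t_min", "x_um", "y_um", "depth_um", "phase"]
        )
    return pd.concat([tr.to_frame() for tr in trajectories], ignore_index=True)
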