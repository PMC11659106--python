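"""CSV readers and writers for every pipeline table.

Formats (UTF-8, dot decimal, header required):

* trajectory CSV: ``track_id,t_min,x_um,y_um,depth_um[,phase]``
* field CSV:      ``nucleus_id,x_um,y_um,depth_um,radius_um,phase``
* event CSV:      ``event_id,x_um,y_um,t_min``
* cohort CSV:     ``depth_um,group``

Simulation writers drop a ground-truth sidecar next to the data file
(same basename, suffix ``.truth.json``) holding the planted parameters and
per-item truth, so downstream recovery is always auditable.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from .core import (
    EventPattern,
    LabeledCohort,
    LoadError,
    NuclearField,
    NuclearTrajectory,
    ValidationError,
    as_trajectory_table,
)

__all__ = [
    "read_trajectories",
    "write_trajectories",
    "read_field",
    "write_field",
    "read_events",
    "write_events",
    "read_cohorts",
    "write_cohort",
    "write_truth_sidecar",
]

_TRAJ_COLUMNS = ["track_id", "t_min", "x_um", "y_um", "depth_um"]


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise LoadError(f"{path}: missing columns {missing}")


def read_trajectories(path) -> List[NuclearTrajectory]:
    """Load and validate a trajectory CSV, grouped by track and ordered by
    time.  Malformed tracks are rejected with the offending track id and
    1-based file line number."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, _TRAJ_COLUMNS, path)
    for col in ("t_min", "x_um", "y_um", "depth_um"):
        if len(df) and not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            line = int(bad[0]) + 2 if len(bad) else "?"
            raise LoadError(f"{path}: non-numeric {col} at line {line}")
    trajectories = []
    for track_id, group in df.groupby("track_id", sort=False):
        dup = group["t_min"].duplicated()
        if dup.any():
            line = int(group.index[dup][0]) + 2
            raise LoadError(
                f"{path}: duplicated timestamp in track {track_id!r} at line {line}"
            )
        g = group.sort_values("t_min")
        phase = None
        if "phase" in g.columns:
            values = g["phase"].dropna().astype(str)
            values = values[values != ""]
            if len(values):
                phase = values.iloc[0]
        try:
            trajectories.append(
                NuclearTrajectory(
                    str(track_id),
                    g["t_min"].to_numpy(float),
                    g["x_um"].to_numpy(float),
                    g["y_um"].to_numpy(float),
                    g["depth_um"].to_numpy(float),
                    phase=phase,
                )
            )
        except ValidationError as err:
            first_line = int(g.index[0]) + 2
            raise LoadError(f"{path} (near line {first_line}): {err}") from err
    return trajectories


def write_trajectories(trajectories, path, truth: Optional[dict] = None) -> None:
    path = Path(path)
    as_trajectory_table(trajectories).to_csv(path, index=False)
    if truth is not None:
        write_truth_sidecar(path, truth)


def read_field(path, box) -> NuclearField:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, NuclearField._COLUMNS[:5], path)
    if "phase" not in df.columns:
        df["phase"] = ""
    try:
        return NuclearField(df, tuple(box))
    except ValidationError as err:
        raise LoadError(f"{path}: {err}") from err


def write_field(field: NuclearField, path, truth: Optional[dict] = None) -> None:
    path = Path(path)
    field.nuclei.to_csv(path, index=False)
    if truth is not None:
        write_truth_sidecar(path, truth)


def read_events(path, window=(100.0, 100.0), span: float = 180.0) -> EventPattern:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["x_um", "y_um", "t_min"], path)
    if "event_id" not in df.columns:
        df.insert(0, "event_id", [f"ev{i:05d}" for i in range(len(df))])
    try:
        return EventPattern(df, window=tuple(window), cumulation_span=span)
    except ValidationError as err:
        raise LoadError(f"{path}: {err}") from err


def write_events(pattern: EventPattern, path, truth: Optional[dict] = None) -> None:
    path = Path(path)
    pattern.events.to_csv(path, index=False)
    if truth is not None:
        write_truth_sidecar(path, truth)


def read_cohorts(path, ne_thickness: Optional[float] = None) -> List[LabeledCohort]:
    """Read a cohort CSV (depth_um, group) into one cohort per group.

    Without an explicit ``ne_thickness`` the maximum observed depth
    (rounded up to 10 μm) is used."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["depth_um", "group"], path)
    cohorts = []
    for group, sub in df.groupby("group", sort=False):
        depths = sub["depth_um"].to_numpy(float)
        thickness = (
            ne_thickness
            if ne_thickness is not None
            else max(float(np.ceil(depths.max() / 10.0) * 10.0), 10.0)
        )
        try:
            cohorts.append(LabeledCohort(depths, str(group), thickness))
        except ValidationError as err:
            raise LoadError(f"{path}: {err}") from err
    return cohorts


def write_cohort(cohorts, path, truth: Optional[dict] = None) -> None:
    path = Path(path)
    frames = [
        pd.DataFrame({"depth_um": c.depths, "group": c.group}) for c in cohorts
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    if truth is not None:
        write_truth_sidecar(path, truth)


class _TruthEncoder(json.JSONEncoder):
    def default(self, o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, np.generic):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_truth_sidecar(data_path, truth: dict) -> Path:
    """Write ``<data_path>.truth.json`` next to a simulated data file."""
    sidecar = Path(str(data_path) + ".truth.json")
    sidecar.write_text(json.dumps(truth, cls=_TruthEncoder, indent=1))
    return sidecar
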