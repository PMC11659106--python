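"""Umbrella pipeline: run the requested analysis stages and write outputs.

Each stage reads a canonical CSV, runs its analysis at the configured
constants, and writes result CSVs plus a machine-readable run manifest
(config hash, seed, package version, per-stage record counts).  Outputs
are deterministic for a fixed config: running twice produces byte-identical
files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict

import numpy as np
import pandas as pd

from . import __version__
from .config import AnalysisConfig
from .core import ValidationError
from . import io as iknm_io
from . import density as density_mod
from . import msd as msd_mod
from . import pulsechase as pc_mod
from . import ripley as ripley_mod
from . import stats as stats_mod
from . import synthetic as syn
from .trajectory import cohort_metrics, cohort_summary

__all__ = ["run_pipeline", "generate_demo_inputs", "STAGES"]

STAGES = ("trajectories", "msd", "ripley", "density", "pulsechase", "stats")


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


def _stage_trajectories(config, path, out_dir):
    trajs = iknm_io.read_trajectories(path)
    metrics = cohort_metrics(
        trajs,
        threshold_fraction=config.pause_threshold_fraction,
        arrival_tolerance=config.arrival_tolerance_um,
    )
    metrics.to_csv(out_dir / "run_metrics.csv", index=False)
    cohort_summary(metrics).to_csv(out_dir / "run_summary.csv")
    return {"records": int(len(metrics)),
            "excluded": len(metrics.attrs.get("excluded", []))}


def _stage_msd(config, path, out_dir):
    trajs = iknm_io.read_trajectories(path)
    curve = msd_mod.compute_msd(trajs, dims="xy")
    estimate = msd_mod.fit_diffusion(curve, config.msd_fit_window_min)
    curve.to_frame().to_csv(out_dir / "msd_curve.csv", index=False)
    pd.DataFrame(
        [{
            "D_um2_min": estimate.D,
            "slope_um2_min": estimate.slope,
            "intercept_um2": estimate.intercept,
            "stderr_D": estimate.stderr_D,
            "fit_window_min": estimate.fit_window,
            "n_lags": estimate.n_lags,
            "curvature_ratio": estimate.curvature_ratio,
            "superlinear": estimate.superlinear,
        }]
    ).to_csv(out_dir / "diffusion_estimate.csv", index=False)
    return {"records": int(curve.lags.size)}


def _stage_ripley(config, path, out_dir):
    pattern = iknm_io.read_events(
        path, window=config.window_um, span=config.ripley_span_min
    )
    result = ripley_mod.analyze_pattern(
        pattern,
        n_sims=config.ripley_nsims,
        seed=config.child_seed("ripley"),
    )
    result.to_frame().to_csv(out_dir / "k_function.csv", index=False)
    record = {
        "classification": result.classification,
        "n_events": result.n_events,
        "n_sims": result.n_sims,
        "correction": result.correction,
        "excursion": list(result.excursion) if result.excursion else None,
        "tie": result.tie,
        "seed": config.child_seed("ripley"),
    }
    (out_dir / "classification.json").write_text(json.dumps(record, indent=1))
    return {"records": result.n_events, "classification": result.classification}


def _stage_density(config, path, out_dir):
    # box inferred: lateral extent from the configured window, depth from
    # the deepest nucleus rounded up to a whole slab
    peek = pd.read_csv(path)
    dmax = (
        float(np.ceil(peek["depth_um"].max() / config.depth_bins_um))
        * config.depth_bins_um
        if len(peek)
        else config.depth_bins_um
    )
    box = (config.window_um[0], config.window_um[1], max(dmax, config.depth_bins_um))
    field = iknm_io.read_field(path, box)
    profile = density_mod.depth_profile(
        field, slab=config.depth_bins_um, with_occupancy=True
    )
    profile.to_csv(out_dir / "depth_profile.csv", index=False)
    return {"records": int(field.n_nuclei)}


def _stage_pulsechase(config, path, out_dir):
    cohorts = iknm_io.read_cohorts(path)
    hists = [pc_mod.brdu_histogram(c, config.pulse_bin_um) for c in cohorts]
    rows = []
    for h in hists:
        df = h.to_frame()
        df.insert(0, "group", h.group)
        rows.append(df)
    pd.concat(rows, ignore_index=True).to_csv(
        out_dir / "depth_histograms.csv", index=False
    )
    if len(hists) == 2:
        pc_mod.compare_bins(hists[0], hists[1]).to_csv(
            out_dir / "bin_tests.csv", index=False
        )
    return {"records": sum(h.n_cells for h in hists), "groups": len(hists)}


def _stage_stats(config, path, out_dir):
    df = pd.read_csv(path)
    if not {"value", "group"} <= set(df.columns):
        raise ValidationError(f"{path}: stats input needs columns value,group")
    groups = {
        str(name): sub["value"].to_numpy(float)
        for name, sub in df.groupby("group", sort=False)
    }
    stats_mod.auto_compare(groups).to_csv(out_dir / "group_tests.csv", index=False)
    return {"records": int(len(df)), "groups": len(groups)}


_STAGE_FUNCS = {
    "trajectories": _stage_trajectories,
    "msd": _stage_msd,
    "ripley": _stage_ripley,
    "density": _stage_density,
    "pulsechase": _stage_pulsechase,
    "stats": _stage_stats,
}


def run_pipeline(
    config: AnalysisConfig,
    inputs: Dict[str, str],
    out_dir,
) -> dict:
    """Execute the stages named in ``inputs`` (stage → input CSV path).

    Any stage failure aborts with a stage-named :class:`StageError`; the
    manifest flags partially written outputs.  Returns the manifest dict.
    """
    config.validate()
    unknown = set(inputs) - set(STAGES)
    if unknown:
        raise ValidationError(f"unknown stages: {sorted(unknown)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
        "complete": False,
    }
    try:
        for stage in STAGES:
            if stage not in inputs:
                continue
            stage_dir = out_dir / stage
            stage_dir.mkdir(exist_ok=True)
            try:
                manifest["stages"][stage] = _STAGE_FUNCS[stage](
                    config, inputs[stage], stage_dir
                )
            except Exception as err:
                raise StageError(f"stage {stage!r} failed: {err}") from err
        manifest["complete"] = True
    finally:
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def generate_demo_inputs(out_dir, seed: int = 0) -> Dict[str, str]:
    """Generate a small synthetic input set for every stage (demo / smoke)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) for s in ss.generate_state(5, dtype=np.uint32) % (2 ** 31)]

    sim = syn.simulate_apical_runs(syn.APICAL_RUN_PRESETS["E11"], n=40, seed=seeds[0])
    traj_path = out_dir / "runs.csv"
    iknm_io.write_trajectories(
        sim.trajectories, traj_path,
        truth={"params": sim.params, "runs": sim.truth},
    )

    drift = syn.simulate_lateral_drift(
        syn.DriftParams(diffusion_coefficient=syn.DRIFT_D_PRESETS["E11_30um"],
                        n_tracks=60),
        seed=seeds[1],
    )
    drift_path = out_dir / "drift.csv"
    iknm_io.write_trajectories(
        drift.trajectories, drift_path, truth={"params": drift.params}
    )

    field = syn.simulate_nuclear_field(
        syn.FieldParams(
            density_profile=syn.DENSITY_PROFILE_PRESETS["E11"][:20],
            phase_proportions_by_depth=syn.PHASE_PROPORTION_PRESETS["E11"],
            box=(100.0, 100.0, 40.0),
        ),
        seed=seeds[2],
    )
    field_path = out_dir / "field.csv"
    iknm_io.write_field(field, field_path, truth={"shortfall": field.shortfall})

    pattern = syn.simulate_mitosis_pattern(
        syn.PointProcessParams(kind="csr", intensity=0.005), seed=seeds[3]
    )
    events_path = out_dir / "events.csv"
    iknm_io.write_events(pattern, events_path)

    control = syn.simulate_pulse_chase(
        syn.PULSE_CHASE_PRESETS["control"], seed=seeds[4], group="control"
    )
    cohort_path = out_dir / "cohort.csv"
    iknm_io.write_cohort([control.cohort], cohort_path)

    sim13 = syn.simulate_apical_runs(
        syn.APICAL_RUN_PRESETS["E13"], n=30, seed=seeds[0] + 1
    )
    stats_path = out_dir / "stats.csv"
    pd.concat(
        [
            pd.DataFrame(
                {"value": cohort_metrics(sim.trajectories)["duration_min"],
                 "group": "E11"}
            ),
            pd.DataFrame(
                {"value": cohort_metrics(sim13.trajectories)["duration_min"],
                 "group": "E13"}
            ),
        ],
        ignore_index=True,
    ).to_csv(stats_path, index=False)

    return {
        "trajectories": str(traj_path),
        "msd": str(drift_path),
        "ripley": str(events_path),
        "density": str(field_path),
        "pulsechase": str(cohort_path),
        "stats": str(stats_path),
    }
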