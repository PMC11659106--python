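"""Trajectory metrics: frame speeds, onset/pause detection, run metrics."""

import numpy as np
import pytest

from iknm.core import NuclearTrajectory, ValidationError
from iknm.trajectory import (
    NoRunError,
    cohort_metrics,
    compute_run_metrics,
    detect_onset,
    detect_pauses,
    frame_speeds,
)


def _traj(depths, dt=10.0, x=None, y=None, track="t"):
    depths = np.asarray(depths, float)
    t = np.arange(depths.size) * dt
    x = np.zeros_like(depths) if x is None else np.asarray(x, float)
    y = np.zeros_like(depths) if y is None else np.asarray(y, float)
    return NuclearTrajectory(track, t, x, y, depths)


# ---------------------------------------------------------------------------
# frame speeds


@pytest.mark.parametrize(
    "build, expected",
    [
        (lambda: _traj([10, 10, 10, 10]), [0.0, 0.0, 0.0]),
        (lambda: _traj([20, 15, 10, 5, 0]), [30.0] * 4),
        (lambda: _traj([5, 5], x=[0, 3], y=[0, 4]), [30.0]),  # 3-4-5 triangle
    ],
    ids=["stationary", "constant-descent", "pythagorean"],
)
def test_frame_speeds_closed_forms(build, expected):
    speeds = frame_speeds(build())
    np.testing.assert_allclose(speeds[:, 1], expected, atol=1e-12)
    np.testing.assert_allclose(speeds[:, 0], (np.arange(len(expected)) + 1) * 10.0)


def test_frame_speeds_needs_two_samples():
    with pytest.raises(ValidationError):
        frame_speeds(NuclearTrajectory("one", [0.0], [0.0], [0.0], [5.0]))


# ---------------------------------------------------------------------------
# onset


def test_onset_detected_at_step_change():
    # stationary for 30 min, then 4 μm/frame apicalward
    depths = [20, 20, 20, 20, 16, 12, 8, 4, 0]
    assert detect_onset(_traj(depths)) == 30.0


def test_purely_basalward_trajectory_is_no_run():
    with pytest.raises(NoRunError):
        detect_onset(_traj([5, 10, 15, 20, 25]))


def test_never_arriving_trajectory_is_no_run():
    with pytest.raises(NoRunError):
        detect_onset(_traj([40, 35, 30, 25, 20]))


def test_onset_matches_planted_onset_on_simulated_runs(e11_runs):
    hits = sum(
        detect_onset(traj) == truth.onset_time
        for traj, truth in zip(e11_runs.trajectories, e11_runs.truth)
    )
    assert hits / len(e11_runs.truth) >= 0.95


# ---------------------------------------------------------------------------
# pauses


def test_constant_speed_run_has_no_pauses(constant_run):
    assert detect_pauses(constant_run) == []


def test_single_planted_stop_recovered_exactly():
    # 2 stationary frames at 25 μm inside a constant 5 μm/frame descent
    depths = [45, 40, 35, 30, 25, 25, 25, 20, 15, 10, 5, 0]
    pauses = detect_pauses(_traj(depths))
    assert len(pauses) == 1
    assert pauses[0].duration == 20.0
    assert pauses[0].depth == pytest.approx(25.0)


def test_pause_count_and_duration_match_planted_ground_truth(e13_runs):
    """Planted pauses are whole-frame stops, so detection recovers the count
    exactly and each duration to the planted (grid-quantized) value."""
    total_planted = total_detected = 0
    for traj, truth in zip(e13_runs.trajectories, e13_runs.truth):
        detected = detect_pauses(traj)
        total_planted += truth.n_pauses
        total_detected += len(detected)
        if truth.n_pauses == len(detected):
            for p_det, p_true in zip(detected, truth.pauses):
                assert abs(p_det.duration - p_true.duration) <= 10.0
                assert abs(p_det.depth - p_true.depth) <= 3.0
    assert abs(total_detected - total_planted) <= 0.05 * max(total_planted, 1)


def test_raising_threshold_never_loses_pauses_on_simulated_runs(e13_runs):
    for traj in e13_runs.trajectories[:40]:
        counts = [len(detect_pauses(traj, f)) for f in (0.05, 0.1, 0.2, 0.4)]
        assert counts == sorted(counts)


# ---------------------------------------------------------------------------
# run metrics


def test_run_metrics_closed_form(constant_run):
    m = compute_run_metrics(constant_run)
    assert m.total_distance == pytest.approx(40.0)
    assert m.duration == pytest.approx(80.0)
    assert m.average_speed == pytest.approx(30.0)
    assert m.max_speed == pytest.approx(30.0)
    assert m.n_pauses == 0


def test_average_speed_times_duration_equals_distance(e11_runs):
    for traj in e11_runs.trajectories[:50]:
        m = compute_run_metrics(traj)
        assert m.average_speed * m.duration / 60.0 == pytest.approx(
            m.total_distance, rel=1e-12
        )


def test_path_length_bounds_net_displacement(e11_runs):
    """3D path length ≥ net apicobasal displacement, with equality for
    monotone jitter-free descent and strict excess when a back-step exists."""
    for traj in e11_runs.trajectories[:50]:
        m = compute_run_metrics(traj)
        i0 = int(np.searchsorted(traj.t, m.onset_time))
        ia = int(np.searchsorted(traj.t, m.arrival_time))
        net = traj.depth[i0] - traj.depth[ia]
        assert m.total_distance >= net - 1e-9

    smooth = _traj([40, 30, 20, 10, 0])
    assert compute_run_metrics(smooth).total_distance == pytest.approx(40.0)
    backstep = _traj([40, 30, 33, 20, 10, 0])
    assert compute_run_metrics(backstep).total_distance == pytest.approx(46.0)


def test_metrics_invariant_under_rigid_lateral_translation(e11_runs):
    traj = e11_runs.trajectories[0]
    shifted = NuclearTrajectory(
        traj.track_id, traj.t, traj.x + 111.5, traj.y - 42.0, traj.depth
    )
    a, b = compute_run_metrics(traj), compute_run_metrics(shifted)
    assert a.total_distance == pytest.approx(b.total_distance)
    assert a.duration == b.duration
    assert a.n_pauses == b.n_pauses
    assert a.max_speed == pytest.approx(b.max_speed)


def test_cohort_metrics_excludes_no_run_tracks(e11_runs):
    basal = _traj([5, 10, 15, 20], track="basal")
    df = cohort_metrics(list(e11_runs.trajectories[:5]) + [basal])
    assert len(df) == 5
    assert df.attrs["excluded"][0]["track_id"] == "basal"
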