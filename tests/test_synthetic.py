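"""Generator correctness: determinism, planted moments, construction invariants."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from iknm.core import ValidationError
from iknm import synthetic as syn


# ---------------------------------------------------------------------------
# determinism


@pytest.mark.parametrize(
    "factory",
    [
        lambda s: syn.simulate_apical_runs(syn.APICAL_RUN_PRESETS["E11"], 5, s),
        lambda s: syn.simulate_lateral_drift(
            syn.DriftParams(n_tracks=3, track_duration=60.0), s
        ),
        lambda s: syn.simulate_mitosis_pattern(syn.PointProcessParams(), s),
        lambda s: syn.simulate_pulse_chase(syn.PulseChaseParams(n_cells=50), s),
    ],
    ids=["runs", "drift", "pattern", "pulsechase"],
)
def test_generators_deterministic_given_seed(factory):
    a, b = factory(123), factory(123)
    if hasattr(a, "trajectories"):
        for ta, tb in zip(a.trajectories, b.trajectories):
            np.testing.assert_array_equal(ta.depth, tb.depth)
            np.testing.assert_array_equal(ta.x, tb.x)
    elif hasattr(a, "events"):
        np.testing.assert_array_equal(a.coordinates(), b.coordinates())
    else:
        np.testing.assert_array_equal(a.cohort.depths, b.cohort.depths)


def test_field_deterministic_given_seed(small_field):
    params = syn.FieldParams(
        box=(100.0, 100.0, 40.0),
        density_profile=[(0.0, 2.0, 40.0), (18.0, 20.0, 80.0), (20.0, 22.0, 80.0),
                         (28.0, 30.0, 60.0), (30.0, 32.0, 60.0)],
        phase_proportions_by_depth=[(0.0, 40.0, 0.8)],
    )
    again = syn.simulate_nuclear_field(params, seed=5)
    np.testing.assert_array_equal(
        small_field.nuclei["depth_um"], again.nuclei["depth_um"]
    )


# ---------------------------------------------------------------------------
# apical runs


def test_degenerate_distributions_give_identical_runs():
    params = syn.ApicalRunParams(pause_rate=0.0, sd_distance=0.0, sd_duration=0.0)
    sim = syn.simulate_apical_runs(params, n=5, seed=0)
    assert len(sim.trajectories) == 5
    assert {round(t.distance, 9) for t in sim.truth} == {42.3}
    assert {round(t.duration, 9) for t in sim.truth} == {95.7}
    assert all(t.n_pauses == 0 for t in sim.truth)


def test_planted_distance_and_duration_moments_recover_e11_values():
    sim = syn.simulate_apical_runs(syn.APICAL_RUN_PRESETS["E11"], n=1500, seed=42)
    d = np.array([t.distance for t in sim.truth])
    u = np.array([t.duration for t in sim.truth])
    assert abs(d.mean() - 42.3) < 3 * 9.6 / np.sqrt(d.size)
    assert abs(u.mean() - 95.7) < 3 * 41.9 / np.sqrt(u.size)
    assert abs(d.std(ddof=1) - 9.6) < 1.5
    assert abs(u.std(ddof=1) - 41.9) < 4.0


def test_planted_pause_count_is_poisson_with_requested_rate():
    params = syn.ApicalRunParams(
        mean_duration=180.0, sd_duration=60.0, pause_rate=2.0
    )
    sim = syn.simulate_apical_runs(params, n=1000, seed=7)
    counts = np.array([t.n_pauses for t in sim.truth])
    se = np.sqrt(2.0 / counts.size)
    assert abs(counts.mean() - 2.0) < 3 * se


def test_pause_displacement_well_below_detection_threshold(e13_runs):
    """During planted pauses the frame displacement is < 10% of the run's
    maximum frame displacement (detection is well-posed by construction)."""
    for traj, truth in zip(e13_runs.trajectories, e13_runs.truth):
        if not truth.pauses:
            continue
        pos = traj.positions("xyz")
        disp = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        vmax = disp.max()
        for p in truth.pauses:
            i0 = int(np.searchsorted(traj.t, p.start))
            i1 = int(np.searchsorted(traj.t, p.end))
            assert np.all(disp[i0:i1] < 0.1 * vmax)


def test_runs_end_at_apical_surface_and_start_near_planted_distance(e11_runs):
    for traj, truth in zip(e11_runs.trajectories, e11_runs.truth):
        assert traj.depth[0] == pytest.approx(truth.distance)
        assert traj.depth[-1] == 0.0


def test_impossible_pause_parameters_rejected():
    with pytest.raises(ValidationError):
        syn.simulate_apical_runs(
            syn.ApicalRunParams(mean_duration=30.0, sd_duration=5.0,
                                pause_rate=2.0, pause_mean_duration=20.0),
            n=2, seed=0,
        )
    with pytest.raises(ValidationError):
        syn.simulate_apical_runs(syn.ApicalRunParams(), n=0, seed=0)


# ---------------------------------------------------------------------------
# lateral drift


def test_zero_diffusion_tracks_are_frozen():
    sim = syn.simulate_lateral_drift(
        syn.DriftParams(diffusion_coefficient=0.0, n_tracks=3,
                        track_duration=30.0), seed=1
    )
    for t in sim.trajectories:
        assert np.ptp(t.x) == 0.0 and np.ptp(t.y) == 0.0


def test_drift_step_variance_matches_2_D_dt():
    """Per-step per-axis increment variance is 2·D·Δt (D=0.175, Δt=6 →
    2.1 μm²), tallied over >10⁴ steps."""
    sim = syn.simulate_lateral_drift(
        syn.DriftParams(diffusion_coefficient=0.175, n_tracks=200), seed=2
    )
    steps = np.concatenate(
        [np.diff(np.column_stack([t.x, t.y]), axis=0).ravel()
         for t in sim.trajectories]
    )
    assert steps.size > 10_000
    se = 2.1 * np.sqrt(2.0 / steps.size)
    assert abs(steps.var() - 2.1) < 3 * se


def test_reflecting_boundary_keeps_tracks_inside_window():
    sim = syn.simulate_lateral_drift(
        syn.DriftParams(diffusion_coefficient=1.5, n_tracks=20,
                        track_duration=300.0, window=(20.0, 20.0),
                        boundary="reflect"),
        seed=3,
    )
    for t in sim.trajectories:
        assert t.x.min() >= 0 and t.x.max() <= 20
        assert t.y.min() >= 0 and t.y.max() <= 20


def test_negative_diffusion_rejected():
    with pytest.raises(ValidationError):
        syn.simulate_lateral_drift(
            syn.DriftParams(diffusion_coefficient=-0.1), seed=0
        )


# ---------------------------------------------------------------------------
# nuclear field


def test_zero_density_profile_gives_empty_field():
    field = syn.simulate_nuclear_field(
        syn.FieldParams(density_profile=[(0.0, 2.0, 0.0), (2.0, 4.0, 0.0)]),
        seed=0,
    )
    assert field.n_nuclei == 0 and field.shortfall == {}


def test_hard_sphere_placement_reports_shortfall_when_overpacked():
    """Spheres of radius 10 at a density beyond the packing bound cannot all
    be placed; the shortfall is reported, not silently truncated."""
    params = syn.FieldParams(
        box=(50.0, 50.0, 20.0),
        density_profile=[(0.0, 20.0, 500.0)],
        radius_mean=10.0, radius_sd=0.0,
        allow_overlap=False, max_attempts_per_nucleus=30,
    )
    field = syn.simulate_nuclear_field(params, seed=1)
    assert sum(field.shortfall.values()) > 0
    centers = field.nuclei[["x_um", "y_um", "depth_um"]].to_numpy()
    if len(centers) >= 2:
        assert pdist(centers).min() >= 20.0 - 1e-9


# ---------------------------------------------------------------------------
# mitosis patterns


def test_csr_event_count_is_poisson_over_seeds():
    lam, area = 0.005, 1.0e4
    counts = [
        syn.simulate_mitosis_pattern(
            syn.PointProcessParams(kind="csr", intensity=lam), seed=s
        ).n_events
        for s in range(200)
    ]
    mean, se = lam * area, np.sqrt(lam * area / 200)
    assert abs(np.mean(counts) - mean) < 3 * se


def test_hardcore_pattern_respects_minimum_distance_exhaustively():
    pat = syn.simulate_mitosis_pattern(
        syn.PointProcessParams(kind="regular", intensity=0.02,
                               hardcore_radius=8.0),
        seed=4,
    )
    assert pat.n_events >= 2
    assert pdist(pat.coordinates()).min() >= 8.0 - 1e-12


def test_event_times_lie_within_cumulation_span():
    pat = syn.simulate_mitosis_pattern(syn.PointProcessParams(), seed=9)
    assert (pat.events["t_min"] >= 0).all()
    assert (pat.events["t_min"] <= 180.0).all()


def test_unknown_pattern_kind_rejected():
    with pytest.raises(ValidationError):
        syn.simulate_mitosis_pattern(
            syn.PointProcessParams(kind="fractal"), seed=0
        )


# ---------------------------------------------------------------------------
# pulse chase


def test_zero_g2_fraction_draws_only_s_component():
    sim = syn.simulate_pulse_chase(
        syn.PulseChaseParams(n_cells=200, g2_fraction=0.0), seed=0
    )
    assert set(sim.component) == {"S"}


def test_pulse_chase_depths_clipped_to_epithelium():
    sim = syn.simulate_pulse_chase(
        syn.PulseChaseParams(n_cells=500, s_phase_depth=(90.0, 40.0),
                             ne_thickness=92.6),
        seed=1,
    )
    d = sim.cohort.depths
    assert d.min() >= 0.0 and d.max() <= 92.6


def test_pulse_chase_mixture_mean_recovered():
    params = syn.PULSE_CHASE_PRESETS["control"]
    sim = syn.simulate_pulse_chase(params, seed=2)
    d = sim.cohort.depths
    se = d.std(ddof=1) / np.sqrt(d.size)
    assert abs(d.mean() - params.mixture_mean) < 3 * se
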