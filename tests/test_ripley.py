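"""Ripley's K estimator, CSR envelope, and pattern classification."""

import numpy as np
import pandas as pd
import pytest

from iknm.core import EventPattern, ValidationError
from iknm.ripley import (
    accumulate_events,
    analyze_pattern,
    classify_pattern,
    csr_envelope,
    default_radii,
    ripley_k,
)
from iknm import synthetic as syn


def _pattern(coords, window=(100.0, 100.0)):
    df = pd.DataFrame(coords, columns=["x_um", "y_um"])
    df["t_min"] = 0.0
    df.insert(0, "event_id", [f"e{i}" for i in range(len(df))])
    return EventPattern(df, window=window)


def brute_force_k(pts, radii, area):
    """O(n²) distance-matrix oracle for the uncorrected estimator."""
    n = len(pts)
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    out = []
    for r in radii:
        count = int(((d <= r) & ~np.eye(n, dtype=bool)).sum())
        out.append(area / (n * n) * count)
    return np.asarray(out)


def test_two_point_worked_example():
    """Two events 10 μm apart in a 100×100 μm window: K(5)=0 and
    K(15) = (1/2)·(1+1)/2e-4 = 5000 μm²."""
    pat = _pattern([(45.0, 50.0), (55.0, 50.0)])
    k = ripley_k(pat, [5.0, 15.0])
    assert k[0] == 0.0
    assert k[1] == pytest.approx(5000.0)


def test_estimator_matches_distance_matrix_oracle():
    pat = syn.simulate_mitosis_pattern(
        syn.PointProcessParams(kind="csr", intensity=0.02), seed=10
    )
    assert 2 <= pat.n_events <= 250
    radii = default_radii(pat.window)
    np.testing.assert_allclose(
        ripley_k(pat, radii),
        brute_force_k(pat.coordinates(), radii, pat.area),
        rtol=1e-12,
    )


def test_k_scales_as_c_squared_under_rescaling():
    pat = syn.simulate_mitosis_pattern(syn.PointProcessParams(), seed=11)
    c = 2.5
    scaled = _pattern(
        c * pat.coordinates(), window=(100.0 * c, 100.0 * c)
    )
    radii = np.array([5.0, 10.0, 20.0])
    np.testing.assert_allclose(
        ripley_k(scaled, c * radii), c ** 2 * ripley_k(pat, radii), rtol=1e-10
    )


def test_k_monotone_nondecreasing_in_radius():
    for seed in range(5):
        pat = syn.simulate_mitosis_pattern(syn.PointProcessParams(), seed=seed)
        k = ripley_k(pat)
        assert np.all(np.diff(k) >= 0)


def test_csr_mean_k_matches_pi_r2_up_to_known_edge_deficit():
    """At r=10 in a 100×100 window the uncorrected estimator's null mean is
    πr² − (8/3)r³/L (first-order edge deficit ≈ 8.5%); the
    translation-corrected estimator is unbiased within 2%."""
    r = 10.0
    plain, trans = [], []
    for seed in range(300):
        pat = syn.simulate_mitosis_pattern(
            syn.PointProcessParams(kind="csr", intensity=0.02), seed=seed
        )
        if pat.n_events < 2:
            continue
        plain.append(ripley_k(pat, [r])[0])
        trans.append(ripley_k(pat, [r], correction="translation")[0])
    target = np.pi * r ** 2 - (8.0 / 3.0) * r ** 3 / 100.0
    assert abs(np.mean(plain) - target) < 0.05 * target
    assert abs(np.mean(trans) - np.pi * r ** 2) < 0.02 * np.pi * r ** 2


def test_single_event_pattern_rejected():
    with pytest.raises(ValidationError):
        ripley_k(_pattern([(50.0, 50.0)]), [5.0])


# ---------------------------------------------------------------------------
# accumulation


def test_accumulation_window_is_half_open():
    df = pd.DataFrame(
        {
            "event_id": ["a", "b", "c", "d"],
            "x_um": [10.0, 20.0, 30.0, 40.0],
            "y_um": [10.0, 20.0, 30.0, 40.0],
            "t_min": [119.0, 120.0, 250.0, 300.0],
        }
    )
    pat = accumulate_events(df, t0=300.0, span=180.0)
    # (120, 300]: t=119 and t=120 excluded, 250 and 300 retained
    assert set(pat.events["event_id"]) == {"c", "d"}
    assert pat.events["t_min"].max() == pytest.approx(180.0)


def test_accumulation_matches_brute_force_filter():
    rng = np.random.default_rng(0)
    df = pd.DataFrame(
        {
            "x_um": rng.uniform(0, 100, 15),
            "y_um": rng.uniform(0, 100, 15),
            "t_min": np.concatenate([rng.uniform(130, 300, 10),
                                     rng.uniform(0, 119, 5)]),
        }
    )
    pat = accumulate_events(df, t0=300.0, span=180.0)
    expected = [t for t in df["t_min"] if 120.0 < t <= 300.0]
    assert pat.n_events == len(expected) == 10


def test_duplicate_event_ids_deduplicated():
    df = pd.DataFrame(
        {
            "event_id": ["a", "a", "b"],
            "x_um": [10.0, 10.0, 20.0],
            "y_um": [10.0, 10.0, 20.0],
            "t_min": [200.0, 200.0, 210.0],
        }
    )
    assert accumulate_events(df, t0=300.0).n_events == 2


# ---------------------------------------------------------------------------
# envelope and classification


def test_single_simulation_envelope_is_degenerate():
    pat = syn.simulate_mitosis_pattern(syn.PointProcessParams(), seed=12)
    lo, hi = csr_envelope(pat, n_sims=1, seed=0)
    np.testing.assert_array_equal(lo, hi)


def test_envelope_contains_theoretical_curve_under_null():
    """With the unbiased (translation-corrected) estimator, the 99-sim
    envelope contains πr² at all radii in ≥95% of seeded runs."""
    hits = 0
    for seed in range(20):
        pat = syn.simulate_mitosis_pattern(
            syn.PointProcessParams(kind="csr", intensity=0.01), seed=100 + seed
        )
        radii = default_radii(pat.window)
        lo, hi = csr_envelope(pat, radii, seed=seed, correction="translation")
        theory = np.pi * radii ** 2
        hits += bool(np.all((theory >= lo) & (theory <= hi)))
    assert hits >= 19


def test_midline_curve_classifies_random():
    radii = np.arange(1.0, 11.0)
    lo, hi = np.pi * radii ** 2 * 0.8, np.pi * radii ** 2 * 1.2
    label, exc, tie = classify_pattern((lo + hi) / 2, lo, hi, radii)
    assert label == "random" and exc is None and not tie


def test_single_point_blip_does_not_trigger_classification():
    radii = np.arange(1.0, 11.0)
    lo, hi = np.zeros(10), np.full(10, 100.0)
    k = np.full(10, 50.0)
    k[4] = 150.0  # one-point excursion only
    label, _, _ = classify_pattern(k, lo, hi, radii)
    assert label == "random"
    k[5] = 150.0  # now two contiguous points
    label, exc, _ = classify_pattern(k, lo, hi, radii)
    assert label == "clustered" and exc == (5.0, 6.0)


def test_mismatched_grids_rejected():
    with pytest.raises(ValidationError):
        classify_pattern(np.zeros(5), np.zeros(4), np.zeros(4), np.arange(4.0))


def test_thomas_cluster_and_hardcore_patterns_classified_correctly():
    labels = {"cluster": [], "regular": []}
    for seed in range(15):
        pat = syn.simulate_mitosis_pattern(
            syn.PointProcessParams(kind="cluster", cluster_sigma=2.0,
                                   cluster_mean_offspring=5.0),
            seed=200 + seed,
        )
        labels["cluster"].append(analyze_pattern(pat, seed=seed).classification)
        pat = syn.simulate_mitosis_pattern(
            syn.PointProcessParams(kind="regular", intensity=0.02,
                                   hardcore_radius=8.0),
            seed=300 + seed,
        )
        labels["regular"].append(analyze_pattern(pat, seed=seed).classification)
    assert labels["cluster"].count("clustered") >= 14
    assert labels["regular"].count("regular") >= 14
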