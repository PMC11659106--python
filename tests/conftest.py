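import numpy as np
import pytest

from iknm.core import NuclearTrajectory
from iknm import synthetic as syn


@pytest.fixture
def constant_run():
    """Apicalward run at exactly 0.5 μm/min from 40 μm, sampled every 10 min,
    held stationary afterwards (closed-form metrics: 40 μm, 80 min,
    30 μm/hr, no pauses)."""
    t = np.arange(0.0, 101.0, 10.0)
    depth = np.maximum(40.0 - 0.5 * t, 0.0)
    return NuclearTrajectory("const", t, np.zeros_like(t), np.zeros_like(t), depth)


@pytest.fixture
def e11_runs():
    return syn.simulate_apical_runs(syn.APICAL_RUN_PRESETS["E11"], n=120, seed=11)


@pytest.fixture
def e13_runs():
    return syn.simulate_apical_runs(syn.APICAL_RUN_PRESETS["E13"], n=120, seed=13)


@pytest.fixture
def small_field():
    params = syn.FieldParams(
        box=(100.0, 100.0, 40.0),
        density_profile=[(0.0, 2.0, 40.0), (18.0, 20.0, 80.0), (20.0, 22.0, 80.0),
                         (28.0, 30.0, 60.0), (30.0, 32.0, 60.0)],
        phase_proportions_by_depth=[(0.0, 40.0, 0.8)],
    )
    return syn.simulate_nuclear_field(params, seed=5)
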