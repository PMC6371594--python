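import numpy as np
import pytest

from sharedreach.kinematics import forward
from sharedreach.synthetic import TrajectorySpec, default_target_layout, generate_trials


@pytest.fixture(scope="session")
def layout():
    """Default 4-target evaluation layout and start configuration."""
    return default_target_layout()


@pytest.fixture(scope="session")
def start_position(layout):
    _, start = layout
    return forward(start).position


@pytest.fixture(scope="session")
def small_ensemble(layout, start_position):
    """A reduced decoded-velocity ensemble (4 directions x 3 trials, 25 steps)."""
    targets, _ = layout
    spec = TrajectorySpec(
        trials_per_direction=3, n_steps=25, base_step=0.016, seed=42
    )
    return generate_trials(spec, targets, start_position)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
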