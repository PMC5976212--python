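import numpy as np
import pytest

from edog import SpaceTimeGrid, feedforward_only_circuit, mixed_feedback_circuit


@pytest.fixture
def small_grid() -> SpaceTimeGrid:
    """Tiny grid for brute-force oracle comparisons."""
    return SpaceTimeGrid(n_spatial=16, extent=8.0, n_time=32, duration=200.0)


@pytest.fixture
def spatial_grid() -> SpaceTimeGrid:
    """Well-resolved grid for static (spatial-only) analyses; 4*pi deg wide
    so that |k| = 0.5 rad/deg multiples are exact DFT frequencies."""
    return SpaceTimeGrid(n_spatial=256, extent=4 * np.pi, n_time=8, duration=100.0)


@pytest.fixture
def ff_only():
    return feedforward_only_circuit()


@pytest.fixture
def mixed():
    return mixed_feedback_circuit()
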