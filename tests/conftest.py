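import numpy as np
import pytest

from emgmap import build_grid, default_config
from emgmap.simulate import CompartmentModel, EnslavingMatrix, SimulationConfig


@pytest.fixture
def grid():
    """The standard 63-channel 7 x 9 full-circumference grid."""
    return build_grid(7, 9, (0.0, 100.0))


@pytest.fixture
def rng():
    return np.random.default_rng(20150279)


def fast_sim_config(seed=0, **overrides):
    """Reduced-protocol simulation for tests: short windows, low fs.

    The signal chain is identical; only durations shrink so that a full
    condition simulates in milliseconds.
    """
    defaults = dict(
        fs=1000.0,
        n_reps=2,
        active_s=1.0,
        rest_s=1.0,
        pad_s=0.3,
        noise_rms=0.02,
    )
    defaults.update(overrides)
    return default_config(seed=seed, **defaults)


@pytest.fixture
def fast_config():
    return fast_sim_config()


@pytest.fixture
def single_compartment_config():
    """One compartment centered exactly on an electrode position."""
    grid = build_grid(7, 9, (0.0, 100.0))
    center = (grid.x_per_col[4], grid.y_per_row[3])  # an exact lattice point
    comp = CompartmentModel("index", center=center, spread=(9.0, 10.0), gain=1.0)
    return SimulationConfig(
        grid=grid,
        compartments=(comp,),
        enslaving=EnslavingMatrix.default(neighbour=0.0, far=0.0),
        effort_gain={"high": 1.0, "low": 0.4},
        dynamic_shift=(0.0, 0.0),
        noise_rms=0.0,
        fs=1000.0,
        n_reps=2,
        active_s=2.0,
        rest_s=1.0,
        pad_s=0.3,
        seed=7,
    )
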