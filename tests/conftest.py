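"""Shared fixtures: the two reference coupled runs used across the suite.

Both are session-scoped because a multi-day coupled soil-xylem-growth run
takes a few seconds; every test reads from the same immutable trajectory.
"""

import pytest

from rhizosim.fixtures import obstacle_config, petri_config
from rhizosim.simulate import Simulation, simulate


@pytest.fixture(scope="session")
def petri_traj():
    """Six-day wheat run in the petri-dish scenario (calibrated traits)."""
    return simulate(petri_config(nx=30, nz=30, horizon=6.0), seed=11)


@pytest.fixture(scope="session")
def obstacle_traj():
    """Single axis against a 45-degree obstacle, run past two recovery
    periods after contact loss (delta = 0, calibrated weights)."""
    return simulate(obstacle_config(eta=45.0, horizon=7.0), seed=1)


@pytest.fixture(scope="session")
def coupled_1day():
    """One-day coupled run on the 40x40 petri mesh; keeps the Simulation
    object so the final xylem solution is inspectable."""
    sim = Simulation(petri_config(nx=40, nz=40, horizon=1.0), seed=5)
    sim.run()
    return sim
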