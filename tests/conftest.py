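import numpy as np
import pytest

import dgmap as dg


@pytest.fixture(scope="session")
def grid():
    """Canonical config-1 grid: 6 layers x 10 needles x 4 terminals."""
    return dg.build_grid(1)


@pytest.fixture(scope="session")
def grid2():
    return dg.build_grid(2)


@pytest.fixture(scope="session")
def rotor_core():
    """Intramural scroll-wave axis threading the LV free wall."""
    return dg.CavityAxis(np.array([0.0, 19.0, 30.0]), np.array([1.0, 0.0, 0.0]))


@pytest.fixture(scope="session")
def rotor_episode(grid, rotor_core):
    """Scroll-wave fixture analysed end-to-end (shared: it is expensive)."""
    events, truth = dg.gen_rotor(grid, rotor_core, cycle_length=200.0, n_rotations=5)
    egm = dg.gen_electrograms(events, grid, truth)
    return dg.run_episode(events, grid, electrograms=egm), truth


@pytest.fixture(scope="session")
def focal_episode(grid):
    """Multi-beat focal fixture analysed end-to-end."""
    origin = grid.position(5)
    events, truth = dg.gen_focal(
        grid, origin, cv=0.8, beat_times=[100.0, 500.0, 900.0, 1300.0, 1700.0]
    )
    egm = dg.gen_electrograms(events, grid, truth)
    return dg.run_episode(events, grid, electrograms=egm), truth
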