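import numpy as np
import pytest

import dopadiff as dd


@pytest.fixture(scope="session")
def params() -> dd.SimulationParams:
    return dd.default_params()


@pytest.fixture(scope="session")
def small_params() -> dd.SimulationParams:
    """Default physics on a 16-µm cube, for cheap engine checks."""
    return dd.default_params(grid=dd.GridSpec(shape=(16, 16, 16)))


@pytest.fixture(scope="session")
def study():
    """Full condition-grid ensemble: 10 placement seeds × 10 phasic branches.

    Shared by the acceptance-level checks; this is the expensive fixture
    (~6 min) so it is computed once per session.
    """
    from dopadiff.reproduce import run_phasic_study

    return run_phasic_study(dd.default_params(), n_seeds=10, branch_reps=10,
                            base_seed=0)


@pytest.fixture(scope="session")
def ramp():
    """Reuptake-block ramp ensemble (protocol E), 10 seeds."""
    from dopadiff.reproduce import run_blocked_ramp

    return run_blocked_ramp(dd.default_params(), n_seeds=10, base_seed=7,
                            block_time=1.0, t_end=3.5)


@pytest.fixture(scope="session")
def site_profile():
    """Steady-state radial profile of a single continuously releasing site."""
    from dopadiff.reproduce import single_site_profile

    return single_site_profile(dd.default_params(), t_end=3.0)


def roll_laplacian(c: np.ndarray) -> np.ndarray:
    """Independent periodic 7-point Laplacian via np.roll (reference)."""
    return (np.roll(c, 1, 0) + np.roll(c, -1, 0)
            + np.roll(c, 1, 1) + np.roll(c, -1, 1)
            + np.roll(c, 1, 2) + np.roll(c, -1, 2) - 6.0 * c)
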