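import numpy as np
import pytest

from amoebokinetics.gle_model import TABLE_GLE, TABLE_GLE_NOISY, simulate_gle


@pytest.fixture(scope="session")
def table_params():
    """The fitted GLE parameter set without positional noise."""
    return TABLE_GLE


@pytest.fixture(scope="session")
def table_params_noisy():
    return TABLE_GLE_NOISY


@pytest.fixture(scope="session")
def reference_simulation():
    """The study-scale ensemble: 35 trajectories x 3600 s, 2 ms steps, 1 s samples.

    Session-scoped because the Euler-Maruyama integration dominates suite
    runtime; every consumer treats it as read-only.
    """
    return simulate_gle(TABLE_GLE_NOISY, 35, 3600.0, dt_internal=0.002,
                        sample_interval=1.0, seed=11)


@pytest.fixture()
def disc_mask():
    from skimage.draw import disk
    mask = np.zeros((256, 256), dtype=bool)
    rr, cc = disk((128, 128), 50)
    mask[rr, cc] = True
    return mask
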