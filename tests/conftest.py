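import numpy as np
import pytest

import invasipath as ip


@pytest.fixture(scope="session")
def small_scenario():
    """A 30x40 landscape with 59 presences, shared across tests."""
    return ip.SyntheticScenario(grid_shape=(30, 40), n_presences=59, seed=7)


@pytest.fixture(scope="session")
def small_bundle(small_scenario):
    return ip.generate_scenario(small_scenario)


@pytest.fixture(scope="session")
def small_table(small_bundle):
    """Training table: 59 presences + 400 pseudo-absences."""
    stack = small_bundle["stack"]
    occ = small_bundle["occurrences"]
    pres = occ.cells(stack.grid, dedupe=True)
    pseudo = ip.generate_pseudo_absences(stack, n=400, seed=11, exclude=pres)
    return ip.build_training_table(stack, occ, pseudo)


def flat_raster(shape=(10, 10), value=0.0, cell_size=100.0, kind="continuous"):
    return ip.RasterLayer(
        np.full(shape, value), cell_size=cell_size, kind=kind
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
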