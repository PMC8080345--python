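import numpy as np
import pytest

import geckomorph as gm


@pytest.fixture(scope="session")
def scheme():
    return gm.default_scheme()


@pytest.fixture(scope="session")
def base_shape(scheme):
    return gm.default_base_shape(scheme)


@pytest.fixture(scope="session")
def sim_data():
    """Default synthetic study: 86 modern configurations (43 paired
    individuals), 11 single-sided fossils, true fossil genera."""
    return gm.simulate_dataset(gm.SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def aligned(sim_data, scheme):
    """Modern configurations after mirroring, GPA, sliding, symmetrization."""
    modern, _, _ = sim_data
    return gm.prepare_dataset(modern, scheme)


@pytest.fixture(scope="session")
def space(aligned):
    return gm.pca_fit(aligned)


def random_rotation(rng):
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
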