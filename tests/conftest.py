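import numpy as np
import pytest

import twinmap as tm


@pytest.fixture(scope="session")
def reported_paths():
    """Generating paths matching the reported behavioral model: rG=0.40, rE=0.04."""
    return tm.correlated_ae_paths()


@pytest.fixture(scope="session")
def small_cohort(reported_paths):
    A, E = reported_paths
    return tm.simulate_bivariate_cohort(A, E, n_mz=120, n_dz=115,
                                        singleton_fraction=0.13, seed=5)


@pytest.fixture(scope="session")
def grid_mesh():
    return tm.make_mesh("grid", n_vertices=100, scale_mm=5.0)


@pytest.fixture(scope="session")
def sphere_mesh():
    return tm.make_mesh("sphere", n_vertices=162, scale_mm=50.0)
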