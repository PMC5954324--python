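import numpy as np
import pytest

from mwfpipe import (
    AcquisitionProtocol,
    FitConfig,
    PhantomSpec,
    PoolSet,
    T2Grid,
    build_decay_basis,
    make_phantom,
)


@pytest.fixture(scope="session")
def protocol():
    return AcquisitionProtocol()


@pytest.fixture(scope="session")
def default_basis(protocol):
    return build_decay_basis(protocol, T2Grid())


@pytest.fixture(scope="session")
def ongrid_config():
    """Fit config whose grid contains the simulator's default pool T2s,
    so noise-free phantoms are exactly representable."""
    t2 = np.unique(np.concatenate([np.geomspace(15.0, 2000.0, 40), [20.0, 80.0]]))
    return FitConfig(grid=T2Grid(t2))


@pytest.fixture(scope="session")
def noisefree_phantom(protocol):
    spec = PhantomSpec(noise_sigma=0.0)
    return make_phantom(spec, protocol, seed=0)


@pytest.fixture(scope="session")
def nawm_pool():
    return PoolSet(fractions=[0.0999, 0.8801, 0.02], t2s=[20.0, 80.0, 2000.0])


@pytest.fixture(scope="session")
def lesion_pool():
    return PoolSet(fractions=[0.080, 0.900, 0.02], t2s=[20.0, 80.0, 2000.0])
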