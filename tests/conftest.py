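import numpy as np
import pytest

from mrsynth import (
    AcquisitionAxis,
    PhantomSpec,
    TissueAxis,
    build_dictionary,
    decompose,
    generate_phantom,
)


@pytest.fixture(scope="session")
def small_dictionary():
    """A coarse but non-degenerate dictionary (99 rows x 144 cols)."""
    tissue = TissueAxis(np.arange(0.0, 5001.0, 500.0),
                        np.arange(0.0, 2001.0, 250.0))
    acq = AcquisitionAxis(np.arange(30.0, 181.0, 30.0),
                          np.linspace(1.0, 5000.0, 6),
                          np.linspace(1.0, 400.0, 4))
    return build_dictionary(tissue, acq)


@pytest.fixture(scope="session")
def small_landscape(small_dictionary):
    return decompose(small_dictionary, k=6)


@pytest.fixture(scope="session")
def medium_landscape():
    """Denser tissue grid for synthesis tests (nearest-node error small;
    the T2 grid contains the WM reference node so white matter does not
    collapse onto the degenerate T2 = 0 row)."""
    tissue = TissueAxis(np.arange(0.0, 5001.0, 200.0),
                        np.arange(0.0, 2001.0, 40.0))
    acq = AcquisitionAxis(np.arange(30.0, 181.0, 30.0),
                          np.linspace(1.0, 5000.0, 8),
                          np.linspace(1.0, 400.0, 5))
    return decompose(build_dictionary(tissue, acq), k=6)


@pytest.fixture(scope="session")
def phantom_maps():
    return generate_phantom(PhantomSpec(), seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
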