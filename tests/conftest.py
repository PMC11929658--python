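import numpy as np
import pytest

from brainnext.architecture import ArchSpec, build_brainnext
from brainnext.phantoms import PhantomConfig, generate_phantoms


@pytest.fixture(scope="session")
def small_spec() -> ArchSpec:
    """Reduced-width network spec used throughout the fast tests."""
    return ArchSpec(stage_depths=[1, 1, 1, 1], stage_widths=[8, 16, 32, 64],
                    num_classes=4, input_size=32, seed=0)


@pytest.fixture(scope="session")
def small_net(small_spec):
    return build_brainnext(small_spec)


@pytest.fixture(scope="session")
def phantom_set():
    """40 phantoms per class, seeded, with an 80/20 split."""
    return generate_phantoms(PhantomConfig(n_per_class=40, seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
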