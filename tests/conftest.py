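import numpy as np
import pytest

from archbar import (
    SyntheticModelSpec,
    generate_reference_model,
    make_scan_config,
)


@pytest.fixture(scope="session")
def model_spec():
    return SyntheticModelSpec()


@pytest.fixture(scope="session")
def reference_model(model_spec):
    """Undistorted synthetic arch-plus-bar model (mesh, regions, truth)."""
    return generate_reference_model(model_spec)


@pytest.fixture(scope="session")
def scan_config(model_spec):
    return make_scan_config(model_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(424242)
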