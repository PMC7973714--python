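import numpy as np
import pytest

from mitdet import synthetic


@pytest.fixture(scope="session")
def small_scene():
    """One deterministic desk-scale scene shared across read-only tests."""
    return synthetic.generate_scene(
        synthetic.SceneSpec(n_mitoses=5, n_nonmitoses=20, seed=1)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
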