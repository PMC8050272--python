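import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def nuclei_scene():
    from microqc.fixtures import SceneSpec, make_nuclei_scene

    return make_nuclei_scene(SceneSpec(image_shape=(96, 96), n_objects=8, seed=7))
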