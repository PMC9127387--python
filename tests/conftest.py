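import numpy as np
import pytest

from fluorotrack.synthetic import make_scene, render


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_scene():
    return render(make_scene("clean_translation", 1))


@pytest.fixture(scope="session")
def occlusion_scene():
    return render(make_scene("occlusion_pass", 1))


@pytest.fixture(scope="session")
def scale_scene():
    return render(make_scene("scale_change", 1))


@pytest.fixture(scope="session")
def lean_scene():
    return render(make_scene("forward_lean", 1))


@pytest.fixture(scope="session")
def sideview_scene():
    return render(make_scene("side_view", 1))
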