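import numpy as np
import pytest

from mammopipe.phantom import PhantomSpec, make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def mlo_bundle():
    """Clean-geometry MLO phantom with a bright pectoral triangle."""
    spec = PhantomSpec(
        view="MLO",
        side="left",
        height=128,
        width=128,
        breast_intensity=120.0,
        background_intensity=20.0,
        pectoral_intensity=200.0,
        noise_sigma=2.0,
        seed=7,
    )
    return make_phantom(spec)


@pytest.fixture
def cc_bundle():
    spec = PhantomSpec(
        view="CC",
        side="left",
        height=96,
        width=96,
        breast_intensity=120.0,
        background_intensity=20.0,
        lesions=((48.0, 30.0, 8.0, 100.0),),
        noise_sigma=2.0,
        illumination_slope=0.05,
        seed=11,
    )
    return make_phantom(spec)
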