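import numpy as np
import pytest

from colorqr.codegen import default_palette
from colorqr.synth import default_spec, render_scene
from colorqr.vision import default_layout


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def btb_spec(layout):
    return default_spec("BTB", layout=layout)


@pytest.fixture(scope="session")
def dpd_spec(layout):
    return default_spec("DPD", layout=layout)


@pytest.fixture(scope="session")
def btb_palette():
    return default_palette("BTB")


@pytest.fixture(scope="session")
def identity_scene(btb_spec, layout):
    """Noise-free, unwarped BTB scene at the 6500 K reference illuminant."""
    return render_scene(spec=btb_spec, chemistry="BTB", concentration=0.5,
                        layout=layout, cct=6500, warp_jitter=0.0,
                        noise_sigma=0.0, seed=1)


@pytest.fixture(scope="session")
def warped_scene(btb_spec, layout):
    """Realistic BTB capture: warm light, perspective jitter, sensor noise."""
    return render_scene(spec=btb_spec, chemistry="BTB", concentration=0.5,
                        layout=layout, cct=3000, warp_jitter=0.03,
                        noise_sigma=2.0, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
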