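import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def taper_scene():
    """One rendered vessel with WI=120 um, WG=-4 um/mm, shared across tests."""
    from oculovasc import synth

    vessels = [synth.VesselTruth(width_intercept_um=120.0,
                                 width_gradient_um_per_mm=-4.0,
                                 quadrant="ST", length_mm=8.0)]
    scene, truths = synth.gen_vessel_scene(vessels, image_shape=(1400, 1400),
                                           pixel_scale_um=10.0, seed=0)
    return scene, truths[0]
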