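import numpy as np
import pytest

from mle import frameio, phantoms


@pytest.fixture(scope="session")
def library():
    return frameio.default_library()


@pytest.fixture(scope="session")
def tissue_scene():
    return phantoms.default_tissue_scene(48, 48)


@pytest.fixture(scope="session")
def static_speckle_frame():
    """Single fully developed speckle frame over a static field."""
    scene = phantoms.FlowScene(
        width=128, height=128, channel_mask=np.zeros((128, 128), bool),
        velocity=0.0, n_frames=1, speckle_grain=2.0,
    )
    return phantoms.make_speckle_sequence(scene, seed=11).frames[0]


@pytest.fixture(scope="session")
def hemisphere_bundle():
    """Rendered hemisphere triple with its generating scene and geometry."""
    scene = phantoms.hemisphere_scene(96)
    geometry = phantoms.default_geometry()
    images = np.stack(
        [phantoms.render_directional(scene, geometry, i + 1) for i in range(3)]
    )
    return scene, geometry, images


@pytest.fixture(scope="session")
def registration_scene():
    """Smooth structured image suitable as a registration target."""
    import scipy.ndimage as ndi

    scene = phantoms.FlowScene(
        width=128, height=128, channel_mask=np.zeros((128, 128), bool),
        velocity=0.0, n_frames=1, speckle_grain=3.0,
    )
    base = phantoms.make_speckle_sequence(scene, seed=7).frames[0]
    base = ndi.gaussian_filter(base, 2.0)
    return base / base.max()
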