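import numpy as np
import pytest

from lvipathnet.types import SlidePlane
from lvipathnet.synthetic_slide import SceneConfig, generate_scene


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def small_plane(rng):
    """A 200x160 RGB plane at 1 um/px with random but fixed content."""
    pixels = rng.integers(0, 256, size=(200, 160, 3), dtype=np.uint8)
    return SlidePlane(pixels, mpp=1.0, name="fixture")


@pytest.fixture(scope="session")
def demo_slide():
    """One small synthetic slide with a mix of states, shared per session."""
    cfg = SceneConfig(
        width_px=256, height_px=256, mpp=2.0,
        n_vessels_by_kind={"vein": 1, "capillary": 3, "lymphatic": 2},
        invasion_fraction=0.5, intramural_fraction=0.3, stain_jitter=0.1,
        seed=42,
    )
    return generate_scene(cfg)
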