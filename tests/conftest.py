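import numpy as np
import pytest

from pyrascreen.synthetic import LesionSpec, SlideSpec, generate_slide


@pytest.fixture(scope="session")
def small_slide():
    """512 px slide at 1 um/px with one 100 um lesion (session-cached)."""
    spec = SlideSpec(base_height=512, base_width=512, n_levels=5,
                     pixel_size_um=1.0,
                     lesions=[LesionSpec(center=(256, 256), diameter_um=100,
                                         shape_irregularity=0.3)],
                     nuclei_density=400.0, background_seed=11)
    return generate_slide(spec, seed=7)


@pytest.fixture(scope="session")
def negative_slide():
    spec = SlideSpec(base_height=256, base_width=256, n_levels=4,
                     pixel_size_um=1.0, nuclei_density=400.0,
                     background_seed=5)
    return generate_slide(spec, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
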