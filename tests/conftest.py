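import numpy as np
import pytest

from floatscan.scenes import SceneParams, default_library, generate_scene


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def clean_scene(library):
    """Noise-free scene with moderate-chi patches and no confounders."""
    params = SceneParams(
        n_patches=8,
        chi_range=(0.002, 0.01),
        noise_sd=0.0,
        aerosol_range=(0.001, 0.004),
    )
    return generate_scene(96, 96, library, params, seed=11)


@pytest.fixture(scope="session")
def confounded_scene(library):
    """Noisy scene with clouds, shadows and glint present."""
    params = SceneParams(
        n_patches=6,
        chi_range=(0.005, 0.05),
        noise_sd=5e-5,
        cloud_fraction=0.05,
        shadow_fraction=0.03,
        glint_fraction=0.03,
    )
    return generate_scene(96, 96, library, params, seed=21)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
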