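import numpy as np
import pytest
from hypothesis import settings

from lcoratio import (
    MixWeights,
    PlaqueSpec,
    SceneSpec,
    make_wavelength_grid,
    render_cube,
    standard_templates,
)

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid():
    """Default acquisition grid: 450-700 nm in 10 nm steps."""
    return make_wavelength_grid(450, 700, 10, require_ratiometry=True)


@pytest.fixture(scope="session")
def fine_grid():
    return make_wavelength_grid(450, 700, 1, require_ratiometry=True)


@pytest.fixture(scope="session")
def templates(grid):
    return standard_templates(grid)


@pytest.fixture(scope="session")
def small_scene():
    """A 96x96 field with one hand-specified plaque (core 2 um, corona 6 um)."""
    plaque = PlaqueSpec(
        center=(48, 48),
        core_radius_um=2.0,
        corona_radius_um=6.0,
        core_weights=MixWeights(w_q=0.6, w_h=0.4),
        corona_weights=MixWeights(w_q=0.15, w_h=0.85),
        brightness=100.0,
    )
    return SceneSpec(shape=(96, 96), plaques=[plaque], genotype_label="test")


@pytest.fixture(scope="session")
def small_render(small_scene, grid):
    """(cube, truth) of the small scene with noise, seed 7."""
    return render_cube(small_scene, grid, seed=7)


@pytest.fixture(scope="session")
def small_render_clean(small_scene, grid):
    return render_cube(small_scene, grid, seed=7, noise=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
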