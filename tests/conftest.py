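"""Shared fixtures: small synthetic trials and scenes, generated at test time."""

import numpy as np
import pytest

from peafuse import simulate
from peafuse.raster import Band, Scene
from peafuse.simulate import (
    SATELLITE_BANDS,
    SceneSpec,
    TrialDesign,
    YieldModel,
    default_link,
    generate_trial,
    render_scene,
)


@pytest.fixture(scope="session")
def small_design():
    return TrialDesign(n_entries=6, n_replicates=2)


@pytest.fixture(scope="session")
def small_yield_model():
    return YieldModel.from_total_sd(1938.0, 498.0)


@pytest.fixture(scope="session")
def small_plots(small_design, small_yield_model):
    return generate_trial(small_design, small_yield_model, seed=11)


@pytest.fixture(scope="session")
def noiseless_link():
    return default_link(pixel_noise_sd=0.0)


@pytest.fixture(scope="session")
def fine_scene(small_plots, noiseless_link):
    """Noiseless 0.05 m UAS-like scene over the small trial."""
    return render_scene(
        small_plots, noiseless_link, SceneSpec(gsd_m=0.05), timepoint="TP2", seed=5
    )


@pytest.fixture(scope="session")
def sat_scene(fine_scene):
    """0.45 m satellite-like companion of the fine scene (ratio 9)."""
    return simulate.degrade_to_sensor(
        fine_scene, SceneSpec(gsd_m=0.45, bands=SATELLITE_BANDS)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_scene(rng, height=16, width=16, bands=("a", "b", "c"), gsd=1.0, low=0.05, high=0.95):
    """Random reflectance-like scene used by property tests."""
    values = rng.uniform(low, high, size=(height, width, len(bands)))
    descriptors = tuple(Band(n, 500.0 + 50 * i) for i, n in enumerate(bands))
    return Scene(values, descriptors, gsd, (0.0, 0.0))


@pytest.fixture()
def make_random_scene(rng):
    def _make(**kwargs):
        return random_scene(rng, **kwargs)

    return _make
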