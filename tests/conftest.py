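import numpy as np
import pytest

from ramanmix import NoiseSpec, WavenumberAxis, default_components, render_scene
from ramanmix.synth import default_axis


@pytest.fixture(scope="session")
def axis() -> WavenumberAxis:
    return default_axis()


@pytest.fixture(scope="session")
def refs_and_models():
    return default_components()


@pytest.fixture(scope="session")
def refs(refs_and_models):
    return refs_and_models[0]


@pytest.fixture(scope="session")
def clean_tile_scene():
    """Zero-nuisance tile scene: exact forward model, pure tiles included."""
    return render_scene("tiles", (24, 24), noise=NoiseSpec.zero(), seed=7)


@pytest.fixture(scope="session")
def noisy_cells_scene():
    """Cells layout with 2% Gaussian noise, fluorescence, and cosmic spikes."""
    return render_scene(
        "cells",
        (40, 50),
        noise=NoiseSpec(gaussian_sd=0.02, spike_rate=0.02, spike_magnitude=10.0,
                        baseline_scale=1.0),
        seed=3,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
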