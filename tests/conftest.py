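import numpy as np
import pytest

from spotlag.synthetic_data import (
    make_screen_design,
    render_series,
    sample_strain_models,
)


@pytest.fixture(scope="session")
def small_experiment():
    """A small rendered screen shared across tests: 4 strains x 3 doses x 2
    densities on one plate, noise-free and jitter-free (exact ground truth)."""
    models = sample_strain_models(4, seed=1)
    design = make_screen_design(
        models, doses=(0.0, 0.05, 0.5), density_classes=("low", "high")
    )
    series, truth = render_series(
        design, models, seed=2, sigma=0.0, jitter=False, gradient_amplitude=0.0
    )
    return models, design, series, truth


@pytest.fixture(scope="session")
def noisy_experiment():
    """Same screen with the generator's default noise, jitter and gradient."""
    models = sample_strain_models(4, seed=1)
    design = make_screen_design(
        models, doses=(0.0, 0.05, 0.5), density_classes=("low", "high")
    )
    series, truth = render_series(design, models, seed=2)
    return models, design, series, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
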