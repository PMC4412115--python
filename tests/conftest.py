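import numpy as np
import pytest

from phenoscope import (
    FeatureConfig,
    SceneConfig,
    render_scene,
    train_default_model,
)


@pytest.fixture(scope="session")
def feature_config():
    return FeatureConfig()


@pytest.fixture(scope="session")
def default_model():
    """Phenotype network trained once on the default synthetic set."""
    model = train_default_model(n_per_class=100, seed=0)
    assert model.converged_
    return model


def noiseless_config(**kw) -> SceneConfig:
    """Flat-field, noise-free scene config for exact-value tests."""
    base = dict(
        image_height=300,
        image_width=400,
        n_cells=20,
        noise_sd=0.0,
        vignette_strength=0.0,
        seed=0,
    )
    base.update(kw)
    return SceneConfig(**base)


@pytest.fixture()
def noiseless_scene():
    return render_scene(noiseless_config())


def draw_block(image: np.ndarray, row: int, col: int, shape, color) -> None:
    """Paint a solid rectangle (test helper for constructed counterexamples)."""
    h, w = shape
    image[row : row + h, col : col + w] = np.asarray(color, dtype=image.dtype)
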