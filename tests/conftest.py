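import numpy as np
import pytest

from retikan.synthetic import LesionModel, generate_image


@pytest.fixture(scope="session")
def lesion_model() -> LesionModel:
    return LesionModel()


@pytest.fixture(scope="session")
def fundus64(lesion_model):
    """One small moderate-grade fundus image, reused across read-only tests."""
    return generate_image(2, 64, lesion_model, np.random.default_rng(42),
                          id="fixture64")


@pytest.fixture(scope="session")
def fundus224(lesion_model):
    return generate_image(3, 224, lesion_model, np.random.default_rng(43),
                          id="fixture224")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
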