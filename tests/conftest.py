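import numpy as np
import pytest

from a3som import A3SOM, ArtificialSpec, generate_artificial


@pytest.fixture(scope="session")
def artificial_default():
    """The default 3000-point, 6-class artificial benchmark dataset."""
    return generate_artificial()


@pytest.fixture(scope="session")
def artificial_small():
    """A 600-point draw of the artificial benchmark, for fast model tests."""
    return generate_artificial(ArtificialSpec(n_total=600, seed=11))


@pytest.fixture(scope="session")
def trained_small(artificial_small):
    """A quickly-trained softmax model on the small artificial dataset."""
    model = A3SOM(artificial_small, map_shape=(6, 6))
    return model.fit(epochs=15, optimizer="adam", learning_rate=3e-3, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
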