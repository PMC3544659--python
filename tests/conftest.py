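import numpy as np
import pytest

from ihcscore.stain_separation import StainMatrix


@pytest.fixture(scope="session")
def hdab() -> StainMatrix:
    return StainMatrix.preset("hdab")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20261001)


def render_from_concentrations(hema_c, dab_c, matrix, background=255.0):
    """Forward Beer-Lambert render used as the independent test oracle."""
    od = np.stack([hema_c, dab_c, np.zeros_like(dab_c)], axis=-1) @ matrix.matrix.T
    rgb = background * np.power(10.0, -od)
    return np.clip(np.floor(rgb + 0.5), 0, 255).astype(np.uint8)
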