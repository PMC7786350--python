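import numpy as np
import pytest

from elneuro.field_core import Montage, average_reference
from elneuro.simulate import default_montage


@pytest.fixture(scope="session")
def montage() -> Montage:
    return default_montage()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def orthogonal_templates(montage):
    """Three average-referenced, unit-GFP, pairwise-orthogonal scalp maps."""
    raw = np.random.default_rng(7).standard_normal((3, montage.n_channels))
    q, _ = np.linalg.qr(average_reference(raw, axis=1).T)
    tmpl = average_reference(q[:, :3].T, axis=1)
    return tmpl / tmpl.std(axis=1, keepdims=True)
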