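import numpy as np
import pytest

from spermshape import ShapeParams, generate_shape
from spermshape.geometry import Outline


@pytest.fixture(scope="session")
def circle_outline() -> Outline:
    t = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    return Outline(np.column_stack([np.cos(t), np.sin(t)]))


@pytest.fixture(scope="session")
def square_outline() -> Outline:
    s = np.linspace(0, 1, 100, endpoint=False)
    z = np.zeros_like(s)
    return Outline(np.vstack([
        np.column_stack([s, z]),
        np.column_stack([z + 1, s]),
        np.column_stack([1 - s, z + 1]),
        np.column_stack([z, 1 - s]),
    ]))


@pytest.fixture(scope="session")
def ellipse_outline() -> Outline:
    t = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    return Outline(np.column_stack([2 * np.cos(t), np.sin(t)]))


@pytest.fixture(scope="session")
def wt_outline() -> Outline:
    return generate_shape(ShapeParams(), seed=1)
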