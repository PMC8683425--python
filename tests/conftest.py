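import numpy as np
import pytest

from funfor import CurveMatrix, Grid, PredictorTable


@pytest.fixture
def grid20():
    return Grid.uniform(20)


@pytest.fixture
def grid100():
    return Grid.uniform(100)


@pytest.fixture
def noisy_sin_curves(grid100):
    """n=200 curves: sin(2*pi*t) mean + one random cosine mode + iid noise."""
    rng = np.random.default_rng(42)
    t = grid100.points
    Y = (
        np.sin(2 * np.pi * t)[None, :]
        + rng.standard_normal((200, 1)) * np.cos(2 * np.pi * t)[None, :]
        + 0.1 * rng.standard_normal((200, 100))
    )
    return CurveMatrix(Y, grid100)


@pytest.fixture
def two_group_data(grid20):
    """A binary predictor perfectly separating two constant-offset curve groups."""
    rng = np.random.default_rng(7)
    n = 60
    t = grid20.points
    X = rng.standard_normal((n, 5))
    X[:, 0] = (rng.random(n) > 0.5).astype(float)
    Y = X[:, 0][:, None] * 1.0 + np.sin(2 * np.pi * t)[None, :]
    Y = Y + 0.05 * rng.standard_normal((n, 20))
    return CurveMatrix(Y, grid20), PredictorTable(X)
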