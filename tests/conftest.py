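import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def numerical_gradient(f, x, eps=1e-5):
    """Central finite differences of a scalar function wrt array x (in place)."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        old = x[i]
        x[i] = old + eps
        fp = f()
        x[i] = old - eps
        fm = f()
        x[i] = old
        g[i] = (fp - fm) / (2 * eps)
    return g


@pytest.fixture
def tiny_classification_data(rng):
    """Small labeled source + unlabeled target arrays for 16x16 networks."""
    xs = rng.random((24, 16, 16, 3), dtype=np.float32)
    ys = np.zeros((24, 2), dtype=np.float32)
    ys[:9, 1] = 1.0
    ys[9:, 0] = 1.0
    xt = rng.random((16, 16, 16, 3), dtype=np.float32)
    return xs, ys, xt
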