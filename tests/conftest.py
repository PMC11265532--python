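import numpy as np
import pytest

from hexademosaic.experiments import scaled_down_experiment


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def scaled_down():
    """The desk-scale train-vs-bilinear experiment (run once per session).

    Minutes of CPU; shared by every test that needs a trained model.
    """
    return scaled_down_experiment(seed=1)


def bilinear_loop_oracle(data: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Per-pixel reference for the 1D horizontal interpolation baseline."""
    h, w, _ = data.shape
    out = data.copy()
    for r in range(h):
        for c in range(w):
            if valid[r, c]:
                continue
            neigh = []
            if c > 0 and valid[r, c - 1]:
                neigh.append(data[r, c - 1])
            if c < w - 1 and valid[r, c + 1]:
                neigh.append(data[r, c + 1])
            assert neigh, "checkerboard guarantees a horizontal neighbour"
            out[r, c] = np.mean(neigh, axis=0)
    return out


def conv_loop_oracle(x: np.ndarray, weight: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Direct zero-padded convolution, one multiply at a time (NHWC)."""
    b, h, w, cin = x.shape
    k = weight.shape[0]
    pad = k // 2
    cout = weight.shape[3]
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    out = np.zeros((b, h, w, cout))
    for bi in range(b):
        for r in range(h):
            for c in range(w):
                for co in range(cout):
                    acc = bias[co]
                    for kr in range(k):
                        for kc in range(k):
                            for ci in range(cin):
                                acc += xp[bi, r + kr, c + kc, ci] * weight[kr, kc, ci, co]
                    out[bi, r, c, co] = acc
    return out
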