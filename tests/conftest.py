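import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def naive_conv2d(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Independent direct-convolution oracle: same-padded cross-correlation.

    Loops over every output element; kept deliberately separate from the
    package's einsum-based implementation.
    """
    B, ci, H, W = x.shape
    ci2, co, kh, kw = kernel.shape
    assert ci == ci2
    ph, pw = (kh - 1) // 2, (kw - 1) // 2
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    out = np.zeros((B, co, H, W))
    for b in range(B):
        for o in range(co):
            for h in range(H):
                for w in range(W):
                    acc = 0.0
                    for c in range(ci):
                        for i in range(kh):
                            for j in range(kw):
                                acc += kernel[c, o, i, j] * xp[b, c, h + i, w + j]
                    out[b, o, h, w] = acc
    return out


@pytest.fixture
def naive_conv():
    return naive_conv2d
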