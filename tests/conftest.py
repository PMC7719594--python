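import numpy as np
import pytest

from ventseg import BoundingBox, make_disk_phantom, make_ventricle_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def disk():
    """Noiseless 64x64 disk phantom (contrast 80) with a padded seed box."""
    ph = make_disk_phantom()
    box = BoundingBox.around_mask(ph.truth, pad=5)
    return ph, box


@pytest.fixture(scope="session")
def ventricle():
    """Default ventricle phantom (60 deg weak arc, noise 5) with seed box."""
    ph = make_ventricle_phantom()
    box = BoundingBox.around_mask(ph.truth, pad=4)
    return ph, box


def loop_gradient(f):
    """Independent loop-based stencil: central interior, one-sided borders."""
    f = np.asarray(f, dtype=float)
    h, w = f.shape
    gx = np.zeros_like(f)
    gy = np.zeros_like(f)
    for i in range(h):
        for j in range(w):
            if 0 < j < w - 1:
                gx[i, j] = (f[i, j + 1] - f[i, j - 1]) / 2.0
            elif j == 0:
                gx[i, j] = f[i, 1] - f[i, 0]
            else:
                gx[i, j] = f[i, w - 1] - f[i, w - 2]
            if 0 < i < h - 1:
                gy[i, j] = (f[i + 1, j] - f[i - 1, j]) / 2.0
            elif i == 0:
                gy[i, j] = f[1, j] - f[0, j]
            else:
                gy[i, j] = f[h - 1, j] - f[h - 2, j]
    return gx, gy


def loop_divergence(vx, vy):
    gxx, _ = loop_gradient(vx)
    _, gyy = loop_gradient(vy)
    return gxx + gyy


def loop_gaussian_smooth(I, sigma, ksize):
    """Independent truncated-Gaussian convolution with replicate borders."""
    I = np.asarray(I, dtype=float)
    r = ksize // 2
    k1 = np.exp(-0.5 * ((np.arange(ksize) - r) / sigma) ** 2)
    k1 = k1 / k1.sum()
    k2 = np.outer(k1, k1)
    h, w = I.shape
    out = np.zeros_like(I)
    for i in range(h):
        for j in range(w):
            acc = 0.0
            for a in range(-r, r + 1):
                for b in range(-r, r + 1):
                    ii = min(max(i + a, 0), h - 1)
                    jj = min(max(j + b, 0), w - 1)
                    acc += k2[a + r, b + r] * I[ii, jj]
            out[i, j] = acc
    return out
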