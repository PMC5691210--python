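import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def disc_mask():
    def make(radius, pad=5):
        n = 2 * (radius + pad)
        yy, xx = np.mgrid[:n, :n]
        return (yy - n // 2) ** 2 + (xx - n // 2) ** 2 <= radius * radius
    return make


def random_histograms(n, seed):
    """Assorted random 256-bin histograms: bimodal mixtures, uniform noise,
    sparse spikes — the shapes thresholding methods actually meet."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        kind = i % 3
        hist = np.zeros(256, dtype=np.int64)
        if kind == 0:  # two gaussian-ish modes
            for mu, sig, size in (
                (rng.integers(20, 100), rng.uniform(5, 20), 4000),
                (rng.integers(140, 240), rng.uniform(5, 25), rng.integers(500, 4000)),
            ):
                vals = np.clip(rng.normal(mu, sig, int(size)).round(), 0, 255)
                hist += np.bincount(vals.astype(int), minlength=256)
        elif kind == 1:  # uniform support with noise
            lo, hi = sorted(rng.integers(0, 256, 2))
            hi = max(hi, lo + 2)
            hist[lo:hi] = rng.integers(0, 50, hi - lo)
            if np.count_nonzero(hist) < 2:
                hist[lo] = 5
                hist[hi - 1] = 7
        else:  # sparse spikes
            bins = rng.choice(256, size=rng.integers(2, 8), replace=False)
            hist[bins] = rng.integers(1, 1000, len(bins))
        out.append(hist)
    return out
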