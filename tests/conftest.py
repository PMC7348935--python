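import numpy as np
import pytest

from stromaquant.io import CalibratedImage


def pearson_over_pairs(img: np.ndarray, offset: tuple[int, int],
                       symmetric: bool = True) -> float:
    """Brute-force oracle: Pearson correlation over enumerated pixel pairs.

    Walks every pixel, collects the (value, offset-value) pairs that fall
    in bounds (both orders when symmetric), and computes np.corrcoef on the
    resulting sample.  Independent of the co-occurrence-matrix code path.
    """
    dx, dy = offset
    h, w = img.shape
    first, second = [], []
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dy, c + dx
            if 0 <= r2 < h and 0 <= c2 < w:
                first.append(img[r, c])
                second.append(img[r2, c2])
                if symmetric:
                    first.append(img[r2, c2])
                    second.append(img[r, c])
    a = np.asarray(first, dtype=float)
    b = np.asarray(second, dtype=float)
    return float(np.corrcoef(a, b)[0, 1])


@pytest.fixture
def checkerboard():
    board = (np.indices((64, 64)).sum(axis=0) % 2).astype(float)
    return CalibratedImage(board)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
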