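import numpy as np
import pytest

import histoswt as hs


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def graded_small():
    """30-image graded dataset (10 per class), 32x32, fixed seed."""
    spec = hs.SyntheticSpec(n_per_class=(10, 10, 10), image_size=(32, 32), seed=7)
    return hs.generate_graded_dataset(spec)


@pytest.fixture(scope="session")
def seg_pairs_small():
    """Ten 48x48 epithelium/stroma image-mask pairs, fixed seed."""
    spec = hs.SyntheticSpec(image_size=(48, 48), seed=3, n_seg_images=10)
    return hs.generate_seg_dataset(spec)


def pairwise_auc(y, s):
    """Brute-force concordant-pair AUC oracle (ties count one half)."""
    y = np.asarray(y)
    s = np.asarray(s, dtype=float)
    pos = s[y == 1]
    neg = s[y == 0]
    conc = sum(float(p > q) + 0.5 * float(p == q) for p in pos for q in neg)
    return conc / (len(pos) * len(neg))
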