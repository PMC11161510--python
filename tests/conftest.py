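import numpy as np
import pandas as pd
import pytest

from sarcomics.images import ImageVolume, SegmentationMask
from sarcomics.synthetic import PhenotypeSpec, generate_tumor_study


@pytest.fixture(scope="session")
def small_study():
    """One deterministic synthetic tumor study on a small grid."""
    spec = PhenotypeSpec("A", size_mm_mean=40, size_mm_sd=5,
                         texture_contrast=1.5, necrosis_prob=1.0,
                         peritumoral_rim_prob=1.0, heterogeneity_prob=1.0)
    return generate_tumor_study(spec, grid_shape=(32, 32, 10),
                                spacing=(2.0, 2.0, 4.0), seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ball_mask():
    """Spherical mask on an isotropic grid."""
    n = 24
    c = (n - 1) / 2
    ii, jj, kk = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
    m = (ii - c) ** 2 + (jj - c) ** 2 + (kk - c) ** 2 <= 9 ** 2
    return SegmentationMask(m, (1.0, 1.0, 1.0))


def blob_matrix(k, n_per, p=20, sep=3.0, seed=0):
    """Well-separated planted clusters with dense mean patterns, as a
    feature DataFrame plus the planted labels."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for i in range(k):
        c = sep * rng.choice([-1.0, 1.0], size=p)
        X.append(rng.normal(0, 1, (n_per, p)) + c)
        y += [i] * n_per
    return pd.DataFrame(np.vstack(X)), np.array(y)
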