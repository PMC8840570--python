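import numpy as np
import pytest

from glcmtex import (
    FeatureTable,
    QuantizedROI,
    canonical_directions,
    compute_glcm_set,
)


@pytest.fixture(scope="session")
def dirs13():
    return canonical_directions()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_roi(rng, shape=(6, 6, 6), n_levels=4, mask_p=0.85):
    """A small random quantized ROI with a random (nonempty) mask."""
    levels = rng.integers(0, n_levels, size=shape)
    mask = rng.random(shape) < mask_p
    if not mask.any():
        mask[tuple(s // 2 for s in shape)] = True
    return QuantizedROI(levels=levels, mask=mask, n_levels=n_levels)


@pytest.fixture
def small_roi(rng):
    return random_roi(rng)


@pytest.fixture
def constant_roi():
    shape = (5, 5, 5)
    return QuantizedROI(
        levels=np.zeros(shape, dtype=int), mask=np.ones(shape, bool), n_levels=32
    )


@pytest.fixture
def constant_glcmset(constant_roi):
    return compute_glcm_set(constant_roi)


@pytest.fixture
def small_glcmset(small_roi):
    return compute_glcm_set(small_roi)


def simple_table(rng, n=40, n_noise=6, n_informative=2, delta=2.0, groups=None):
    """Tiny labelled table: leading columns informative, rest noise."""
    y = np.tile([0, 1], n // 2)
    cols = []
    p = n_informative + n_noise
    for j in range(p):
        x = rng.standard_normal(n)
        if j < n_informative:
            x = x + delta * y
        cols.append(x)
    if groups is None:
        groups = np.ones(p, dtype=int)
    return FeatureTable(
        matrix=np.column_stack(cols),
        labels=y,
        feature_labels=[f"f{j}" for j in range(p)],
        group_assignment=np.asarray(groups),
    )
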