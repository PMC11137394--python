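import numpy as np
import pytest

from leafspec.io import SampleMeta, SpectraSet, Spectrum


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_set(matrix, axis=None, modality="raman", ids=None):
    """SpectraSet from a plain matrix with synthetic metadata."""
    matrix = np.asarray(matrix, dtype=float)
    if axis is None:
        axis = 100.0 + 10.0 * np.arange(matrix.shape[1])
    metas = [SampleMeta(acquisition_index=i) for i in range(matrix.shape[0])]
    return SpectraSet(np.asarray(axis, float), matrix, metas, modality, ids)


def make_spectrum(values, axis=None, modality="raman"):
    values = np.asarray(values, dtype=float)
    if axis is None:
        axis = 100.0 + 10.0 * np.arange(values.size)
    return Spectrum(np.asarray(axis, float), values, modality)


@pytest.fixture
def toy_set(rng):
    """Seeded 8 x 6 matrix with genuine correlation structure."""
    m, q = 8, 6
    base = rng.normal(size=(m, 2)) @ rng.normal(size=(2, q))
    return make_set(base + 0.1 * rng.normal(size=(m, q)))
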