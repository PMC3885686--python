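import numpy as np
import pytest

from seqsig.synthetic_data import generate_counts
from seqsig.preprocess import filter_low_counts, normalize, truncate_extremes


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture(scope="session")
def small_counts():
    """A small but structured count matrix shared across tests."""
    return generate_counts(200, 60, seed=42)


@pytest.fixture(scope="session")
def small_normalized(small_counts):
    filtered, _ = filter_low_counts(small_counts)
    tm = truncate_extremes(normalize(filtered))
    keep = tm.values.var(axis=1) > 0
    tm.values = tm.values[keep]
    tm.genes = [g for g, k in zip(tm.genes, keep) if k]
    return tm
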