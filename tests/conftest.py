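import numpy as np
import pytest

from swarmbalance import LabeledDataset, SynthSpec, make_imbalanced


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_imbalanced():
    """90 vs 10 separable blobs — minimal dataset for evaluation-loop tests."""
    return make_imbalanced(SynthSpec(n_majority=90, n_minority=10,
                                     n_features=3, separation=4.0, seed=3))


@pytest.fixture
def line_dataset():
    """Three 1-D minority points at 0, 1, 10 plus majority filler."""
    feats = np.array([[0.0], [1.0], [10.0], [50.0], [60.0], [70.0], [80.0]])
    labels = np.array([1, 1, 1, 0, 0, 0, 0])
    return LabeledDataset(feats, labels)


def counts_dataset(negative: int, positive: int) -> LabeledDataset:
    """Minimal dataset carrying exact class counts (single zero feature)."""
    n = negative + positive
    labels = np.concatenate([np.zeros(negative, dtype=int),
                             np.ones(positive, dtype=int)])
    return LabeledDataset(np.zeros((n, 1)), labels)
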