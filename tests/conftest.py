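import numpy as np
import pytest

from soaptriage import CorpusConfig, generate_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """400 records with strong class signal; shared read-only across tests."""
    return generate_corpus(CorpusConfig(n_records=400, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_scores_labels(rng, n=40, tie_prob=0.0):
    """Random score/label instance with both classes, optionally with ties."""
    while True:
        labels = rng.integers(0, 2, n)
        if 0 < labels.sum() < n:
            break
    scores = rng.normal(size=n)
    if tie_prob > 0:
        scores = np.round(scores / tie_prob) * tie_prob  # coarse grid -> ties
    return scores, labels
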