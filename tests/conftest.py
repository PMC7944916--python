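"""Shared fixtures: fixture corpora and session-scoped trained models.

The expensive models (generator pre-trained on 2,000 fixture molecules)
are session-scoped so the training-curve tests and the end-to-end RL
tests share one fit.
"""

import numpy as np
import pytest

from divmolgen import generate_fixture_corpus
from divmolgen.generator import SmilesGenerator

# Desk-scale study conditions: 2,000 fixture molecules, 5 pre-training
# epochs, a 2x64 LSTM policy and padded length 32 (the fixture corpus
# tokenizes to at most ~30 tokens).
DESK_CORPUS_N = 2000
DESK_CORPUS_SEED = 7
DESK_GEN_CONFIG = dict(recurrent_layers=2, recurrent_units=64, dropout=0.3,
                       max_len=32, epochs=5, batch_size=16, random_state=1)


@pytest.fixture(scope="session")
def fixture_corpus():
    return generate_fixture_corpus(DESK_CORPUS_N, seed=DESK_CORPUS_SEED)


@pytest.fixture(scope="session")
def small_corpus():
    return generate_fixture_corpus(300, seed=DESK_CORPUS_SEED)


@pytest.fixture(scope="session")
def pretrained_generator(fixture_corpus):
    """Generator pre-trained under the desk-scale study conditions."""
    return SmilesGenerator(**DESK_GEN_CONFIG).fit(fixture_corpus)


@pytest.fixture(scope="session")
def tiny_generator(small_corpus):
    """A cheap, lightly trained generator for structural/sampling tests."""
    gen = SmilesGenerator(recurrent_layers=1, recurrent_units=32, dropout=0.0,
                          max_len=32, epochs=2, batch_size=16, random_state=1)
    return gen.fit(small_corpus)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
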