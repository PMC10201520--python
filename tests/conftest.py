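"""Shared fixtures: fixture corpora, tiny models, and the (expensive)
desk-scale overfit training run reused by the acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

from moldvae import seeding
from moldvae.model import DVAE, ModelConfig
from moldvae.smiles import build_vocab, generate_fixture_corpus
from moldvae.training import TrainConfig, train

FIXTURE_SEED = 7  # corpus seed used throughout the desk-scale experiments


@pytest.fixture(scope="session")
def fixture_corpus() -> list[str]:
    return generate_fixture_corpus(32, seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def vocab(fixture_corpus):
    return build_vocab(fixture_corpus)


@pytest.fixture()
def tiny_model(vocab) -> DVAE:
    """Untrained reduced model — cheap enough to build per test."""
    return DVAE(ModelConfig.reduced(len(vocab)), vocab, seed=0)


@pytest.fixture(scope="session")
def overfit_run(fixture_corpus, vocab):
    """The 200-epoch desk-scale memorization run (reduced model, 32-molecule
    fixture).  Trained once per session; several tests read from it."""
    model = DVAE(ModelConfig.reduced(len(vocab)), vocab, seed=0)
    config = TrainConfig.overfit(epochs=200, seed=0)
    result = train(config, model, list(fixture_corpus))
    return result


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_rbm(n_a: int, n_b: int, seed: int, scale: float = 1.0):
    """Random small RBM for oracle comparisons."""
    from moldvae.rbm import RBM
    rbm = RBM(n_a, n_b, np.random.default_rng(seed))
    g = np.random.default_rng(seed + 1000)
    rbm.h.data = g.normal(0.0, scale, n_a + n_b)
    rbm.W.data = g.normal(0.0, scale, (n_a, n_b))
    return rbm
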