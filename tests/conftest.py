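"""Shared fixtures: tiny hand-checkable models and the default study setup."""

import logging

import numpy as np
import pytest

import lossyctx as lx

logging.getLogger("lossyctx").setLevel(logging.ERROR)


# --------------------------------------------------------------------------
# tiny, hand-checkable language models


@pytest.fixture(scope="session")
def tiny_corpus():
    # stream: a b a b b a -> bigrams ab, ba, ab, bb, ba
    return lx.CorpusSample((("a", "b", "a"), ("b", "b", "a")), seed=0, grammar_digest="tiny")


@pytest.fixture(scope="session")
def tiny_bigram(tiny_corpus):
    return lx.fit_ngram(tiny_corpus, order=2, smoothing={"add_k": 0.1})


@pytest.fixture(scope="session")
def tiny_bigram_exact(tiny_corpus):
    """Unsmoothed bigram for hand-count checks."""
    return lx.fit_ngram(tiny_corpus, order=2, smoothing={"add_k": 0.0})


def _random_tiny_instance(rng, max_vocab=6, max_n=4):
    """Random small n-gram model + policy + scored position, for oracle tests."""
    v = int(rng.integers(3, max_vocab + 1))
    vocab = [f"w{i}" for i in range(v)]
    n = int(rng.integers(2, max_n + 1))
    # random corpus over the vocab
    sents = []
    for _ in range(30):
        ln = int(rng.integers(2, 6))
        sents.append(tuple(vocab[i] for i in rng.integers(0, v, size=ln)))
    corpus = lx.CorpusSample(tuple(sents), seed=0, grammar_digest="rand")
    lm = lx.fit_ngram(corpus, order=2, smoothing={"add_k": 0.2})
    kind = rng.integers(0, 3)
    if kind == 0:
        policy = lx.UniformPolicy(float(rng.uniform(0.2, 0.8)), n)
    elif kind == 1:
        policy = lx.WindowPolicy(int(rng.integers(1, n)), n)
    else:
        table = rng.uniform(0.1, 0.9, size=(v, n))
        policy = lx.TabularPolicy(vocab, table, n)
    tokens = tuple(vocab[i] for i in rng.integers(0, v, size=n + 1))
    return lm, policy, tokens, n


@pytest.fixture(scope="session")
def random_tiny_instances():
    rng = np.random.default_rng(2024)
    return [_random_tiny_instance(rng) for _ in range(50)]


# --------------------------------------------------------------------------
# default study setup (expensive; built once per session)

N = 12
DELTA_MID = 6.0
CORPUS_SEED = 11
TRAIN_SEED = 5


@pytest.fixture(scope="session")
def grammar():
    return lx.build_default_grammar()


@pytest.fixture(scope="session")
def prior(grammar):
    return lx.EnumerativeGrammarPrior(grammar)


@pytest.fixture(scope="session")
def corpus(grammar):
    return lx.generate_corpus(grammar, 3000, seed=CORPUS_SEED)


@pytest.fixture(scope="session")
def stimuli(grammar):
    return lx.generate_stimuli(grammar)


@pytest.fixture(scope="session")
def train_settings():
    return lx.InferenceSettings(method="is", n_particles=64)


@pytest.fixture(scope="session")
def trained_policies(prior, corpus, train_settings):
    """Policies optimized at low / featured / full retention bounds."""
    out = {}
    for delta in (2.0, DELTA_MID, float(N)):
        cfg = lx.TrainingConfig(
            delta=delta, n=N, seed=TRAIN_SEED, inference=train_settings
        )
        out[delta], _ = lx.train_policy(prior, corpus, cfg)
    return out


@pytest.fixture(scope="session")
def experiment_result(prior, stimuli, trained_policies):
    policies = {f"trained@{d}": (p, d) for d, p in trained_policies.items()}
    return lx.run_reading_time_experiment(
        prior,
        policies,
        stimuli,
        settings=lx.InferenceSettings(method="is", n_particles=128),
        n_masks=64,
        seed=4,
    )
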