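"""Priors: n-gram counts, enumerative grammar process, embedding bias."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lossyctx as lx
from lossyctx.exceptions import ConfigurationError, UndefinedBiasError, VocabularyError
from lossyctx.grammar import language
from lossyctx.lm import BOS


def _idx(lm, tok):
    return lm.compiled.index[tok]


# --------------------------------------------------------------------------
# n-gram fitting


def test_bigram_hand_counts(tiny_bigram_exact):
    # stream a b a b b a: after "a" always "b" (2/2), after "b": a 2/3, b 1/3
    lm = tiny_bigram_exact
    d = lm.next_dist(["a"])
    assert np.isclose(d[_idx(lm, "b")], 1.0)
    d = lm.next_dist(["x", "b"][1:])  # plain ["b"]
    assert np.isclose(d[_idx(lm, "a")], 2 / 3)


def test_bigram_conditional_seven_of_ten():
    sents = tuple([("the", "fact")] * 7 + [("the", "story")] * 3)
    lm = lx.fit_ngram(lx.CorpusSample(sents, 0, "x"), 2, {"add_k": 0.0})
    assert np.isclose(lm.next_dist(["the"])[_idx(lm, "fact")], 0.7)


def test_fit_is_deterministic(tiny_corpus):
    a = lx.fit_ngram(tiny_corpus, 2)
    b = lx.fit_ngram(tiny_corpus, 2)
    assert a.counts == b.counts and a.vocabulary == b.vocabulary


def test_fit_rejects_bad_inputs(tiny_corpus):
    with pytest.raises(ConfigurationError):
        lx.fit_ngram(lx.CorpusSample((), 0, "x"), 2)
    with pytest.raises(ConfigurationError):
        lx.fit_ngram(tiny_corpus, 99)
    with pytest.raises(ConfigurationError):
        lx.NGramModel(0, {}, ["a"])


def test_uniform_model_surprisal_and_logprob():
    vocab = [f"w{i}" for i in range(8)]
    lm = lx.NGramModel(1, {}, vocab, add_k=1.0)
    assert np.allclose(lm.next_dist([]), 1 / 8)
    assert np.isclose(lm.sequence_logprob(vocab[:3]), 3 * np.log(1 / 8))
    assert np.isclose(lx.plain_surprisal(lm, ["w0"], 0), np.log(8))


def test_deterministic_continuation_zero_surprisal(tiny_bigram_exact):
    assert lx.plain_surprisal(tiny_bigram_exact, ["a", "b"], 1) == pytest.approx(0.0)


def test_empty_sequence_logprob_is_zero(tiny_bigram):
    assert tiny_bigram.sequence_logprob([]) == 0.0
    assert tiny_bigram.sequence_logprob([BOS, BOS]) == 0.0


def test_logprob_monotone_under_extension(tiny_bigram):
    lp2 = tiny_bigram.sequence_logprob(["a", "b"])
    lp3 = tiny_bigram.sequence_logprob(["a", "b", "a"])
    assert lp3 <= lp2 <= 0.0


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.lists(st.sampled_from(["a", "b"]), min_size=0, max_size=5))
def test_next_dist_normalized_and_joint_consistent(prefix):
    corpus = lx.CorpusSample((("a", "b", "a"), ("b", "b", "a")), 0, "tiny")
    lm = lx.fit_ngram(corpus, 2, {"add_k": 0.1})
    d = lm.next_dist(prefix)
    assert d.min() > 0 and abs(d.sum() - 1.0) < 1e-9
    # joint equals the product of conditionals
    joint = lm.sequence_logprob(prefix)
    step = sum(
        np.log(lm.next_dist(prefix[:i])[_idx(lm, prefix[i])]) for i in range(len(prefix))
    )
    assert np.isclose(joint, step)


def test_unknown_token_raises(tiny_bigram):
    with pytest.raises(VocabularyError):
        tiny_bigram.next_dist(["zzz"])
    with pytest.raises(VocabularyError):
        tiny_bigram.sequence_logprob(["a", BOS, "b"])  # pad not at the left edge
    with pytest.raises(IndexError):
        lx.plain_surprisal(tiny_bigram, ["a"], 3)


def test_trigram_compiles_and_normalizes(tiny_corpus):
    lm = lx.fit_ngram(tiny_corpus, 3, {"add_k": 0.5})
    for prefix in ([], ["a"], ["a", "b"], ["b", "b", "a"]):
        d = lm.next_dist(prefix)
        assert abs(d.sum() - 1.0) < 1e-9


# --------------------------------------------------------------------------
# enumerative grammar prior


@pytest.fixture(scope="module")
def small_prior():
    g = lx.build_default_grammar(
        {
            "complement_probs": {"fact": 0.7, "report": 0.007},
            "human_nouns": ["doctor", "diplomat"],
            "proper_names": [],
            "relativizer_probs": {"who": 1.0},
            "transitive_verbs": {"annoyed": ["abstract", "human"], "cured": ["human"]},
            "intransitive_verbs": {"mattered": ["abstract", "human"]},
            "verb_weights": {},
            "pp_probs": {"by": 0.1},
            "verb_preference": {},
        }
    )
    return g, lx.EnumerativeGrammarPrior(g, smoothing_eps=1e-4)


def test_enumerative_prefix_mass_is_one(small_prior):
    _, prior = small_prior
    vocab = prior.vocabulary
    total = 0.0
    for a in vocab:
        for b in vocab:
            total += np.exp(prior.sequence_logprob([a, b]))
    assert abs(total - 1.0) < 1e-9


def test_enumerative_matches_bruteforce_conditional(small_prior):
    """Next-token distribution equals the ratio of enumerated prefix masses."""
    g, prior = small_prior
    lang = language(g)
    prefix = ("the", "fact", "that", "the", "doctor")
    mass = sum(p for t, p in lang if t[: len(prefix)] == prefix)
    nxt = {}
    for t, p in lang:
        if t[: len(prefix)] == prefix and len(t) > len(prefix):
            nxt[t[len(prefix)]] = nxt.get(t[len(prefix)], 0.0) + p
    d = prior.next_dist(list(prefix))
    eps, v = prior.smoothing_eps, len(prior.vocabulary)
    for tok, m in nxt.items():
        expected = (1 - eps) * m / mass + eps / v
        assert np.isclose(d[_idx(prior, tok)], expected)


def test_enumerative_resets_at_sentence_boundary(small_prior):
    _, prior = small_prior
    after = prior.next_dist(["the", "fact", "mattered", "."])
    initial = prior.next_dist([])
    assert np.allclose(after, initial)


def test_plain_surprisal_on_stimulus_matches_enumeration(grammar, prior, stimuli):
    item = next(i for i in stimuli if i.condition == "Three")
    lang = language(grammar)
    prefix = item.tokens[: item.critical_index]
    mass = sum(p for t, p in lang if t[: len(prefix)] == prefix)
    hit = sum(
        p
        for t, p in lang
        if t[: len(prefix) + 1] == prefix + (item.critical_word,)
    )
    eps, v = prior.smoothing_eps, len(prior.vocabulary)
    expected = -np.log((1 - eps) * hit / mass + eps / v)
    assert np.isclose(lx.plain_surprisal(prior, item.tokens, item.critical_index), expected)


# --------------------------------------------------------------------------
# embedding bias


def test_embedding_bias_corpus_hand_counts():
    sents = tuple([("the", "fact", "that")] * 70 + [("the", "fact", "x")] * 30)
    corpus = lx.CorpusSample(sents, 0, "x")
    assert np.isclose(lx.embedding_bias(corpus, "fact"), np.log(0.7))


def test_embedding_bias_smoothing_formula():
    fillers = tuple((f"t{i}",) for i in range(46))  # 46 + the/noun/x/that = 50 types
    sents = tuple([("the", "noun", "x")] * 100) + fillers + (("that",), ("x",))
    corpus = lx.CorpusSample(sents, 0, "x")
    assert len(corpus.vocabulary) == 50
    assert np.isclose(lx.embedding_bias(corpus, "noun", add_k=1.0), np.log(1 / 150))
    with pytest.raises(UndefinedBiasError):
        lx.embedding_bias(corpus, "noun", add_k=0.0)


def test_embedding_bias_lm_mode_matches_grammar(grammar, prior):
    for noun in ("fact", "report"):
        lm_bias = lx.embedding_bias(prior, noun)
        true = lx.true_embedding_bias(grammar, noun)
        assert abs(lm_bias - true) < 0.02  # smoothing-mass wiggle only
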