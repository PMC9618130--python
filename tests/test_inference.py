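"""Posterior reconstruction and lossy surprisal against exact oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lossyctx as lx
from lossyctx.exceptions import BudgetExceededError, ConfigurationError
from lossyctx.inference import ensemble_next_dist
from lossyctx.lm import BOS
from lossyctx.retention import ERASED, LossyRepresentation, apply_mask, pad_context

EXACT = lx.InferenceSettings(method="exact")


@pytest.fixture(scope="module")
def abx_bigram():
    """Bigram on a tiny corpus; conditionals strictly positive (add-k)."""
    sents = (("a", "b", "a"), ("b", "b", "a"), ("a", "a", "b"))
    return lx.fit_ngram(lx.CorpusSample(sents, 0, "x"), 2, {"add_k": 0.2})


# --------------------------------------------------------------------------
# channel


def test_channel_likelihood_values():
    pol = lx.UniformPolicy(0.5, 3)
    c = ("a", "b", "a")
    assert lx.channel_likelihood(pol, c, LossyRepresentation(("a", ERASED, ERASED))) == 0.125
    assert lx.channel_likelihood(pol, c, LossyRepresentation(("b", ERASED, ERASED))) == 0.0
    assert lx.channel_likelihood(lx.all_retain(3), c, LossyRepresentation(c)) == 1.0
    with pytest.raises(ConfigurationError):
        lx.channel_likelihood(pol, c, LossyRepresentation(("a", ERASED)))


def test_channel_is_a_distribution_over_traces():
    pol = lx.TabularPolicy(["a", "b"], np.array([[0.3, 0.6, 0.9], [0.2, 0.5, 0.8]]), 3)
    c = ("a", "b", "a")
    total = 0.0
    for bits in itertools.product([True, False], repeat=3):
        total += lx.channel_likelihood(pol, c, apply_mask(c, np.array(bits)))
    assert abs(total - 1.0) < 1e-12


# --------------------------------------------------------------------------
# posteriors


def test_exact_posterior_no_erasure_is_point_mass(abx_bigram):
    c_prime = LossyRepresentation(("a", "b", "a"))
    ens = lx.exact_posterior(abx_bigram, lx.UniformPolicy(0.7, 3), c_prime)
    assert len(ens) == 1 and np.isclose(ens.weights[0], 1.0)
    assert ens.contexts[0] == ("a", "b", "a")


def test_exact_posterior_hand_bayes():
    """One erased cell, two-word vocab: posterior computed by hand."""
    sents = (("a", "b"), ("b", "b"), ("a", "a"), ("a", "b"))
    lm = lx.fit_ngram(lx.CorpusSample(sents, 0, "x"), 2, {"add_k": 0.0})
    q = 0.6
    pol = lx.UniformPolicy(q, 2)
    c_prime = LossyRepresentation((ERASED, "b"))
    ens = lx.exact_posterior(lm, pol, c_prime)
    # weights ∝ P(c1) P(b|c1) — the channel factor is identical across candidates
    w = {}
    for c1 in ("a", "b"):
        p1 = np.exp(lm.sequence_logprob([c1]))
        w[c1] = p1 * lm.next_dist([c1])[lm.compiled.index["b"]]
    expected_a = w["a"] / (w["a"] + w["b"])
    got = dict(zip([c[0] for c in ens.contexts], ens.weights))
    assert np.isclose(got["a"], expected_a)
    assert ens.check_support(c_prime)


def test_exact_posterior_budget_error(abx_bigram):
    c_prime = LossyRepresentation((ERASED,) * 3)
    with pytest.raises(BudgetExceededError, match="importance sampling"):
        lx.exact_posterior(abx_bigram, lx.UniformPolicy(0.5, 3), c_prime, enumeration_budget=4)


def test_posterior_prefers_prior_likely_completion(prior):
    """Erasing the complementizer after a high-bias noun: the top candidate
    restores it."""
    ctx = pad_context(("the", "fact", "that", "the", "doctor", "annoyed", "the", "senator"), 12)
    mask = np.ones(12, dtype=bool)
    mask[6] = False  # the "that" cell
    ens = lx.exact_posterior(prior, lx.UniformPolicy(0.5, 12), apply_mask(ctx, mask))
    top = ens.contexts[int(np.argmax(ens.weights))]
    assert top[6] == "that"
    assert ens.check_support(apply_mask(ctx, mask))


def test_is_posterior_no_erasure(abx_bigram):
    c_prime = LossyRepresentation(("a", "b", "a"))
    rng = np.random.default_rng(0)
    ens = lx.is_posterior(abx_bigram, lx.UniformPolicy(0.7, 3), c_prime, 64, rng)
    assert ens.effective_sample_size == pytest.approx(64)
    assert all(c == ("a", "b", "a") for c in ens.contexts)


def test_is_posterior_deterministic_under_seed(abx_bigram):
    c_prime = LossyRepresentation(("a", ERASED, ERASED))
    pol = lx.UniformPolicy(0.5, 3)
    e1 = lx.is_posterior(abx_bigram, pol, c_prime, 128, np.random.default_rng(5))
    e2 = lx.is_posterior(abx_bigram, pol, c_prime, 128, np.random.default_rng(5))
    assert e1.contexts == e2.contexts
    assert np.allclose(e1.weights, e2.weights)


def test_is_posterior_marginals_match_exact(abx_bigram):
    """|V|=4, two erased cells, 10^4 particles vs exact enumeration."""
    vocab = abx_bigram.vocabulary
    pol = lx.TabularPolicy(
        vocab, np.random.default_rng(1).uniform(0.2, 0.8, size=(len(vocab), 3)), 3
    )
    c_prime = LossyRepresentation((ERASED, "b", ERASED))
    exact = lx.exact_posterior(abx_bigram, pol, c_prime)
    rng = np.random.default_rng(7)
    approx = lx.is_posterior(abx_bigram, pol, c_prime, 10_000, rng)
    for pos in (0, 2):
        m_exact = exact.marginal(pos, vocab)
        m_is = approx.marginal(pos, vocab)
        se = np.sqrt(m_exact * (1 - m_exact) / approx.effective_sample_size)
        assert np.all(np.abs(m_is - m_exact) <= 3 * se + 1e-3)


# --------------------------------------------------------------------------
# lossy next-word distribution and surprisal


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 2**3 - 1), st.floats(0.2, 0.8))
def test_next_dist_lossy_normalized(mask_bits, q):
    sents = (("a", "b", "a"), ("b", "b", "a"), ("a", "a", "b"))
    lm = lx.fit_ngram(lx.CorpusSample(sents, 0, "x"), 2, {"add_k": 0.2})
    mask = np.array([(mask_bits >> i) & 1 for i in range(3)], dtype=bool)
    c_prime = apply_mask(("a", "b", "a"), mask)
    d = lx.next_dist_lossy(lm, lx.UniformPolicy(q, 3), c_prime, EXACT)
    assert abs(d.sum() - 1.0) < 1e-9 and d.min() > 0


def test_all_retain_next_dist_equals_veridical(abx_bigram):
    ctx = ("a", "b", "a")
    d = lx.next_dist_lossy(abx_bigram, lx.all_retain(3), LossyRepresentation(ctx), EXACT)
    assert np.allclose(d, abx_bigram.next_dist(ctx))


def test_all_erased_single_cell_hand_mixture(abx_bigram):
    """N=1, everything erased: mixture sum_c P(c) P(w|c), by hand."""
    d = lx.next_dist_lossy(
        abx_bigram, lx.all_erase(1), LossyRepresentation((ERASED,)), EXACT
    )
    vocab = abx_bigram.vocabulary
    expected = np.zeros(len(vocab))
    for i, c in enumerate(vocab):
        expected += np.exp(abx_bigram.sequence_logprob([c])) * abx_bigram.next_dist([c])
    assert np.allclose(d, expected)


def test_lossy_equals_plain_under_all_retain(prior, stimuli):
    item = stimuli[0]
    est = lx.lossy_surprisal(
        prior, lx.all_retain(12), item.scored_tokens, item.scored_index, settings=EXACT
    )
    assert est.method == "exact" and est.mc_standard_error == 0.0
    assert abs(est.mean_nats - lx.plain_surprisal(prior, item.scored_tokens, item.scored_index)) < 1e-9


def test_all_erase_equals_prior_predictive(abx_bigram):
    """Full enumeration oracle for the zero-retention limit."""
    tokens = ("a", "b", "b", "a")
    est = lx.lossy_surprisal(abx_bigram, lx.all_erase(3), tokens, 3, settings=EXACT)
    vocab = abx_bigram.vocabulary
    total = 0.0
    for c in itertools.product(vocab, repeat=3):
        total += np.exp(abx_bigram.sequence_logprob(list(c))) * abx_bigram.next_dist(
            list(c)
        )[abx_bigram.compiled.index["a"]]
    assert abs(est.mean_nats - (-np.log(total))) < 1e-9


def test_exact_masks_are_weighted_by_channel_probability(abx_bigram):
    """Exact expectation equals the hand sum over all masks."""
    v = len(abx_bigram.vocabulary)
    pol = lx.TabularPolicy(
        abx_bigram.vocabulary,
        np.random.default_rng(3).uniform(0.2, 0.8, (v, 3)),
        3,
    )
    tokens = ("a", "b", "a", "b")
    est = lx.lossy_surprisal(abx_bigram, pol, tokens, 3, settings=EXACT)
    ctx = tokens[:3]
    q = pol.q_vector(ctx)
    total = 0.0
    for bits in itertools.product([True, False], repeat=3):
        p_mask = np.prod(np.where(bits, q, 1 - q))
        d = lx.next_dist_lossy(abx_bigram, pol, apply_mask(ctx, np.array(bits)), EXACT)
        total += p_mask * -np.log(d[abx_bigram.compiled.index["b"]])
    assert abs(est.mean_nats - total) < 1e-9


def test_is_estimate_matches_exact_within_error(abx_bigram):
    pol = lx.UniformPolicy(0.5, 3)
    tokens = ("a", "b", "a", "b")
    exact = lx.lossy_surprisal(abx_bigram, pol, tokens, 3, settings=EXACT)
    est = lx.lossy_surprisal(
        abx_bigram, pol, tokens, 3, n_masks=400,
        settings=lx.InferenceSettings(method="is", n_particles=2000),
        rng=np.random.default_rng(11),
    )
    assert abs(est.mean_nats - exact.mean_nats) <= 3 * est.mc_standard_error


def test_window_information_monotonicity(abx_bigram):
    """Expected lossy surprisal under the model's own data distribution is
    non-increasing in the window size K (wider windows carry strictly more
    information about the true context)."""
    lm = abx_bigram
    vocab = lm.vocabulary
    pairs = []  # (context, target, probability under the model)
    for c in itertools.product(vocab, repeat=3):
        pc = np.exp(lm.sequence_logprob(list(c)))
        nxt = lm.next_dist(list(c))
        for w in vocab:
            pairs.append((c, w, pc * nxt[lm.compiled.index[w]]))
    means = []
    for k in range(0, 4):
        pol = lx.WindowPolicy(k, 3)
        total = sum(
            p * lx.lossy_surprisal(lm, pol, c + (w,), 3, settings=EXACT).mean_nats
            for c, w, p in pairs
        )
        means.append(total)
    assert all(means[i + 1] <= means[i] + 1e-9 for i in range(3))


def test_grammatical_continuation_prob(abx_bigram):
    prefix = ("a", "b", "a")
    full = lx.grammatical_continuation_prob(
        abx_bigram, lx.all_retain(3), prefix, abx_bigram.vocabulary, EXACT
    )
    assert np.isclose(full, 1.0)
    verid = lx.grammatical_continuation_prob(
        abx_bigram, lx.all_retain(3), prefix, ["a"], EXACT
    )
    assert np.isclose(verid, abx_bigram.next_dist(prefix)[abx_bigram.compiled.index["a"]])
    with pytest.raises(ConfigurationError):
        lx.grammatical_continuation_prob(abx_bigram, lx.all_retain(3), prefix, [], EXACT)


def test_lossy_nonverb_mass_rises_when_structure_is_erased(grammar, prior):
    """Erasing the complementizer region moves probability to non-verb
    continuations relative to the veridical context."""
    item = next(
        i for i in lx.generate_stimuli(grammar)
        if i.condition == "Three" and i.noun_id == "report" and i.compatibility == "Compatible"
    )
    ctx = pad_context(item.tokens[: item.critical_index], 12)
    verbs = [prior.compiled.index[v] for v in grammar.verbs()]
    veridical = prior.next_dist(ctx)
    mask = np.ones(12, dtype=bool)
    mask[[0, 1, 2, 5]] = [True, True, False, False]  # erase "that" and "who"
    rng = np.random.default_rng(2)
    lossy = lx.next_dist_lossy(
        prior, lx.UniformPolicy(0.5, 12), apply_mask(ctx, mask),
        lx.InferenceSettings(method="is", n_particles=4000), rng,
    )
    nonverb = lambda d: 1.0 - sum(d[v] for v in verbs)
    assert nonverb(lossy) > nonverb(veridical)
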