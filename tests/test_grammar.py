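"""Generator: exact probabilities, stimulus construction, serialization."""

import collections

import numpy as np
import pytest
from scipy.stats import chisquare

import lossyctx as lx
from lossyctx.exceptions import ConfigurationError, StimulusDesignError
from lossyctx.grammar import (
    annotate_stimulus,
    embedding_depth,
    language,
    save_stimuli,
    load_stimuli,
    stimuli_to_frame,
)

TINY_CONFIG = {
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


@pytest.fixture(scope="module")
def tiny_grammar():
    return lx.build_default_grammar(TINY_CONFIG)


def test_language_probabilities_sum_to_one(tiny_grammar):
    probs = [p for _, p in language(tiny_grammar)]
    assert abs(sum(probs) - 1.0) < 1e-9
    assert min(probs) > 0


def test_rule_probabilities_sum_to_one(grammar):
    by_lhs = collections.defaultdict(float)
    for lhs, _, p in grammar.rules:
        by_lhs[lhs] += p
    for lhs, total in by_lhs.items():
        assert abs(total - 1.0) < 1e-12, lhs


def test_complement_prob_validation():
    with pytest.raises(ConfigurationError, match="complement_probs"):
        lx.build_default_grammar({"complement_probs": {"fact": 1.5}})
    with pytest.raises(ConfigurationError, match="unknown grammar config"):
        lx.build_default_grammar({"nonsense_field": 1})


def test_relativization_zero_removes_deepest_structures(tiny_grammar):
    g0 = lx.build_default_grammar({**TINY_CONFIG, "relativization_prob": 0.0})
    depths = {embedding_depth(t) for t, _ in language(g0)}
    assert 3 not in depths
    assert 2 in depths  # complement clauses alone still give depth two
    assert 3 in {embedding_depth(t) for t, _ in language(tiny_grammar)}


def test_deeper_embeddings_are_rarer(grammar):
    mass = collections.defaultdict(float)
    for tokens, p in language(grammar):
        mass[min(embedding_depth(tokens), 3)] += p
    assert mass[1] > mass[2] > mass[3] > 0


def test_corpus_seeded_determinism_and_no_commas(grammar):
    c1 = lx.generate_corpus(grammar, 100, seed=7)
    c2 = lx.generate_corpus(grammar, 100, seed=7)
    assert c1.sentences == c2.sentences
    assert all("," not in t for s in c1.sentences for t in s)
    assert all(s[-1] == "." for s in c1.sentences)
    with pytest.raises(ConfigurationError):
        lx.generate_corpus(grammar, 0, seed=1)


def test_corpus_complement_fraction_matches_grammar(grammar):
    corpus = lx.generate_corpus(grammar, 10_000, seed=3)
    b = grammar.noun_lexicon["fact"].complement_prob
    n_bigram = n_that = 0
    for s in corpus.sentences:
        for i in range(len(s) - 1):
            if s[i] == "the" and s[i + 1] == "fact":
                n_bigram += 1
                n_that += int(i + 2 < len(s) and s[i + 2] == "that")
    frac = n_that / n_bigram
    se = np.sqrt(b * (1 - b) / n_bigram)
    assert abs(frac - b) < 3 * se


def test_degenerate_grammar_yields_identical_sentences():
    g = lx.build_default_grammar(
        {
            "complement_probs": {"fact": 0.5},  # unused: abstract share is zero
            "human_nouns": ["doctor"],
            "proper_names": [],
            "transitive_verbs": {},
            "intransitive_verbs": {"mattered": ["human"]},
            "pp_probs": {},
            "relativization_prob": 0.0,
            "abstract_subject_prob": 0.0,
            "verb_preference": {},
            "verb_weights": {},
        }
    )
    corpus = lx.generate_corpus(g, 50, seed=1)
    assert set(corpus.sentences) == {("the", "doctor", "mattered", ".")}


def test_generated_sentences_are_derivable(grammar, stimuli):
    lang = {t for t, _ in language(grammar)}
    corpus = lx.generate_corpus(grammar, 500, seed=9)
    assert all(s in lang for s in corpus.sentences)
    assert all(item.tokens in lang for item in stimuli)


def test_initial_trigram_frequencies_match_analytic(tiny_grammar):
    """Chi-square goodness of fit of sentence-initial 3-gram counts."""
    analytic = collections.defaultdict(float)
    for tokens, p in language(tiny_grammar):
        analytic[tokens[:3]] += p
    corpus = lx.generate_corpus(tiny_grammar, 8000, seed=5)
    counts = collections.Counter(s[:3] for s in corpus.sentences)
    keys = [k for k, p in analytic.items() if p * 8000 >= 5]
    obs = np.array([counts.get(k, 0) for k in keys], dtype=float)
    exp = np.array([analytic[k] * 8000 for k in keys])
    # pool the remainder so totals match
    obs = np.append(obs, 8000 - obs.sum())
    exp = np.append(exp, 8000 - exp.sum())
    stat, pval = chisquare(obs, exp)
    assert pval > 0.01


# --------------------------------------------------------------------------
# stimuli


def test_full_crossing_counts(grammar):
    items = lx.generate_stimuli(grammar)
    # 8 frames x 8 nouns x (One + {Two,Three} x {Compatible,Incompatible})
    assert len(items) == 8 * 8 * 5
    design = dict(lx.default_design(grammar))
    design["frames"] = design["frames"][:4]
    design["nouns"] = design["nouns"][:4]
    design["compatibility"] = None
    items = lx.generate_stimuli(grammar, design)
    assert len(items) == 48
    per_cond = collections.Counter(i.condition for i in items)
    assert per_cond == {"One": 16, "Two": 16, "Three": 16}


def test_stimulus_token_patterns(grammar):
    items = lx.generate_stimuli(grammar)
    verbs = set(grammar.verbs())
    for item in items:
        assert item.tokens[item.critical_index] in verbs
        n_verbs = sum(1 for t in item.tokens if t in verbs)
        assert n_verbs == {"One": 1, "Two": 2, "Three": 3}[item.condition]
    two = next(i for i in items if i.condition == "Two" and i.noun_id == "report")
    assert two.tokens[:5] == ("the", "report", "that", "the", two.tokens[4])


def test_incompatible_items_exclude_outer_subject_class(grammar):
    for item in lx.generate_stimuli(grammar):
        v2 = item.tokens[item.critical_index - 3]  # ... v2 the obj v1
        if item.compatibility == "Incompatible":
            assert "abstract" not in grammar.verb_lexicon[v2].subject_classes
        elif item.compatibility == "Compatible":
            assert "abstract" in grammar.verb_lexicon[v2].subject_classes


def test_frame_condition_incompatibility_error(grammar):
    design = dict(lx.default_design(grammar))
    design["nouns"] = ["doctor"]  # not an abstract noun
    with pytest.raises(StimulusDesignError, match="f1.*One"):
        lx.generate_stimuli(grammar, design)


def test_lead_tokens_fill_context_window(grammar, stimuli):
    for item in stimuli:
        assert len(item.lead_tokens) + item.critical_index == 12
        assert item.scored_tokens[item.scored_index] == item.critical_word
        if item.lead_tokens:
            assert item.lead_tokens[-1] == "."


def test_stimuli_tsv_roundtrip(tmp_path, grammar, stimuli):
    path = tmp_path / "stimuli.tsv"
    save_stimuli(stimuli, path)
    loaded = load_stimuli(path)
    assert loaded == stimuli
    frame = stimuli_to_frame(stimuli)
    assert set(frame.columns) >= {"item_id", "condition", "compatibility", "noun_id",
                                  "tokens", "critical_index", "preamble_end"}


# --------------------------------------------------------------------------
# embedding bias and serialization


def test_true_embedding_bias_equals_log_complement_prob(grammar):
    assert np.isclose(lx.true_embedding_bias(grammar, "fact"), np.log(0.7))
    assert np.isclose(lx.true_embedding_bias(grammar, "report"), np.log(0.007))
    with pytest.raises(lx.exceptions.VocabularyError):
        lx.true_embedding_bias(grammar, "unicorn")


def test_equal_rules_give_equal_biases():
    cfg = dict(TINY_CONFIG)
    cfg["complement_probs"] = {"fact": 0.3, "claim": 0.3}
    g = lx.build_default_grammar(cfg)
    assert np.isclose(
        lx.true_embedding_bias(g, "fact"), lx.true_embedding_bias(g, "claim")
    )


def test_bias_independent_of_relativization_with_distinct_relativizer():
    biases = []
    for r in (0.0, 0.4):
        g = lx.build_default_grammar({**TINY_CONFIG, "relativization_prob": r})
        biases.append(lx.true_embedding_bias(g, "fact"))
    assert np.isclose(biases[0], biases[1])


def test_grammar_json_roundtrip_and_digest(grammar):
    clone = lx.GrammarSpec.from_json(grammar.to_json())
    assert clone.checksum == grammar.checksum
    assert clone.noun_lexicon == dict(grammar.noun_lexicon)
    other = lx.build_default_grammar({"relativization_prob": 0.11})
    assert other.checksum != grammar.checksum


def test_dependency_annotations_by_condition(grammar, stimuli):
    for item in stimuli:
        ann = annotate_stimulus(item)
        assert len(ann.heads) == len(item.tokens)
        assert ann.heads[item.critical_index] == -1  # critical verb is the root
        assert ann.referent[item.critical_index]
        # nouns and verbs are referents; determiners/markers are not
        verbs, nouns = set(grammar.verbs()), set(grammar.noun_lexicon)
        for tok, flag in zip(item.tokens, ann.referent):
            assert flag == (tok in verbs or tok in nouns)
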