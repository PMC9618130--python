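"""Probabilistic grammar for center-embedded stimuli and training corpora.

The generator produces a small English-like fragment with the statistical
structure that drives difficulty in nested relative-clause / complement-clause
sentences:

* abstract nouns differ in *embedding bias* — the probability that the noun
  takes a "that"-complement clause ("the fact that ..." is common, "the report
  that ..." is rare);
* noun phrases can host object relative clauses ("the doctor who the diplomat
  mistrusted"), so one, two, or three noun–verb dependencies can be open at
  once, with deeper nesting strictly rarer;
* verbs carry hard (or optionally soft) selectional restrictions on the
  semantic class of their subject, so a verb can be compatible with both the
  outer and the inner noun, or with the inner noun only;
* abstract nouns can alternatively take a prepositional modifier ("the report
  by the doctor ..."), which yields surface-similar competitor sentences that
  close with fewer verbs — the structures a noisy-memory comprehender
  confuses with the true context.

The language is finite (recursion is truncated at ``depth_cap`` by
renormalizing the rule probabilities), so sentence probabilities, next-token
distributions, and embedding biases are all exactly computable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import digest
from .exceptions import (
    ConfigurationError,
    StimulusDesignError,
    UndefinedBiasError,
    VocabularyError,
)

DET = "the"
COMPLEMENTIZER = "that"
RELATIVIZER = "who"
TERMINATOR = "."

ABSTRACT = "abstract"
HUMAN = "human"

CONDITIONS = ("One", "Two", "Three")

#: number of noun–verb dependency pairs per condition
DEPTH_OF_CONDITION = {"One": 1, "Two": 2, "Three": 3}


@dataclass(frozen=True)
class NounEntry:
    semantic_class: str
    complement_prob: float | None = None  # P(that-clause | noun); abstract only
    weight: float = 1.0
    bare: bool = False  # proper name: realized without a determiner


@dataclass(frozen=True)
class VerbEntry:
    subject_classes: frozenset
    transitive: bool
    weight: float = 1.0


@dataclass(frozen=True)
class GrammarSpec:
    """Finite probabilistic grammar over a small lexicon.

    ``noun_lexicon`` maps nouns to their semantic class, weight (relative
    frequency within the class), and — for abstract nouns — the probability of
    a "that"-complement. ``verb_lexicon`` carries subject-class compatibility
    sets. ``pp_probs`` gives per-preposition probabilities of a prepositional
    post-nominal modifier on abstract nouns. Relative clauses attach to human
    noun phrases with probability ``relativization_prob`` while the clause
    depth stays below ``depth_cap``; at the cap the remaining options are
    renormalized.
    """

    noun_lexicon: Mapping[str, NounEntry]
    verb_lexicon: Mapping[str, VerbEntry]
    relativization_prob: float = 0.2
    relativizer_probs: Mapping[str, float] = field(
        default_factory=lambda: {RELATIVIZER: 1.0}
    )
    pp_probs: Mapping[str, float] = field(default_factory=dict)
    abstract_subject_prob: float = 0.5
    depth_cap: int = 3
    soft_incompatibility: float = 0.0
    verb_preference: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    sentence_terminator: str = TERMINATOR

    # -- validation ----------------------------------------------------------
    def __post_init__(self):
        for noun, entry in self.noun_lexicon.items():
            if entry.semantic_class not in (ABSTRACT, HUMAN):
                raise ConfigurationError(
                    f"noun_lexicon[{noun!r}].semantic_class: unknown class "
                    f"{entry.semantic_class!r}"
                )
            if entry.semantic_class == ABSTRACT:
                p = entry.complement_prob
                if p is None or not (0.0 < p < 1.0):
                    raise ConfigurationError(
                        f"noun_lexicon[{noun!r}].complement_prob: must lie in (0,1), "
                        f"got {p!r}"
                    )
                slack = p + sum(self.pp_probs.values())
                if slack >= 1.0:
                    raise ConfigurationError(
                        f"noun_lexicon[{noun!r}].complement_prob: complement + PP "
                        f"probability mass {slack} >= 1"
                    )
            if entry.weight <= 0:
                raise ConfigurationError(f"noun_lexicon[{noun!r}].weight: must be > 0")
        for verb, entry in self.verb_lexicon.items():
            if not entry.subject_classes:
                raise ConfigurationError(f"verb_lexicon[{verb!r}].subject_classes: empty")
            if entry.weight <= 0:
                raise ConfigurationError(f"verb_lexicon[{verb!r}].weight: must be > 0")
        if not (0.0 <= self.relativization_prob < 1.0):
            raise ConfigurationError("relativization_prob: must lie in [0,1)")
        if abs(sum(self.relativizer_probs.values()) - 1.0) > 1e-9:
            raise ConfigurationError("relativizer_probs: must sum to 1")
        for prep, p in self.pp_probs.items():
            if not (0.0 <= p < 1.0):
                raise ConfigurationError(f"pp_probs[{prep!r}]: must lie in [0,1)")
        if not (0.0 <= self.abstract_subject_prob <= 1.0):
            raise ConfigurationError("abstract_subject_prob: must lie in [0,1]")
        if self.depth_cap < 1:
            raise ConfigurationError("depth_cap: must be >= 1")
        if not (0.0 <= self.soft_incompatibility < 1.0):
            raise ConfigurationError("soft_incompatibility: must lie in [0,1)")

    # -- derived views -------------------------------------------------------
    def nouns(self, semantic_class: str) -> list[str]:
        return [n for n, e in self.noun_lexicon.items() if e.semantic_class == semantic_class]

    def verbs(self, *, transitive: bool | None = None) -> list[str]:
        return [
            v
            for v, e in self.verb_lexicon.items()
            if transitive is None or e.transitive == transitive
        ]

    @property
    def vocabulary(self) -> list[str]:
        words = [DET, COMPLEMENTIZER, RELATIVIZER, *self.pp_probs, self.sentence_terminator]
        words += list(self.noun_lexicon) + list(self.verb_lexicon)
        seen, out = set(), []
        for w in words:
            if w not in seen:
                seen.add(w)
                out.append(w)
        return out

    @property
    def nonterminals(self) -> set:
        return {"S", "NP_ABS", "NP_HUM", "NP_HUM_SIMPLE", "NP_OBJ", "VP_ABS", "VP_HUM", "S_C"}

    @property
    def rules(self) -> list[tuple]:
        """Structural productions with probabilities (lexicalized choices are
        expanded per word so each left-hand side sums to one)."""
        rules = [
            ("S", ("NP_ABS", "VP_ABS"), self.abstract_subject_prob),
            ("S", ("NP_HUM", "VP_HUM"), 1.0 - self.abstract_subject_prob),
            ("S_C", ("NP_HUM", "VP_HUM"), 1.0),
            ("NP_HUM", (DET, "N_HUM"), 1.0 - self.relativization_prob),
        ]
        for rel, p_rel in self.relativizer_probs.items():
            rules.append(
                (
                    "NP_HUM",
                    (DET, "N_HUM", rel, "NP_HUM_SIMPLE", "V_T"),
                    self.relativization_prob * p_rel,
                )
            )
        for cls, lhs in ((ABSTRACT, "N_ABS"), (HUMAN, "N_HUM")):
            names = self.nouns(cls)
            total = sum(self.noun_lexicon[n].weight for n in names)
            for n in names:
                rules.append((lhs, (n,), self.noun_lexicon[n].weight / total))
        for cls, lhs in ((ABSTRACT, "VP_ABS"), (HUMAN, "VP_HUM")):
            for verb, p in self._verb_dist(cls, subject_noun=None).items():
                rhs = (verb, "NP_OBJ") if self.verb_lexicon[verb].transitive else (verb,)
                rules.append((lhs, rhs, p))
        for noun in self.nouns(ABSTRACT):
            b = self.noun_lexicon[noun].complement_prob
            rest = 1.0 - b - sum(self.pp_probs.values())
            rules.append((f"POST[{noun}]", (), rest))
            rules.append((f"POST[{noun}]", (COMPLEMENTIZER, "S_C"), b))
            for prep, p in self.pp_probs.items():
                rules.append((f"POST[{noun}]", (prep, "NP_HUM"), p))
        return rules

    # -- probability helpers -------------------------------------------------
    def _noun_dist(self, semantic_class: str) -> dict[str, float]:
        names = self.nouns(semantic_class)
        if not names:
            raise ConfigurationError(f"noun_lexicon: no nouns of class {semantic_class!r}")
        w = np.array([self.noun_lexicon[n].weight for n in names])
        return dict(zip(names, w / w.sum()))

    def _verb_dist(
        self,
        subject_class: str,
        subject_noun: str | None,
        transitive_only: bool = False,
    ) -> dict[str, float]:
        """Distribution over verbs for a subject of the given class/identity.

        Incompatible verbs get weight 0 (hard) or a ``soft_incompatibility``
        multiplier; ``verb_preference`` rescales per subject noun.
        """
        weights = {}
        for verb, entry in self.verb_lexicon.items():
            if transitive_only and not entry.transitive:
                continue
            w = entry.weight
            if subject_class not in entry.subject_classes:
                w *= self.soft_incompatibility
            if subject_noun is not None:
                w *= self.verb_preference.get(subject_noun, {}).get(verb, 1.0)
            if w > 0:
                weights[verb] = w
        if not weights:
            raise ConfigurationError(
                f"verb_lexicon: no verb admits a {subject_class!r} subject"
            )
        total = sum(weights.values())
        return {v: w / total for v, w in weights.items()}

    def to_json(self) -> str:
        obj = {
            "noun_lexicon": {
                n: {
                    "semantic_class": e.semantic_class,
                    "complement_prob": e.complement_prob,
                    "weight": e.weight,
                    "bare": e.bare,
                }
                for n, e in self.noun_lexicon.items()
            },
            "verb_lexicon": {
                v: {
                    "subject_classes": sorted(e.subject_classes),
                    "transitive": e.transitive,
                    "weight": e.weight,
                }
                for v, e in self.verb_lexicon.items()
            },
            "relativization_prob": self.relativization_prob,
            "relativizer_probs": dict(self.relativizer_probs),
            "pp_probs": dict(self.pp_probs),
            "abstract_subject_prob": self.abstract_subject_prob,
            "depth_cap": self.depth_cap,
            "soft_incompatibility": self.soft_incompatibility,
            "verb_preference": {n: dict(d) for n, d in self.verb_preference.items()},
            "sentence_terminator": self.sentence_terminator,
        }
        return json.dumps(obj, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GrammarSpec":
        obj = json.loads(text)
        return cls(
            noun_lexicon={
                n: NounEntry(
                    d["semantic_class"], d["complement_prob"], d["weight"], d.get("bare", False)
                )
                for n, d in obj["noun_lexicon"].items()
            },
            verb_lexicon={
                v: VerbEntry(frozenset(d["subject_classes"]), d["transitive"], d["weight"])
                for v, d in obj["verb_lexicon"].items()
            },
            relativization_prob=obj["relativization_prob"],
            relativizer_probs=obj.get("relativizer_probs", {RELATIVIZER: 1.0}),
            pp_probs=obj["pp_probs"],
            abstract_subject_prob=obj["abstract_subject_prob"],
            depth_cap=obj["depth_cap"],
            soft_incompatibility=obj["soft_incompatibility"],
            verb_preference=obj["verb_preference"],
            sentence_terminator=obj["sentence_terminator"],
        )

    @property
    def checksum(self) -> str:
        return digest(self.to_json())


# ---------------------------------------------------------------------------
# default configurations


DEFAULT_COMPLEMENT_PROBS = {
    # anchored to the observed range of English embedding biases:
    # ~70% for the most complement-taking nouns down to ~0.7%
    "fact": 0.70,
    "belief": 0.35,
    "claim": 0.18,
    "idea": 0.09,
    "story": 0.045,
    "rumor": 0.022,
    "statement": 0.011,
    "report": 0.007,
}

DEFAULT_CONFIG = {
    "complement_probs": DEFAULT_COMPLEMENT_PROBS,
    "human_nouns": ["doctor", "diplomat", "senator"],
    # proper names fill human-NP slots without a determiner, keeping the
    # function-word share of the language closer to natural text
    "proper_names": ["smith"],
    # object relatives are introduced by "that" or "who", as in English, so the
    # complementizer token is a genuinely frequent function word
    "relativizer_probs": {"that": 0.6, "who": 0.4},
    "transitive_verbs": {
        "annoyed": [ABSTRACT, HUMAN],
        "pleased": [ABSTRACT, HUMAN],
        "cured": [HUMAN],
        "mistrusted": [HUMAN],
    },
    "intransitive_verbs": {
        "mattered": [ABSTRACT, HUMAN],
        "failed": [ABSTRACT, HUMAN],
    },
    # intransitives down-weighted so sentences carry more material, keeping
    # the per-window density of content words closer to natural text
    "verb_weights": {"mattered": 0.6, "failed": 0.6},
    "pp_probs": {"by": 0.12, "from": 0.08},
    "relativization_prob": 0.3,
    "abstract_subject_prob": 0.5,
    "depth_cap": 3,
    "soft_incompatibility": 0.0,
    "noun_weights": {},
    # mild selectional preferences of abstract nouns for their matrix
    # predicates, emulating the lexical cohesion of natural text that makes
    # content-word identity predictively valuable at a distance; each verb is
    # preferred by one high-bias and one low-bias noun, so preferences are
    # orthogonal to embedding bias by construction
    # preference targets are the two verbs that can end a stimulus frame, and
    # the noun groups alternate in the embedding-bias ranking (group mean
    # biases -2.71 vs -2.77 nats), so preference is orthogonal to bias
    "verb_preference": {
        "fact": {"mattered": 4.0},
        "idea": {"mattered": 4.0},
        "story": {"mattered": 4.0},
        "report": {"mattered": 4.0},
        "belief": {"failed": 4.0},
        "claim": {"failed": 4.0},
        "rumor": {"failed": 4.0},
        "statement": {"failed": 4.0},
        # human subjects likewise prefer characteristic predicates
        "doctor": {"cured": 4.0},
        "diplomat": {"mistrusted": 4.0},
        "senator": {"annoyed": 4.0},
        "smith": {"pleased": 4.0},
    },
}


def build_default_grammar(config: Mapping | None = None) -> GrammarSpec:
    """Build a grammar from a flat parameter mapping (defaults above).

    ``complement_probs`` maps abstract nouns to their "that"-complement
    probability (the analytic embedding bias); ``transitive_verbs`` /
    ``intransitive_verbs`` map verbs to admissible subject classes.
    """
    cfg = dict(DEFAULT_CONFIG)
    if config:
        unknown = set(config) - set(cfg)
        if unknown:
            raise ConfigurationError(f"unknown grammar config fields: {sorted(unknown)}")
        cfg.update(config)

    noun_weights = dict(cfg["noun_weights"])
    noun_lexicon = {}
    for noun, p in cfg["complement_probs"].items():
        if not isinstance(p, (int, float)) or not (0.0 < float(p) < 1.0):
            raise ConfigurationError(f"complement_probs[{noun!r}]: must lie in (0,1), got {p!r}")
        noun_lexicon[noun] = NounEntry(ABSTRACT, float(p), noun_weights.get(noun, 1.0))
    for noun in cfg["human_nouns"]:
        noun_lexicon[noun] = NounEntry(HUMAN, None, noun_weights.get(noun, 1.0))
    for name in cfg["proper_names"]:
        noun_lexicon[name] = NounEntry(HUMAN, None, noun_weights.get(name, 1.0), bare=True)

    verb_weights = dict(cfg.get("verb_weights", {}))
    verb_lexicon = {}
    for verb, classes in cfg["transitive_verbs"].items():
        verb_lexicon[verb] = VerbEntry(frozenset(classes), True, verb_weights.get(verb, 1.0))
    for verb, classes in cfg["intransitive_verbs"].items():
        verb_lexicon[verb] = VerbEntry(frozenset(classes), False, verb_weights.get(verb, 1.0))

    return GrammarSpec(
        noun_lexicon=noun_lexicon,
        verb_lexicon=verb_lexicon,
        relativization_prob=float(cfg["relativization_prob"]),
        relativizer_probs={
            k: float(v) for k, v in cfg.get("relativizer_probs", {RELATIVIZER: 1.0}).items()
        },
        pp_probs={k: float(v) for k, v in cfg["pp_probs"].items()},
        abstract_subject_prob=float(cfg["abstract_subject_prob"]),
        depth_cap=int(cfg["depth_cap"]),
        soft_incompatibility=float(cfg["soft_incompatibility"]),
        verb_preference={n: dict(d) for n, d in cfg["verb_preference"].items()},
    )


def frequency_manipulated_config() -> dict:
    """Grammar config with matched-role frequent/rare human nouns.

    ``doctor`` (frequent) and ``diplomat`` (rare) fill the same syntactic
    slots; each sharply prefers a different transitive verb, so the noun's
    identity is predictive of later material and the value of retaining it in
    memory can differ only through its frequency.
    """
    return {
        "complement_probs": {"fact": 0.4, "claim": 0.2},
        "human_nouns": ["doctor", "diplomat"],
        "transitive_verbs": {
            "annoyed": [ABSTRACT, HUMAN],
            "cured": [HUMAN],
            "mistrusted": [HUMAN],
        },
        "intransitive_verbs": {"mattered": [ABSTRACT, HUMAN]},
        "proper_names": [],
        "noun_weights": {"doctor": 0.85, "diplomat": 0.15},
        "verb_preference": {
            "doctor": {"cured": 8.0, "mistrusted": 1.0},
            "diplomat": {"cured": 1.0, "mistrusted": 8.0},
        },
        "relativization_prob": 0.35,
        "pp_probs": {"by": 0.10},
    }


# ---------------------------------------------------------------------------
# exact enumeration of the finite language


def _combine(head_options, tail_options):
    return [
        (h_tokens + t_tokens, h_p * t_p)
        for h_tokens, h_p in head_options
        for t_tokens, t_p in tail_options
    ]


def _np_human(g: GrammarSpec, clause_depth: int, allow_rel: bool):
    """Options (tokens, prob, head_noun) for a human NP in subject position."""
    out = []
    rel_ok = allow_rel and clause_depth + 1 <= g.depth_cap and g.relativization_prob > 0
    r = g.relativization_prob if rel_ok else 0.0
    inner_nouns = g._noun_dist(HUMAN)
    for noun, p_n in g._noun_dist(HUMAN).items():
        head = (noun,) if g.noun_lexicon[noun].bare else (DET, noun)
        out.append((head, p_n * (1.0 - r), noun))
        if rel_ok:
            for rel, p_rel in g.relativizer_probs.items():
                for inner, p_i in inner_nouns.items():
                    inner_np = (
                        (inner,) if g.noun_lexicon[inner].bare else (DET, inner)
                    )
                    # object-gap relative: verb distribution over transitive verbs only
                    for verb, p_v in g._verb_dist(HUMAN, inner, transitive_only=True).items():
                        out.append(
                            (
                                head + (rel,) + inner_np + (verb,),
                                p_n * r * p_rel * p_i * p_v,
                                noun,
                            )
                        )
    return out


def _vp(g: GrammarSpec, subject_class: str, subject_noun: str):
    out = []
    obj_nouns = g._noun_dist(HUMAN)
    for verb, p_v in g._verb_dist(subject_class, subject_noun).items():
        if g.verb_lexicon[verb].transitive:
            for obj, p_o in obj_nouns.items():
                obj_np = (obj,) if g.noun_lexicon[obj].bare else (DET, obj)
                out.append(((verb,) + obj_np, p_v * p_o))
        else:
            out.append(((verb,), p_v))
    return out


def _clause(g: GrammarSpec, clause_depth: int):
    """Options for a human-subject clause (complement clauses, matrix human S)."""
    out = []
    for np_tokens, p_np, head in _np_human(g, clause_depth, allow_rel=True):
        for vp_tokens, p_vp in _vp(g, HUMAN, head):
            out.append((np_tokens + vp_tokens, p_np * p_vp))
    return out


def _np_abstract(g: GrammarSpec, clause_depth: int):
    out = []
    comp_ok = clause_depth + 1 <= g.depth_cap
    pp_total = sum(g.pp_probs.values())
    for noun, p_n in g._noun_dist(ABSTRACT).items():
        b = g.noun_lexicon[noun].complement_prob if comp_ok else 0.0
        norm = (1.0 - g.noun_lexicon[noun].complement_prob) if not comp_ok else 1.0
        base = (DET, noun)
        out.append((base, p_n * (1.0 - b - pp_total) / norm, noun))
        if comp_ok:
            for c_tokens, p_c in _clause(g, clause_depth + 1):
                out.append((base + (COMPLEMENTIZER,) + c_tokens, p_n * b * p_c, noun))
        for prep, p_prep in g.pp_probs.items():
            for pp_tokens, p_pp, _ in _np_human(g, clause_depth, allow_rel=True):
                out.append((base + (prep,) + pp_tokens, p_n * (p_prep / norm) * p_pp, noun))
    return out


def enumerate_language(g: GrammarSpec) -> list[tuple[tuple, float]]:
    """All sentences of the finite language with exact probabilities."""
    out = []
    w = g.abstract_subject_prob
    if w > 0:
        for np_tokens, p_np, head in _np_abstract(g, 1):
            for vp_tokens, p_vp in _vp(g, ABSTRACT, head):
                out.append((np_tokens + vp_tokens + (g.sentence_terminator,), w * p_np * p_vp))
    if w < 1:
        for c_tokens, p_c in _clause(g, 1):
            out.append((c_tokens + (g.sentence_terminator,), (1.0 - w) * p_c))
    total = sum(p for _, p in out)
    assert abs(total - 1.0) < 1e-9, f"language probabilities sum to {total}"
    return out


_LANGUAGE_CACHE: dict[str, list] = {}


def language(g: GrammarSpec) -> list[tuple[tuple, float]]:
    """Cached :func:`enumerate_language`."""
    key = g.checksum
    if key not in _LANGUAGE_CACHE:
        _LANGUAGE_CACHE[key] = enumerate_language(g)
    return _LANGUAGE_CACHE[key]


def embedding_depth(tokens: Sequence[str]) -> int:
    """Number of nested noun–verb dependency pairs in a generated sentence."""
    return 1 + sum(1 for t in tokens if t in (COMPLEMENTIZER, RELATIVIZER))


def true_embedding_bias(g: GrammarSpec, noun_id: str) -> float:
    """log P(next token = "that" | prefix "the NOUN"), by exact summation.

    Computed from the enumerated language rather than read off the lexicon, so
    any competing post-nominal source of "that" would be reflected.
    """
    entry = g.noun_lexicon.get(noun_id)
    if entry is None:
        raise VocabularyError(f"unknown noun {noun_id!r}")
    prefix = (DET, noun_id)
    p_prefix = p_that = 0.0
    for tokens, p in language(g):
        if tokens[: len(prefix)] == prefix:
            p_prefix += p
            if len(tokens) > 2 and tokens[2] == COMPLEMENTIZER:
                p_that += p
    if p_prefix == 0.0:
        raise VocabularyError(f"noun {noun_id!r} generates no 'the {noun_id}' prefix")
    if p_that == 0.0:
        raise UndefinedBiasError(f"noun {noun_id!r} is never followed by {COMPLEMENTIZER!r}")
    return float(np.log(p_that / p_prefix))


# ---------------------------------------------------------------------------
# corpus generation


@dataclass(frozen=True)
class CorpusSample:
    sentences: tuple
    seed: int
    grammar_digest: str

    @property
    def vocabulary(self) -> list[str]:
        seen, out = set(), []
        for s in self.sentences:
            for t in s:
                if t not in seen:
                    seen.add(t)
                    out.append(t)
        return sorted(out)

    def save(self, path):
        with open(path, "w") as fh:
            for s in self.sentences:
                fh.write(" ".join(s) + "\n")

    @classmethod
    def load(cls, path, seed: int = -1, grammar_digest: str = "") -> "CorpusSample":
        with open(path) as fh:
            sentences = tuple(tuple(line.split()) for line in fh if line.strip())
        return cls(sentences, seed, grammar_digest)


def generate_corpus(g: GrammarSpec, n: int, seed: int) -> CorpusSample:
    """Sample ``n`` i.i.d. sentences from the exactly enumerated language.

    Sampling from the enumeration keeps corpus statistics provably consistent
    with the analytic grammar probabilities. No comma tokens are emitted.
    """
    if n < 1:
        raise ConfigurationError(f"n: must be >= 1, got {n}")
    lang = language(g)
    probs = np.array([p for _, p in lang])
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(lang), size=n, p=probs / probs.sum())
    sentences = tuple(lang[i][0] for i in idx)
    assert all("," not in s for s in sentences)
    return CorpusSample(sentences, seed, g.checksum)


# ---------------------------------------------------------------------------
# stimuli


@dataclass(frozen=True)
class StimulusItem:
    """Experimental item.

    ``lead_tokens`` holds filler sentences preceding the item so that the
    critical context is a full fixed-length window crossing sentence
    boundaries (matching how the model is trained); fillers contain no
    abstract nouns, and under a sentence-renewal prior they leave veridical
    predictions for the item untouched.
    """

    item_id: str
    tokens: tuple
    condition: str
    compatibility: str  # Compatible | Incompatible | NA
    noun_id: str
    critical_index: int
    preamble_end: int
    lead_tokens: tuple = ()

    def __post_init__(self):
        assert self.condition in CONDITIONS
        assert 0 <= self.critical_index < len(self.tokens)

    @property
    def scored_tokens(self) -> tuple:
        return self.lead_tokens + self.tokens

    @property
    def scored_index(self) -> int:
        return len(self.lead_tokens) + self.critical_index

    @property
    def critical_context(self) -> tuple:
        return self.scored_tokens[: self.scored_index]

    @property
    def critical_word(self) -> str:
        return self.tokens[self.critical_index]


DEFAULT_FRAMES = [
    {
        "id": "f1",
        "n2": "doctor",
        "n3": "diplomat",
        "v3": "mistrusted",
        "v2_compatible": "annoyed",
        "v2_incompatible": "cured",
        "object": "senator",
        "v1": "mattered",
    },
    {
        "id": "f2",
        "n2": "diplomat",
        "n3": "senator",
        "v3": "cured",
        "v2_compatible": "pleased",
        "v2_incompatible": "mistrusted",
        "object": "doctor",
        "v1": "failed",
    },
    {
        "id": "f3",
        "n2": "senator",
        "n3": "doctor",
        "v3": "pleased",
        "v2_compatible": "annoyed",
        "v2_incompatible": "mistrusted",
        "object": "diplomat",
        "v1": "failed",
    },
    {
        "id": "f4",
        "n2": "doctor",
        "n3": "senator",
        "v3": "annoyed",
        "v2_compatible": "pleased",
        "v2_incompatible": "cured",
        "object": "diplomat",
        "v1": "mattered",
    },
    {
        "id": "f5",
        "n2": "senator",
        "n3": "diplomat",
        "v3": "mistrusted",
        "v2_compatible": "pleased",
        "v2_incompatible": "cured",
        "object": "doctor",
        "v1": "failed",
    },
    {
        "id": "f6",
        "n2": "diplomat",
        "n3": "doctor",
        "v3": "cured",
        "v2_compatible": "annoyed",
        "v2_incompatible": "mistrusted",
        "object": "senator",
        "v1": "mattered",
    },
    {
        "id": "f7",
        "n2": "senator",
        "n3": "doctor",
        "v3": "pleased",
        "v2_compatible": "annoyed",
        "v2_incompatible": "cured",
        "object": "diplomat",
        "v1": "mattered",
    },
    {
        "id": "f8",
        "n2": "doctor",
        "n3": "diplomat",
        "v3": "annoyed",
        "v2_compatible": "pleased",
        "v2_incompatible": "mistrusted",
        "object": "senator",
        "v1": "failed",
    },
]


#: complete human-only filler sentences used to extend stimulus contexts to a
#: full window; they contain no abstract nouns, so they cannot interact with
#: the embedding-bias manipulation
FILLER_SENTENCES = [
    ("the", "doctor", "pleased", "the", "senator", "."),
    ("the", "diplomat", "failed", "."),
    ("smith", "mattered", "."),
]


def _lead_for(need: int) -> tuple:
    """Concatenation of filler sentences with total length ``need``."""
    if need == 0:
        return ()
    import itertools as _it

    for k in range(1, len(FILLER_SENTENCES) + 1):
        for combo in _it.permutations(FILLER_SENTENCES, k):
            if sum(len(s) for s in combo) == need:
                return tuple(t for s in combo for t in s)
    raise StimulusDesignError(
        f"no filler combination of length {need}; adjust context_length or fillers"
    )


def default_design(g: GrammarSpec) -> dict:
    return {
        "frames": DEFAULT_FRAMES,
        "nouns": g.nouns(ABSTRACT),
        "conditions": list(CONDITIONS),
        "compatibility": ["Compatible", "Incompatible"],
        "context_length": 12,
    }


def _check_frame(g: GrammarSpec, frame: Mapping, noun: str, condition: str, v2: str | None):
    fid = frame.get("id", "?")

    def fail(msg):
        raise StimulusDesignError(f"frame {fid!r} incompatible with condition {condition!r}: {msg}")

    entry = g.noun_lexicon.get(noun)
    if entry is None or entry.semantic_class != ABSTRACT:
        fail(f"noun {noun!r} is not an abstract (complement-taking) noun")
    v1 = frame["v1"]
    if ABSTRACT not in g.verb_lexicon[v1].subject_classes:
        fail(f"final verb {v1!r} cannot take an abstract subject")
    if condition == "One":
        return
    for role in ("n2",) + (("n3",) if condition == "Three" else ()):
        if g.noun_lexicon.get(frame[role], NounEntry(ABSTRACT, 0.5)).semantic_class != HUMAN:
            fail(f"{role} {frame[role]!r} is not a human noun")
    if g.noun_lexicon.get(frame["object"], NounEntry(ABSTRACT, 0.5)).semantic_class != HUMAN:
        fail(f"object {frame['object']!r} is not a human noun")
    if v2 is None:
        fail("no second-to-last verb supplied")
    e2 = g.verb_lexicon.get(v2)
    if e2 is None or not e2.transitive or HUMAN not in e2.subject_classes:
        fail(f"v2 {v2!r} must be a transitive verb taking a human subject")
    if condition == "Three":
        e3 = g.verb_lexicon.get(frame["v3"])
        if e3 is None or not e3.transitive or HUMAN not in e3.subject_classes:
            fail(f"v3 {frame['v3']!r} must be a transitive verb taking a human subject")


def _item_tokens(frame: Mapping, noun: str, condition: str, v2: str | None):
    t = frame
    if condition == "One":
        tokens = (DET, noun, t["v1"], TERMINATOR)
        return tokens, 2, 2
    if condition == "Two":
        tokens = (DET, noun, COMPLEMENTIZER, DET, t["n2"], v2, DET, t["object"], t["v1"], TERMINATOR)
        return tokens, 8, 5
    tokens = (
        DET, noun, COMPLEMENTIZER, DET, t["n2"], RELATIVIZER, DET, t["n3"],
        t["v3"], v2, DET, t["object"], t["v1"], TERMINATOR,
    )
    return tokens, 12, 8


def generate_stimuli(g: GrammarSpec, design: Mapping | None = None) -> list[StimulusItem]:
    """Full factorial crossing of frames x nouns x conditions.

    Compatibility (identity of the second-to-last verb) is crossed only
    within the Two and Three conditions when the design lists compatibility
    levels; One-condition items carry compatibility "NA".
    """
    design = design or default_design(g)
    compat_levels = design.get("compatibility") or [None]
    context_length = design.get("context_length")
    items = []
    for frame in design["frames"]:
        for noun in design["nouns"]:
            for condition in design["conditions"]:
                levels = compat_levels if condition in ("Two", "Three") else [None]
                for compat in levels:
                    if condition == "One":
                        v2 = None
                    elif compat == "Incompatible":
                        v2 = frame["v2_incompatible"]
                    else:
                        v2 = frame.get("v2_compatible", frame.get("v2"))
                    _check_frame(g, frame, noun, condition, v2)
                    if compat == "Incompatible":
                        e2 = g.verb_lexicon[v2]
                        if ABSTRACT in e2.subject_classes:
                            raise StimulusDesignError(
                                f"frame {frame['id']!r} incompatible with condition "
                                f"{condition!r}: v2 {v2!r} is compatible with abstract "
                                "subjects and cannot serve as the Incompatible verb"
                            )
                    elif compat == "Compatible":
                        e2 = g.verb_lexicon[v2]
                        if ABSTRACT not in e2.subject_classes:
                            raise StimulusDesignError(
                                f"frame {frame['id']!r} incompatible with condition "
                                f"{condition!r}: v2 {v2!r} cannot serve as the Compatible verb"
                            )
                    tokens, crit, pre_end = _item_tokens(frame, noun, condition, v2)
                    label = compat if compat else "NA"
                    lead = (
                        _lead_for(max(0, context_length - crit))
                        if context_length
                        else ()
                    )
                    items.append(
                        StimulusItem(
                            item_id=f"{frame['id']}:{noun}:{condition}:{label}",
                            tokens=tokens,
                            condition=condition,
                            compatibility=label,
                            noun_id=noun,
                            critical_index=crit,
                            preamble_end=pre_end,
                            lead_tokens=lead,
                        )
                    )
    return items


def stimuli_to_frame(items: Sequence[StimulusItem]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "item_id": [i.item_id for i in items],
            "condition": [i.condition for i in items],
            "compatibility": [i.compatibility for i in items],
            "noun_id": [i.noun_id for i in items],
            "tokens": [" ".join(i.tokens) for i in items],
            "critical_index": [i.critical_index for i in items],
            "preamble_end": [i.preamble_end for i in items],
            "lead_tokens": [" ".join(i.lead_tokens) for i in items],
        }
    )


def save_stimuli(items: Sequence[StimulusItem], path) -> None:
    stimuli_to_frame(items).to_csv(path, sep="\t", index=False)


def load_stimuli(path) -> list[StimulusItem]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        StimulusItem(
            item_id=row.item_id,
            tokens=tuple(row.tokens.split()),
            condition=row.condition,
            compatibility=row.compatibility,
            noun_id=row.noun_id,
            critical_index=int(row.critical_index),
            preamble_end=int(row.preamble_end),
            lead_tokens=tuple(str(row.lead_tokens).split()) if row.lead_tokens else (),
        )
        for row in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# grammar-derived dependency annotations (for the DLT baseline)


@dataclass(frozen=True)
class DependencyAnnotation:
    """Head index per token (-1 marks the root) plus new-discourse-referent
    flags (true for nouns and finite verbs)."""

    heads: tuple
    referent: tuple

    def __post_init__(self):
        n = len(self.heads)
        assert len(self.referent) == n
        roots = [i for i, h in enumerate(self.heads) if h == -1]
        assert len(roots) == 1, "annotation must have exactly one root"
        for i, h in enumerate(self.heads):  # acyclicity via root reachability
            seen = set()
            while h != -1:
                assert h not in seen, "cycle in dependency annotation"
                seen.add(h)
                h = self.heads[h]


def annotate_stimulus(item: StimulusItem) -> DependencyAnnotation:
    """Dependency structure of a stimulus, derived from its known frame layout
    (never from parsing)."""
    c = item.condition
    if c == "One":
        heads = (1, 2, -1, 2)
        referent = (False, True, True, False)
    elif c == "Two":
        # the N1 that the n2 v2 the obj v1 .
        heads = (1, 8, 5, 4, 5, 1, 7, 5, -1, 8)
        referent = (False, True, False, False, True, True, False, True, True, False)
    else:
        # the N1 that the n2 who the n3 v3 v2 the obj v1 .
        heads = (1, 12, 9, 4, 9, 8, 7, 8, 4, 1, 11, 9, -1, 12)
        referent = (
            False, True, False, False, True, False, False, True,
            True, True, False, True, True, False,
        )
    return DependencyAnnotation(heads, referent)


def annotate_stimuli(items: Sequence[StimulusItem]) -> dict[str, DependencyAnnotation]:
    return {item.item_id: annotate_stimulus(item) for item in items}
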