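"""Autoregressive priors over token sequences.

Two concrete priors stand in for a large neural language model at desk scale:

* :class:`NGramModel` — count-based n-gram model with add-k smoothing, fit on
  a corpus stream (sentences concatenated, so contexts cross "." boundaries);
* :class:`EnumerativeGrammarPrior` — the exact renewal process obtained by
  concatenating i.i.d. sentences of a finite grammar language, lightly
  interpolated with a uniform distribution so every sequence keeps nonzero
  probability (Bayesian reconstruction of noisy memories requires
  full-support priors).

Both are compiled to dense (state x vocabulary) probability/transition tables,
which makes exact enumeration and importance sampling over thousands of
candidate contexts a handful of vectorized numpy gathers.

All log-probabilities are natural logs (nats).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._util import digest
from .exceptions import ConfigurationError, UndefinedBiasError, VocabularyError
from .grammar import COMPLEMENTIZER, DET, GrammarSpec, CorpusSample, language

BOS = "<s>"  #: begin-of-sequence pad; always retained, never predicted


@dataclass
class CompiledLM:
    """Dense Markov view of an autoregressive model.

    ``dist[s]`` is the next-token distribution in state ``s``; ``trans[s, a]``
    the successor state after emitting token ``a``. State 0 may be a sink for
    out-of-model histories.
    """

    vocab: list
    dist: np.ndarray  # (S, V) float64, rows sum to 1
    trans: np.ndarray  # (S, V) int32
    start_state: int

    def __post_init__(self):
        self.index = {t: i for i, t in enumerate(self.vocab)}
        with np.errstate(divide="ignore"):  # zero-probability cells stay -inf
            self.logdist = np.log(self.dist)

    @property
    def n_states(self) -> int:
        return self.dist.shape[0]

    def encode(self, tokens: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self.index[t] for t in tokens], dtype=np.int32)
        except KeyError as err:
            raise VocabularyError(f"token {err.args[0]!r} not in model vocabulary") from None

    def state_of(self, prefix_ids: np.ndarray) -> int:
        s = self.start_state
        for a in prefix_ids:
            s = int(self.trans[s, a])
        return s

    def walk(self, batch_ids: np.ndarray, start_states: np.ndarray | None = None):
        """Vectorized scoring of a batch of sequences.

        Returns (logprobs (M,), final states (M,)).
        """
        m, t = batch_ids.shape
        states = (
            np.full(m, self.start_state, dtype=np.int64)
            if start_states is None
            else start_states.astype(np.int64).copy()
        )
        logp = np.zeros(m)
        for j in range(t):
            tok = batch_ids[:, j]
            logp += self.logdist[states, tok]
            states = self.trans[states, tok].astype(np.int64)
        return logp, states


class LanguageModelPrior:
    """Interface: a vocabulary, next-token distributions for any prefix, and
    joint sequence log-probabilities (the sum of its conditionals).

    Prefixes may carry leading :data:`BOS` pad tokens, which are stripped:
    they denote "nothing observed yet". An adapter wrapping a large neural
    model would implement this same contract; only exact desk-scale models are
    provided here.
    """

    vocabulary: list

    @property
    def compiled(self) -> CompiledLM:
        raise NotImplementedError

    # -- generic implementations via the compiled tables ----------------------
    def _strip(self, tokens: Sequence[str]) -> list:
        out = list(tokens)
        while out and out[0] == BOS:
            out = out[1:]
        if BOS in out:
            raise VocabularyError(f"{BOS!r} may only appear as a leading pad")
        return out

    def next_dist(self, prefix: Sequence[str]) -> np.ndarray:
        """P(. | prefix) over the vocabulary; sums to one."""
        c = self.compiled
        s = c.state_of(c.encode(self._strip(prefix)))
        return c.dist[s].copy()

    def sequence_logprob(self, seq: Sequence[str]) -> float:
        c = self.compiled
        ids = c.encode(self._strip(seq))
        if len(ids) == 0:
            return 0.0
        logp, _ = c.walk(ids[None, :])
        return float(logp[0])


def plain_surprisal(lm: LanguageModelPrior, tokens: Sequence[str], index: int) -> float:
    """Veridical-context surprisal -log P(w_index | w_<index), in nats."""
    if not (0 <= index < len(tokens)):
        raise IndexError(f"index {index} out of range for {len(tokens)} tokens")
    p = lm.next_dist(tokens[:index])[lm.compiled.index[tokens[index]]]
    return float(-np.log(p))


# ---------------------------------------------------------------------------
# n-gram model


class NGramModel(LanguageModelPrior):
    """Add-k smoothed n-gram model over the corpus stream.

    Histories at the stream start are padded with BOS. All conditionals are
    strictly positive when ``add_k > 0``.
    """

    def __init__(self, order: int, counts: dict, vocabulary: list, add_k: float = 0.1):
        if order < 1:
            raise ConfigurationError(f"order: must be >= 1, got {order}")
        if add_k < 0:
            raise ConfigurationError(f"add_k: must be >= 0, got {add_k}")
        self.order = order
        self.counts = counts  # history tuple -> {token: count}
        self.vocabulary = list(vocabulary)
        self.add_k = add_k
        self._compiled = None

    def conditional(self, history: tuple, token: str) -> float:
        v = len(self.vocabulary)
        table = self.counts.get(tuple(history), {})
        total = sum(table.values())
        num = table.get(token, 0) + self.add_k
        den = total + self.add_k * v
        if den == 0:
            return 1.0 / v  # unseen history, k = 0: fall back to uniform
        return num / den

    @property
    def compiled(self) -> CompiledLM:
        if self._compiled is None:
            self._compiled = self._compile()
        return self._compiled

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "order": self.order,
                "add_k": self.add_k,
                "vocabulary": self.vocabulary,
                "counts": {" ".join(h): t for h, t in self.counts.items()},
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "NGramModel":
        import json

        obj = json.loads(text)
        counts = {tuple(h.split()) if h else (): t for h, t in obj["counts"].items()}
        return cls(obj["order"], counts, obj["vocabulary"], obj["add_k"])

    def _compile(self) -> CompiledLM:
        v = len(self.vocabulary)
        tok_idx = {t: i for i, t in enumerate(self.vocabulary)}
        ctx_len = self.order - 1
        n_states = max((v + 1) ** ctx_len, 1)
        if n_states * v > 50_000_000:
            raise ConfigurationError(
                f"order {self.order} with |V|={v} is too large to compile"
            )

        # state = base-(v+1) code of the history; digit 0 (lowest) is the most
        # recent token; BOS encodes as 0, so the start state (all BOS) is 0
        def hist_of_state(s: int) -> tuple:
            hist = []
            for _ in range(ctx_len):
                code = s % (v + 1)
                hist.append(BOS if code == 0 else self.vocabulary[code - 1])
                s //= v + 1
            return tuple(reversed(hist))

        dist = np.empty((n_states, v))
        for s in range(n_states):
            eff = _effective_history(hist_of_state(s)) if ctx_len else ()
            table = self.counts.get(eff, {})
            den = sum(table.values()) + self.add_k * v
            if den == 0:
                dist[s] = 1.0 / v  # unseen history with k = 0
            else:
                row = np.full(v, self.add_k)
                for tok, cnt in table.items():
                    row[tok_idx[tok]] += cnt
                dist[s] = row / den

        trans = np.empty((n_states, v), dtype=np.int32)
        if ctx_len == 0:
            trans[:] = 0
        else:
            shift = (v + 1) ** (ctx_len - 1)
            for s in range(n_states):
                trans[s] = (s % shift) * (v + 1) + 1 + np.arange(v)
        return CompiledLM(self.vocabulary, dist, trans, start_state=0)


def _effective_history(hist: tuple) -> tuple:
    """Strip leading BOS pads; a BOS after a real token marks an unreachable
    state whose distribution is irrelevant (kept uniform)."""
    out = list(hist)
    while out and out[0] == BOS:
        out.pop(0)
    return tuple(out)


def fit_ngram(
    corpus: CorpusSample, order: int, smoothing: dict | None = None
) -> NGramModel:
    """Count n-grams over the concatenated corpus stream.

    ``smoothing`` accepts ``{"add_k": float}`` (default 0.1).
    """
    if not corpus.sentences:
        raise ConfigurationError("corpus: empty")
    add_k = float((smoothing or {}).get("add_k", 0.1))
    stream = [t for s in corpus.sentences for t in s]
    if order - 1 > len(stream):
        raise ConfigurationError(
            f"order {order} larger than the usable corpus stream ({len(stream)} tokens)"
        )
    vocab = sorted(set(stream))
    counts: dict = {}
    padded = [BOS] * (order - 1) + stream
    for i in range(order - 1, len(padded)):
        hist = _effective_history(tuple(padded[i - order + 1 : i]))
        counts.setdefault(hist, {})
        counts[hist][padded[i]] = counts[hist].get(padded[i], 0) + 1
    return NGramModel(order, counts, vocab, add_k)


# ---------------------------------------------------------------------------
# exact enumerative prior


class EnumerativeGrammarPrior(LanguageModelPrior):
    """Exact prior over token streams formed by concatenating i.i.d. sentences
    of a finite grammar language, interpolated with a uniform distribution.

    P(a | state) = (1 - eps) * P_grammar(a | state) + eps / |V|.

    The sentence terminator deterministically resets the state to the
    sentence-initial state, so sequences may span sentence boundaries. States
    that leave the grammar's prefix trie fall into a sink with a uniform
    distribution until the next terminator.
    """

    DEAD, ROOT = 0, 1

    def __init__(self, grammar: GrammarSpec, smoothing_eps: float = 1e-4):
        if not (0.0 < smoothing_eps < 1.0):
            raise ConfigurationError(f"smoothing_eps: must lie in (0,1), got {smoothing_eps}")
        self.grammar = grammar
        self.smoothing_eps = smoothing_eps
        self.vocabulary = list(grammar.vocabulary)
        self._compiled = self._compile()

    @property
    def compiled(self) -> CompiledLM:
        return self._compiled

    def _compile(self) -> CompiledLM:
        vocab = self.vocabulary
        v = len(vocab)
        idx = {t: i for i, t in enumerate(vocab)}
        period = idx[self.grammar.sentence_terminator]

        children: list[dict] = [{}, {}]  # DEAD, ROOT
        mass = [0.0, 0.0]
        end_mass = [0.0, 0.0]  # probability mass of sentences completing here
        for tokens, p in language(self.grammar):
            mass[self.ROOT] += p
            node = self.ROOT
            for t in tokens[:-1]:  # last token is the terminator
                a = idx[t]
                nxt = children[node].get(a)
                if nxt is None:
                    nxt = len(children)
                    children.append({})
                    mass.append(0.0)
                    end_mass.append(0.0)
                    children[node][a] = nxt
                node = nxt
                mass[node] += p
            end_mass[node] += p

        n = len(children)
        eps = self.smoothing_eps
        dist = np.full((n, v), eps / v)
        trans = np.full((n, v), self.DEAD, dtype=np.int32)
        trans[:, period] = self.ROOT  # terminator always starts a new sentence
        dist[self.DEAD] = 1.0 / v
        for node in range(1, n):
            m = mass[node]
            if m <= 0:
                continue
            dist[node, period] += (1 - eps) * end_mass[node] / m
            for a, child in children[node].items():
                dist[node, a] += (1 - eps) * mass[child] / m
                trans[node, a] = child
        np.testing.assert_allclose(dist.sum(axis=1), 1.0, atol=1e-9)
        return CompiledLM(vocab, dist, trans, start_state=self.ROOT)

    @property
    def checksum(self) -> str:
        return digest([self.grammar.checksum, self.smoothing_eps])


# ---------------------------------------------------------------------------
# embedding bias


def embedding_bias(source, noun: str, add_k: float = 0.0) -> float:
    """log P("that" follows "the NOUN"), in nats.

    Corpus mode counts "the NOUN that" among "the NOUN" occurrences with add-k
    smoothing; LM mode reads the model's next-token distribution after the
    prefix ("the", NOUN).
    """
    if isinstance(source, CorpusSample):
        vocab_size = len(source.vocabulary)
        n_bigram = n_trigram = 0
        for s in source.sentences:
            for i in range(len(s) - 1):
                if s[i] == DET and s[i + 1] == noun:
                    n_bigram += 1
                    if i + 2 < len(s) and s[i + 2] == COMPLEMENTIZER:
                        n_trigram += 1
        if n_bigram == 0 and add_k == 0.0:
            raise UndefinedBiasError(f"'the {noun}' never occurs and add_k=0")
        if n_trigram == 0 and add_k == 0.0:
            raise UndefinedBiasError(f"'the {noun} that' never occurs and add_k=0")
        return float(
            np.log((n_trigram + add_k) / (n_bigram + add_k * vocab_size))
        )
    if isinstance(source, LanguageModelPrior):
        dist = source.next_dist([DET, noun])
        return float(np.log(dist[source.compiled.index[COMPLEMENTIZER]]))
    raise TypeError(f"unsupported bias source: {type(source).__name__}")
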