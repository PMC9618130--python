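"""Retention policies: which context words survive in memory.

A retention policy maps (word identity, distance) to the probability that the
word is still available when the next word is predicted. Distance d counts how
many words have been observed since the word: d = 1 is the immediately
preceding context word, d = N the oldest cell of the fixed-length window.
Erasure is independent across cells; erased cells are replaced by a
position-preserving placeholder, so the comprehender knows *where* material
was lost but not *what* it was. Begin-of-sequence pad cells are always
retained — only real context words are erasable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import ConfigurationError, VocabularyError
from .lm import BOS

ERASED = "<?>"  #: placeholder symbol for lost words

DEFAULT_N = 20


def pad_context(tokens: Sequence[str], n: int) -> tuple:
    """Left-pad (or left-truncate) a context to exactly ``n`` cells."""
    toks = tuple(tokens)
    if len(toks) >= n:
        return toks[len(toks) - n :]
    return (BOS,) * (n - len(toks)) + toks


@dataclass(frozen=True)
class LossyRepresentation:
    """The memory trace c': retained words in their positions, ERASED elsewhere."""

    cells: tuple

    def __post_init__(self):
        assert all(isinstance(c, str) for c in self.cells)

    def __len__(self):
        return len(self.cells)

    @property
    def erased(self) -> np.ndarray:
        return np.array([c == ERASED for c in self.cells])

    @property
    def n_erased(self) -> int:
        return int(self.erased.sum())


class RetentionPolicy:
    """Base class; subclasses define retain_prob(word, d)."""

    n: int  # maximum context length N

    def retain_prob(self, word: str, d: int) -> float:
        if not (1 <= d <= self.n):
            raise ConfigurationError(f"distance {d} outside 1..{self.n}")
        if word == BOS:
            return 1.0
        return self._prob(word, d)

    def _prob(self, word: str, d: int) -> float:
        raise NotImplementedError

    def q_vector(self, context: Sequence[str]) -> np.ndarray:
        """Retention probabilities for each cell of a padded context.

        Cell i of a length-n context sits at distance d = n - i.
        """
        n = len(context)
        return np.array(
            [1.0 if w == BOS else self._prob(w, n - i) for i, w in enumerate(context)]
        )

    def spec(self) -> dict:
        raise NotImplementedError

    def to_json(self) -> str:
        return json.dumps(self.spec(), sort_keys=True)


class UniformPolicy(RetentionPolicy):
    """Every context word retained with the same probability p."""

    def __init__(self, p: float, n: int = DEFAULT_N):
        if not (0.0 <= p <= 1.0):
            raise ConfigurationError(f"p: must lie in [0,1], got {p}")
        self.p = float(p)
        self.n = n

    def _prob(self, word, d):
        return self.p

    def q_vector(self, context):
        return np.where(np.array(context) == BOS, 1.0, self.p)

    def spec(self):
        return {"type": "uniform", "p": self.p, "n": self.n}


class WindowPolicy(RetentionPolicy):
    """Exactly the last K words are available."""

    def __init__(self, k: int, n: int = DEFAULT_N):
        if not (0 <= k <= n):
            raise ConfigurationError(f"k: must lie in 0..{n}, got {k}")
        self.k = int(k)
        self.n = n

    def _prob(self, word, d):
        return 1.0 if d <= self.k else 0.0

    def q_vector(self, context):
        m = len(context)
        d = m - np.arange(m)
        return np.where((d <= self.k) | (np.array(context) == BOS), 1.0, 0.0)

    def spec(self):
        return {"type": "window", "k": self.k, "n": self.n}


def all_retain(n: int = DEFAULT_N) -> UniformPolicy:
    return UniformPolicy(1.0, n)


def all_erase(n: int = DEFAULT_N) -> UniformPolicy:
    return UniformPolicy(0.0, n)


class TabularPolicy(RetentionPolicy):
    """Explicit (word, distance) table; the search space of the brute-force
    policy-grid oracle."""

    def __init__(self, vocab: Sequence[str], table: np.ndarray, n: int | None = None):
        table = np.asarray(table, dtype=float)
        if table.shape != (len(vocab), table.shape[1]):
            raise ConfigurationError("table: shape must be (len(vocab), N)")
        if table.min() < 0 or table.max() > 1:
            raise ConfigurationError("table: entries must lie in [0,1]")
        self.vocab = list(vocab)
        self.index = {w: i for i, w in enumerate(self.vocab)}
        self.table = table
        self.n = n or table.shape[1]

    def _prob(self, word, d):
        i = self.index.get(word)
        if i is None:
            raise VocabularyError(f"word {word!r} not covered by policy")
        return float(self.table[i, d - 1])

    def q_vector(self, context):
        m = len(context)
        out = np.empty(m)
        for i, w in enumerate(context):
            out[i] = 1.0 if w == BOS else self.table[self.index[w], m - i - 1]
        return out

    def spec(self):
        return {"type": "tabular", "vocab": self.vocab, "table": self.table.tolist(), "n": self.n}


class LearnedPolicy(RetentionPolicy):
    """One-hidden-layer network from (word representation, distance) to a
    retention probability through a logistic link.

    The word representation is either low-dimensional — the standardized log
    corpus frequency (default) — or the word's one-hot code plus its log
    frequency. Distance enters through a smooth basis (linear, quadratic, and
    two exponential decays of d/N), so retention value learned at one distance
    generalizes to neighboring distances. Deterministic given the parameter
    vector; gradients are computed analytically in the trainer.
    """

    def __init__(
        self,
        vocab: Sequence[str],
        params: dict,
        log_freq: np.ndarray | None = None,
        n: int = DEFAULT_N,
        word_repr: str = "frequency",
    ):
        if word_repr not in ("frequency", "onehot"):
            raise ConfigurationError(f"word_repr: unknown {word_repr!r}")
        self.vocab = list(vocab)
        self.index = {w: i for i, w in enumerate(self.vocab)}
        self.params = {k: np.asarray(v, dtype=float) for k, v in params.items()}
        v = len(self.vocab)
        self.log_freq = (
            np.zeros(v) if log_freq is None else np.asarray(log_freq, dtype=float)
        )
        self.n = n
        self.word_repr = word_repr
        self._features = self._build_features()
        self._table = None

    @classmethod
    def n_features(cls, n_vocab: int, word_repr: str = "frequency") -> int:
        return (n_vocab + 5) if word_repr == "onehot" else 5

    @classmethod
    def init(
        cls,
        vocab: Sequence[str],
        n: int = DEFAULT_N,
        hidden: int = 8,
        log_freq: np.ndarray | None = None,
        seed: int = 0,
        init_logit: float = 1.0,
        scale: float = 0.1,
        word_repr: str = "frequency",
    ) -> "LearnedPolicy":
        rng = np.random.default_rng(seed)
        f = cls.n_features(len(vocab), word_repr)
        params = {
            "W1": rng.normal(0.0, scale, size=(f, hidden)),
            "b1": np.zeros(hidden),
            "w2": rng.normal(0.0, scale, size=hidden),
            "b2": np.array(float(init_logit)),
        }
        return cls(vocab, params, log_freq=log_freq, n=n, word_repr=word_repr)

    def _build_features(self) -> np.ndarray:
        """(V*N, F) feature matrix, row = word w at distance d (row w*N + d-1)."""
        v, n = len(self.vocab), self.n
        lf = self.log_freq
        if lf.std() > 0:
            lf = (lf - lf.mean()) / lf.std()
        widx = np.repeat(np.arange(v), n)
        d = np.tile(np.arange(1, n + 1), v).astype(float)
        base = np.column_stack(
            [
                lf[widx],
                d / n,
                (d / n) ** 2,
                np.exp(-(d - 1) / 2.0),
                np.exp(-(d - 1) / 5.0),
            ]
        )
        if self.word_repr == "frequency":
            return base
        onehot = np.zeros((v * n, v))
        onehot[np.arange(v * n), widx] = 1.0
        return np.hstack([onehot, base])

    def forward(self, params: dict | None = None):
        """Returns (q (V,N), cache for backprop)."""
        p = params or self.params
        h_pre = self._features @ p["W1"] + p["b1"]
        h = np.tanh(h_pre)
        z = h @ p["w2"] + p["b2"]
        q = 1.0 / (1.0 + np.exp(-z))
        v, n = len(self.vocab), self.n
        cache = {"h": h, "z": z}
        return q.reshape(v, n), cache

    def grad_logits(self, cache: dict, dz: np.ndarray) -> dict:
        """Backpropagate a gradient on the (V*N,) logits to the parameters."""
        p = self.params
        h = cache["h"]
        dh = np.outer(dz, p["w2"]) * (1.0 - h * h)
        return {
            "W1": self._features.T @ dh,
            "b1": dh.sum(axis=0),
            "w2": h.T @ dz,
            "b2": np.array(dz.sum()),
        }

    @property
    def table(self) -> np.ndarray:
        if self._table is None:
            self._table, _ = self.forward()
        return self._table

    def invalidate(self):
        self._table = None

    def _prob(self, word, d):
        i = self.index.get(word)
        if i is None:
            raise VocabularyError(f"word {word!r} not covered by policy")
        return float(self.table[i, d - 1])

    def q_vector(self, context):
        m = len(context)
        t = self.table
        out = np.empty(m)
        for i, w in enumerate(context):
            out[i] = 1.0 if w == BOS else t[self.index[w], m - i - 1]
        return out

    def spec(self):
        return {
            "type": "learned",
            "vocab": self.vocab,
            "params": {k: v.tolist() for k, v in self.params.items()},
            "log_freq": self.log_freq.tolist(),
            "n": self.n,
            "word_repr": self.word_repr,
        }


def policy_from_json(text: str) -> RetentionPolicy:
    obj = json.loads(text)
    t = obj["type"]
    if t == "uniform":
        return UniformPolicy(obj["p"], obj["n"])
    if t == "window":
        return WindowPolicy(obj["k"], obj["n"])
    if t == "tabular":
        return TabularPolicy(obj["vocab"], np.array(obj["table"]), obj["n"])
    if t == "learned":
        return LearnedPolicy(
            obj["vocab"],
            obj["params"],
            np.array(obj["log_freq"]),
            obj["n"],
            obj.get("word_repr", "frequency"),
        )
    raise ConfigurationError(f"unknown policy type {t!r}")


# ---------------------------------------------------------------------------
# channel operations


def retain_prob(policy: RetentionPolicy, word: str, d: int) -> float:
    """q_{w,d}: probability the word is retained d observations later."""
    return policy.retain_prob(word, d)


def sample_mask(
    policy: RetentionPolicy, context: Sequence[str], rng: np.random.Generator
) -> np.ndarray:
    """Independent Bernoulli retention mask over a padded context."""
    q = policy.q_vector(context)
    return rng.random(len(q)) < q


def encode(
    policy: RetentionPolicy, context: Sequence[str], rng: np.random.Generator
) -> LossyRepresentation:
    """Sample a lossy memory trace c' of the context."""
    mask = sample_mask(policy, context, rng)
    return apply_mask(context, mask)


def apply_mask(context: Sequence[str], mask: np.ndarray) -> LossyRepresentation:
    """Pads are never erasable; only real context words can be lost."""
    return LossyRepresentation(
        tuple(w if (w == BOS or m) else ERASED for w, m in zip(context, mask))
    )


def expected_retained(policy: RetentionPolicy, contexts: Sequence[Sequence[str]]) -> float:
    """Mean over contexts of the expected number of retained words (Eq. 3's
    resource measure); pad cells do not count."""
    if len(contexts) == 0:
        raise ConfigurationError("contexts: empty")
    total = 0.0
    for ctx in contexts:
        q = policy.q_vector(ctx)
        real = np.array([w != BOS for w in ctx])
        total += float(q[real].sum())
    return total / len(contexts)
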