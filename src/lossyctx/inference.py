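"""Bayesian reconstruction of lossy contexts and lossy-context surprisal.

Given a memory trace c' (retained words plus placeholders), the comprehender's
next-word distribution marginalizes over possible true contexts:

    P(w | c') = sum_c P(w | c) P(c | c'),
    P(c | c') ∝ P(c) * p(c' | c),

and processing difficulty on the next word w is the surprisal -log P(w | c'),
averaged over the distribution of memory traces for the true context.

Two inference routes are provided: exact enumeration of all completions of the
erased cells (feasible for small vocabularies / few erasures; the test oracle),
and a self-normalized importance sampler whose proposal draws erased cells
autoregressively from the prior with retained cells forced to their observed
values. The importance weight of a particle then reduces to the prior terms of
the forced cells times the channel likelihood.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .exceptions import BudgetExceededError, ConfigurationError, InferenceError
from .lm import BOS, LanguageModelPrior
from .retention import ERASED, LossyRepresentation, RetentionPolicy, pad_context

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class InferenceSettings:
    """How posteriors are approximated.

    method: "exact" (enumerate), "is" (importance sampling) or "auto"
    (exact when the enumeration budgets allow, otherwise IS).
    """

    method: str = "auto"
    n_particles: int = 128
    enumeration_budget: int = 10**6
    mask_budget: int = 2**14
    ess_warning_frac: float = 0.05

    def __post_init__(self):
        if self.method not in ("auto", "exact", "is"):
            raise ConfigurationError(f"method: unknown {self.method!r}")
        if self.n_particles < 1:
            raise ConfigurationError("n_particles: must be >= 1")


EXACT = InferenceSettings(method="exact")


class PosteriorEnsemble:
    """Weighted candidate contexts approximating P(c | c').

    Candidates are stored as token-id arrays; the ``contexts`` view (token
    tuples including BOS pads) is materialized lazily.
    """

    def __init__(
        self,
        weights: np.ndarray,
        effective_sample_size: float,
        ids: np.ndarray,
        npad: int,
        vocab: Sequence[str],
        states: np.ndarray,
        low_ess: bool = False,
    ):
        s = float(weights.sum())
        assert abs(s - 1.0) < 1e-9, f"weights sum to {s}"
        self.weights = weights
        self.effective_sample_size = effective_sample_size
        self.low_ess = low_ess
        self._ids = ids
        self._npad = npad
        self._vocab = list(vocab)
        self._states = states
        self._contexts = None

    @property
    def contexts(self) -> list:
        if self._contexts is None:
            pad = (BOS,) * self._npad
            self._contexts = [
                pad + tuple(self._vocab[a] for a in row) for row in self._ids
            ]
        return self._contexts

    def __len__(self):
        return len(self.weights)

    def check_support(self, c_prime: LossyRepresentation) -> bool:
        for ctx in self.contexts:
            for cell, word in zip(c_prime.cells, ctx):
                if cell != ERASED and cell != word:
                    return False
        return True

    def marginal(self, position: int, vocab: Sequence[str]) -> np.ndarray:
        out = np.zeros(len(vocab))
        index = {t: i for i, t in enumerate(vocab)}
        for ctx, w in zip(self.contexts, self.weights):
            out[index[ctx[position]]] += w
        return out


@dataclass(frozen=True)
class SurprisalEstimate:
    """Expected lossy-context surprisal, in nats, over memory traces."""

    mean_nats: float
    mc_standard_error: float
    n_masks: int
    n_particles: int
    method: str
    per_mask_values: tuple | None = None
    low_ess_fraction: float = 0.0

    def __post_init__(self):
        assert self.mean_nats >= -1e-12
        if self.method == "exact":
            assert self.mc_standard_error == 0.0


# ---------------------------------------------------------------------------
# channel


def policy_qmat(policy: RetentionPolicy, vocab: Sequence[str], n: int) -> np.ndarray:
    """(V, N) retention probabilities; column d-1 holds q(word, d)."""
    out = np.empty((len(vocab), n))
    for i, w in enumerate(vocab):
        for d in range(1, n + 1):
            out[i, d - 1] = policy.retain_prob(w, d)
    return out


def channel_likelihood(
    policy: RetentionPolicy, c: Sequence[str], c_prime: LossyRepresentation
) -> float:
    """p(c' | c): zero on any retained-cell mismatch, else the product of
    per-cell retention / erasure probabilities."""
    if len(c) != len(c_prime.cells):
        raise ConfigurationError(
            f"length mismatch: context {len(c)} vs representation {len(c_prime.cells)}"
        )
    n = len(c)
    prob = 1.0
    for i, (word, cell) in enumerate(zip(c, c_prime.cells)):
        if word == BOS:
            if cell != BOS:
                return 0.0
            continue
        q = policy.retain_prob(word, n - i)
        if cell == ERASED:
            prob *= 1.0 - q
        elif cell == word:
            prob *= q
        else:
            return 0.0
    return prob


# ---------------------------------------------------------------------------
# posterior inference


def _split_cells(c_prime: LossyRepresentation):
    pads, retained, erased = [], [], []
    for i, cell in enumerate(c_prime.cells):
        if cell == BOS:
            pads.append(i)
        elif cell == ERASED:
            erased.append(i)
        else:
            retained.append(i)
    if pads and max(pads) > min(retained + erased, default=len(c_prime.cells)):
        raise ConfigurationError("BOS pads must form a left prefix")
    return pads, retained, erased


def exact_posterior(
    lm: LanguageModelPrior, policy: RetentionPolicy, c_prime: LossyRepresentation,
    enumeration_budget: int = 10**6,
) -> PosteriorEnsemble:
    """Enumerate every completion of the erased cells and weight by
    prior x channel likelihood (Bayes' rule)."""
    comp = lm.compiled
    n = len(c_prime.cells)
    v = len(comp.vocab)
    pads, retained, erased = _split_cells(c_prime)
    n_candidates = v ** len(erased)
    if n_candidates > enumeration_budget:
        raise BudgetExceededError(
            f"|V|^erased = {n_candidates} exceeds budget {enumeration_budget}; "
            "use importance sampling (is_posterior)"
        )
    npad = len(pads)
    qmat = policy_qmat(policy, comp.vocab, n)
    logq, log1mq = _safe_logs(qmat)

    ids = np.zeros((n_candidates, n - npad), dtype=np.int32)
    for i in retained:
        ids[:, i - npad] = comp.index[c_prime.cells[i]]
    if erased:
        fillers = np.array(
            list(itertools.product(range(v), repeat=len(erased))), dtype=np.int32
        )
        for j, i in enumerate(erased):
            ids[:, i - npad] = fillers[:, j]

    logprior, states = comp.walk(ids)
    logw = logprior.copy()
    for i in retained:  # constant across candidates; kept for interpretability
        logw += logq[comp.index[c_prime.cells[i]], n - i - 1]
    for i in erased:
        logw += log1mq[ids[:, i - npad], n - i - 1]

    weights = _normalize(logw, context="exact posterior")
    ess = 1.0 / float((weights**2).sum())
    return PosteriorEnsemble(weights, ess, ids, npad, comp.vocab, states)


def is_posterior(
    lm: LanguageModelPrior,
    policy: RetentionPolicy,
    c_prime: LossyRepresentation,
    n_particles: int,
    rng: np.random.Generator,
    ess_warning_frac: float = 0.05,
) -> PosteriorEnsemble:
    """Self-normalized importance sampler for P(c | c').

    Proposal: draw erased cells autoregressively from the prior, forcing
    retained cells to their observed tokens. The weight of a particle is the
    product of the prior probabilities of the forced cells times the channel
    likelihood (the proposal terms of the sampled cells cancel against the
    prior).
    """
    if n_particles < 1:
        raise ConfigurationError("n_particles: must be >= 1")
    comp = lm.compiled
    n = len(c_prime.cells)
    pads, retained, erased = _split_cells(c_prime)
    npad = len(pads)
    qmat = policy_qmat(policy, comp.vocab, n)
    logq, log1mq = _safe_logs(qmat)

    p = n_particles
    states = np.full(p, comp.start_state, dtype=np.int64)
    logw = np.zeros(p)
    ids = np.empty((p, n - npad), dtype=np.int32)
    retained_set = set(retained)
    for i in range(npad, n):
        if i in retained_set:
            tok = np.full(p, comp.index[c_prime.cells[i]], dtype=np.int64)
            logw += comp.logdist[states, tok]  # forced-cell prior term
            logw += logq[tok, n - i - 1]  # channel: retained
        else:
            probs = comp.dist[states]
            u = rng.random(p)
            cum = np.cumsum(probs, axis=1)
            tok = np.minimum(
                (cum < u[:, None]).sum(axis=1), len(comp.vocab) - 1
            ).astype(np.int64)
            logw += log1mq[tok, n - i - 1]  # channel: erased
        ids[:, i - npad] = tok
        states = comp.trans[states, tok].astype(np.int64)

    weights = _normalize(logw, context="importance sampling")
    ess = 1.0 / float((weights**2).sum())
    low = ess < ess_warning_frac * n_particles
    if low:
        log.warning(
            "importance-sampling ESS %.1f below %.0f%% of %d particles",
            ess, 100 * ess_warning_frac, n_particles,
        )
    return PosteriorEnsemble(weights, ess, ids, npad, comp.vocab, states, low_ess=low)


def _safe_logs(qmat: np.ndarray):
    with np.errstate(divide="ignore"):
        return np.log(qmat), np.log1p(-qmat)


def _normalize(logw: np.ndarray, context: str) -> np.ndarray:
    total = logsumexp(logw)
    if not np.isfinite(total):
        raise InferenceError(
            f"{context}: all candidate weights are zero "
            f"(max log-weight {logw.max():.2f}); the prior or channel assigns "
            "no support to the observed trace"
        )
    return np.exp(logw - total)


# ---------------------------------------------------------------------------
# lossy next-word distributions and surprisal


def _ensemble(lm, policy, c_prime, settings, rng) -> PosteriorEnsemble:
    if settings.method == "exact":
        return exact_posterior(lm, policy, c_prime, settings.enumeration_budget)
    if settings.method == "is":
        return is_posterior(
            lm, policy, c_prime, settings.n_particles, rng, settings.ess_warning_frac
        )
    try:
        return exact_posterior(lm, policy, c_prime, settings.enumeration_budget)
    except BudgetExceededError:
        return is_posterior(
            lm, policy, c_prime, settings.n_particles, rng, settings.ess_warning_frac
        )


def next_dist_lossy(
    lm: LanguageModelPrior,
    policy: RetentionPolicy,
    c_prime: LossyRepresentation,
    settings: InferenceSettings = InferenceSettings(),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """P(w | c') = sum_c P(w | c) P(c | c'), over the model vocabulary."""
    rng = rng if rng is not None else np.random.default_rng(0)
    ens = _ensemble(lm, policy, c_prime, settings, rng)
    return ensemble_next_dist(lm, ens)


def ensemble_next_dist(lm: LanguageModelPrior, ens: PosteriorEnsemble) -> np.ndarray:
    comp = lm.compiled
    if ens._states is None:
        states = np.array(
            [comp.state_of(comp.encode([t for t in c if t != BOS])) for c in ens.contexts]
        )
    else:
        states = ens._states
    return ens.weights @ comp.dist[states]


def _stochastic_cells(policy, context):
    q = policy.q_vector(context)
    real = np.array([w != BOS for w in context])
    stochastic = real & (q > 0.0) & (q < 1.0)
    fixed_retained = real & (q >= 1.0)
    always_erased = real & (q <= 0.0)
    return q, stochastic, fixed_retained, always_erased


def _masked_cells(context, retained_mask):
    return LossyRepresentation(
        tuple(
            w if (w == BOS or retained_mask[i]) else ERASED
            for i, w in enumerate(context)
        )
    )


def lossy_surprisal(
    lm: LanguageModelPrior,
    policy: RetentionPolicy,
    tokens: Sequence[str],
    index: int,
    n_masks: int = 64,
    settings: InferenceSettings = InferenceSettings(),
    rng: np.random.Generator | None = None,
    keep_per_mask: bool = False,
) -> SurprisalEstimate:
    """Expected surprisal of tokens[index] under the retention channel.

    The expectation over memory traces is exact (all masks enumerated, each
    weighted by its channel probability) when the number of stochastic cells
    and the per-mask enumeration stay inside the configured budgets and the
    method allows it; otherwise masks are Monte-Carlo sampled and the standard
    error across masks is reported.
    """
    if not (0 <= index < len(tokens)):
        raise IndexError(f"index {index} out of range for {len(tokens)} tokens")
    rng = rng if rng is not None else np.random.default_rng(0)
    comp = lm.compiled
    context = pad_context(tokens[:index], policy.n)
    w_id = comp.index[tokens[index]]
    q, stochastic, fixed_retained, always_erased = _stochastic_cells(policy, context)
    n_stoch = int(stochastic.sum())
    n_erasable = int((stochastic | always_erased).sum())

    exact_ok = (
        2**n_stoch <= settings.mask_budget
        and len(comp.vocab) ** n_erasable <= settings.enumeration_budget
    )
    if settings.method == "exact" and not exact_ok:
        raise BudgetExceededError(
            f"exact evaluation needs 2^{n_stoch} masks and |V|^{n_erasable} "
            "contexts; raise the budgets or use importance sampling"
        )

    if settings.method == "exact" or (settings.method == "auto" and exact_ok):
        values, mask_logps = [], []
        stoch_idx = np.flatnonzero(stochastic)
        base = fixed_retained | np.array([w == BOS for w in context])
        exact = InferenceSettings(
            method="exact", enumeration_budget=settings.enumeration_budget
        )
        for bits in itertools.product([True, False], repeat=n_stoch):
            mask = base.copy()
            mask[stoch_idx] = bits
            logp_mask = float(
                np.log(np.where(bits, q[stoch_idx], 1.0 - q[stoch_idx])).sum()
            )
            dist = next_dist_lossy(lm, policy, _masked_cells(context, mask), exact)
            values.append(-np.log(dist[w_id]))
            mask_logps.append(logp_mask)
        mask_p = np.exp(np.array(mask_logps))
        assert abs(mask_p.sum() - 1.0) < 1e-9
        mean = float(mask_p @ np.array(values))
        return SurprisalEstimate(
            mean_nats=mean,
            mc_standard_error=0.0,
            n_masks=len(values),
            n_particles=0,
            method="exact",
            per_mask_values=tuple(values) if keep_per_mask else None,
        )

    values = np.empty(n_masks)
    n_low = 0
    for k in range(n_masks):
        mask = rng.random(len(context)) < q
        ens = is_posterior(
            lm, policy, _masked_cells(context, mask), settings.n_particles, rng,
            settings.ess_warning_frac,
        )
        dist = ensemble_next_dist(lm, ens)
        values[k] = -np.log(dist[w_id])
        n_low += int(ens.low_ess)
    se = float(values.std(ddof=1) / np.sqrt(n_masks)) if n_masks > 1 else float("inf")
    return SurprisalEstimate(
        mean_nats=float(values.mean()),
        mc_standard_error=se,
        n_masks=n_masks,
        n_particles=settings.n_particles,
        method="importance_sampling",
        per_mask_values=tuple(values) if keep_per_mask else None,
        low_ess_fraction=n_low / n_masks,
    )


def grammatical_continuation_prob(
    lm: LanguageModelPrior,
    policy: RetentionPolicy,
    prefix: Sequence[str],
    continuation_set: Sequence[str],
    settings: InferenceSettings = InferenceSettings(),
    n_masks: int = 64,
    rng: np.random.Generator | None = None,
) -> float:
    """Expected probability mass on a continuation set (e.g. all verbs) given
    the lossy representation of a prefix."""
    if len(continuation_set) == 0:
        raise ConfigurationError("continuation_set: empty")
    rng = rng if rng is not None else np.random.default_rng(0)
    comp = lm.compiled
    set_ids = np.array([comp.index[t] for t in continuation_set])
    context = pad_context(prefix, policy.n)
    q, stochastic, fixed_retained, always_erased = _stochastic_cells(policy, context)
    n_stoch = int(stochastic.sum())
    n_erasable = int((stochastic | always_erased).sum())
    exact_ok = (
        2**n_stoch <= settings.mask_budget
        and len(comp.vocab) ** n_erasable <= settings.enumeration_budget
    )

    if settings.method == "exact" or (settings.method == "auto" and exact_ok):
        if not exact_ok:
            raise BudgetExceededError("exact evaluation exceeds budgets")
        total = 0.0
        stoch_idx = np.flatnonzero(stochastic)
        base = fixed_retained | np.array([w == BOS for w in context])
        exact = InferenceSettings(
            method="exact", enumeration_budget=settings.enumeration_budget
        )
        for bits in itertools.product([True, False], repeat=n_stoch):
            mask = base.copy()
            mask[stoch_idx] = bits
            p_mask = float(np.prod(np.where(bits, q[stoch_idx], 1.0 - q[stoch_idx])))
            dist = next_dist_lossy(lm, policy, _masked_cells(context, mask), exact)
            total += p_mask * float(dist[set_ids].sum())
        return total

    vals = np.empty(n_masks)
    for k in range(n_masks):
        mask = rng.random(len(context)) < q
        ens = is_posterior(
            lm, policy, _masked_cells(context, mask), settings.n_particles, rng,
            settings.ess_warning_frac,
        )
        dist = ensemble_next_dist(lm, ens)
        vals[k] = float(dist[set_ids].sum())
    return float(vals.mean())
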