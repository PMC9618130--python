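"""Resource-rational optimization of retention policies.

The policy q_{w,d} is chosen to minimize the expected lossy-context surprisal
of the next word over corpus contexts,

    min_theta  E_{c*, w} E_{c' ~ p(c'|c*)} [ -log P(w | c') ],

subject to the resource constraint that the expected number of retained
context words stays below a bound delta:

    E_{c*} [ sum_i q(w_i, d_i) ] <= delta.

Because expected surprisal is weakly non-increasing in retention (more
retained words can only sharpen the posterior), the inequality constraint
binds at the optimum whenever delta is attainable. The trainer therefore
solves the equality-constrained problem by constraint elimination: after every
gradient step, a shared offset on the retention logits is re-solved (the
expected retention is an exactly computable, monotone function of the offset)
so that the policy sits on the E = delta manifold at all times. The shadow
price of the constraint — the classical dual variable — is reported in the
trace as the ratio of the directional objective and retention gradients along
the offset direction. The gradient through the discrete retention masks uses
the score-function (likelihood-ratio) estimator with an
exponential-moving-average baseline. The reconstruction posterior knows the
current retention probabilities, so the inner surprisal is re-estimated under
the live policy at every step (no stale caching).

A brute-force oracle, :func:`exhaustive_policy_search`, evaluates every policy
on a (word x distance) probability grid exactly — including the dependence of
the Bayesian posterior on the candidate policy — and is used to certify the
trained policies on tiny instances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from ._util import child_rng
from .exceptions import ConfigurationError, TrainingError
from .grammar import CorpusSample
from .inference import (
    InferenceSettings,
    ensemble_next_dist,
    exact_posterior,
    is_posterior,
    policy_qmat,
)
from .lm import BOS, LanguageModelPrior
from .retention import (
    LearnedPolicy,
    RetentionPolicy,
    TabularPolicy,
    UniformPolicy,
    expected_retained,
    pad_context,
)
from .retention import apply_mask as _apply_mask

import pandas as pd


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of the constrained policy optimization.

    delta is the retention bound in words (0 <= delta <= n); n is the context
    window length N. Counts and rates below are conventional stochastic-
    optimization knobs; the defaults are sized for vocabularies of a few dozen
    types and N around 10-20.
    """

    delta: float
    n: int = 20
    epochs: int = 800
    batch_size: int = 24
    n_masks_per_example: int = 4
    learning_rate: float = 0.08
    lr_decay: float = 0.1  # final learning rate as a fraction of the initial
    #: retained for the dual-ascent variant; the projection solver ignores it
    dual_learning_rate: float = 0.25
    baseline_decay: float = 0.9
    hidden: int = 8
    word_repr: str = "frequency"  # or "onehot"
    seed: int = 0
    max_examples: int = 1500
    holdout_frac: float = 0.1
    constraint_tol: float = 0.5
    # stand-in for the implicit smoothness of large-scale stochastic fits:
    # without it the exact small-scale optimum is bang-bang in word identity
    weight_decay: float = 0.05
    inference: InferenceSettings = field(
        default_factory=lambda: InferenceSettings(method="is", n_particles=64)
    )

    def __post_init__(self):
        if self.delta < 0 or self.delta > self.n:
            raise ConfigurationError(f"delta: must lie in [0, {self.n}], got {self.delta}")
        for name in ("epochs", "batch_size", "n_masks_per_example", "max_examples"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name}: must be >= 1")


@dataclass
class TrainingTrace:
    """Per-epoch convergence diagnostics."""

    frame: pd.DataFrame  # epoch, objective, expected_retained, lam, grad_norm
    seed: int
    converged: bool = True

    def save(self, path):
        self.frame.to_csv(path, sep="\t", index=False)


def training_windows(corpus: CorpusSample, n: int) -> list[tuple[tuple, str]]:
    """(context, next word) pairs: length-n windows of the corpus stream, each
    anchored at a sentence start and running rightward across "." boundaries."""
    stream: list[str] = []
    starts: list[int] = []
    for s in corpus.sentences:
        starts.append(len(stream))
        stream.extend(s)
    out = []
    for s0 in starts:
        if s0 + n < len(stream):
            out.append((tuple(stream[s0 : s0 + n]), stream[s0 + n]))
    if not out:
        raise ConfigurationError(
            f"corpus too small to form any {n}-token context windows"
        )
    return out


def _mask_loss(lm, policy, context, target_id, mask, settings, rng) -> float:
    c_prime = _apply_mask(context, mask)
    if settings.method == "exact":
        ens = exact_posterior(lm, policy, c_prime, settings.enumeration_budget)
    else:
        ens = is_posterior(lm, policy, c_prime, settings.n_particles, rng, 0.0)
    return float(-np.log(ensemble_next_dist(lm, ens)[target_id]))


class _Adam:
    def __init__(self, params: dict, lr: float):
        self.lr = lr
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] = params[k] - self.lr * mhat / (np.sqrt(vhat) + eps)


def _cell_counts(examples, index, n) -> np.ndarray:
    """Average per-context occupancy of each (word, distance) logit cell."""
    counts = np.zeros(len(index) * n)
    for ctx, _ in examples:
        m = len(ctx)
        for i, w in enumerate(ctx):
            if w != BOS:
                counts[index[w] * n + (m - i - 1)] += 1.0
    return counts / len(examples)


def train_policy(
    lm: LanguageModelPrior,
    corpus: CorpusSample,
    config: TrainingConfig,
) -> tuple[LearnedPolicy, TrainingTrace]:
    """Solve the constrained retention problem on corpus contexts.

    Returns the trained policy and its trace; raises :class:`TrainingError`
    (carrying the trace) if the retention constraint is still violated by more
    than ``constraint_tol`` words after the final epoch.
    """
    rng = child_rng(config.seed, "train")
    windows = training_windows(corpus, config.n)
    if len(windows) > config.max_examples:
        keep = rng.choice(len(windows), size=config.max_examples, replace=False)
        windows = [windows[i] for i in keep]
    n_hold = max(1, int(len(windows) * config.holdout_frac))
    holdout, train = windows[:n_hold], windows[n_hold:]
    if not train:
        raise ConfigurationError("corpus too small after holdout split")

    vocab = list(lm.vocabulary)
    comp = lm.compiled
    # corpus log-frequency feature for the retention network
    freq = np.full(len(vocab), 0.5)
    vidx = {w: i for i, w in enumerate(vocab)}
    for s in corpus.sentences:
        for t in s:
            freq[vidx[t]] += 1.0
    policy = LearnedPolicy.init(
        vocab,
        n=config.n,
        hidden=config.hidden,
        log_freq=np.log(freq),
        seed=int(child_rng(config.seed, "init").integers(2**31 - 1)),
        init_logit=_init_logit(config.delta, config.n),
        word_repr=config.word_repr,
    )
    counts = _cell_counts(train, policy.index, config.n)

    adam = _Adam(policy.params, config.learning_rate)
    _project_offset(policy, counts, config.delta)
    baseline = None
    rows = []
    n_cells = len(vocab) * config.n
    for epoch in range(config.epochs):
        adam.lr = config.learning_rate * (
            config.lr_decay + (1.0 - config.lr_decay) * (1.0 - epoch / config.epochs)
        )
        q_tab, cache = policy.forward()
        q_flat = q_tab.reshape(-1)
        e_retained = float(counts @ q_flat)

        order = rng.permutation(len(train))[: config.batch_size]
        dz_score = np.zeros(n_cells)
        losses = []
        k_masks = config.n_masks_per_example
        for ex in order:
            ctx, target = train[ex]
            target_id = comp.index[target]
            m = len(ctx)
            real = [i for i, w in enumerate(ctx) if w != BOS]
            cells = np.array([policy.index[ctx[i]] * config.n + (m - i - 1) for i in real])
            q_ctx = q_flat[cells]
            ex_rng = child_rng(config.seed, "is", epoch, int(ex))
            ex_losses = np.empty(k_masks)
            ex_bits = np.empty((k_masks, len(cells)), dtype=bool)
            for k in range(k_masks):
                bits = rng.random(len(cells)) < q_ctx
                mask = np.ones(m, dtype=bool)
                mask[real] = bits
                ex_losses[k] = _mask_loss(
                    lm, policy, ctx, target_id, mask, config.inference, ex_rng
                )
                ex_bits[k] = bits
            losses.extend(ex_losses)
            if k_masks > 1:
                # leave-one-out baseline: mean of the example's other masks
                total = ex_losses.sum()
                adv = ex_losses - (total - ex_losses) / (k_masks - 1)
            else:
                adv = ex_losses - (baseline if baseline is not None else ex_losses.mean())
            dz_score[cells] += adv @ (ex_bits - q_ctx)
        batch_mean = float(np.mean(losses))
        baseline = (
            batch_mean
            if baseline is None
            else config.baseline_decay * baseline + (1 - config.baseline_decay) * batch_mean
        )

        dz = dz_score / len(losses)
        # project out the component normal to the E = delta manifold (it is
        # exactly cancelled by the offset re-solve and would otherwise inflate
        # the network weights until the hidden layer saturates); its magnitude
        # is the shadow price of the constraint
        de_dz = counts * q_flat * (1.0 - q_flat)
        norm2 = float(de_dz @ de_dz)
        lam = -float(dz @ de_dz) / max(norm2, 1e-12)
        dz = dz + lam * de_dz
        grads = policy.grad_logits(cache, dz)
        # b2 is owned by the constraint projection and stays undecayed
        for k in ("W1", "b1", "w2"):
            grads[k] = grads[k] + config.weight_decay * policy.params[k]
        gnorm = float(np.sqrt(sum((g**2).sum() for g in grads.values())))
        adam.step(policy.params, grads)
        policy.invalidate()
        _project_offset(policy, counts, config.delta)

        rows.append(
            {
                "epoch": epoch,
                "objective": batch_mean,
                "expected_retained": e_retained,
                "lam": lam,
                "grad_norm": gnorm,
            }
        )

    trace = TrainingTrace(pd.DataFrame(rows), seed=config.seed)
    gap = constraint_gap(policy, [c for c, _ in train], config.delta)
    if gap > config.constraint_tol:
        trace.converged = False
        raise TrainingError(
            f"retention constraint violated after {config.epochs} epochs: "
            f"expected retained exceeds delta by {gap:.3f} words "
            f"(tolerance {config.constraint_tol})",
            trace=trace,
        )
    return policy, trace


def _project_offset(policy: LearnedPolicy, counts: np.ndarray, delta: float) -> None:
    """Shift the output bias so expected retention equals delta exactly.

    E(beta) = sum_cells counts * sigmoid(z + beta) is strictly increasing in
    beta, so a bisection suffices. When delta is outside the attainable range
    (e.g. delta = N requires q = 1 everywhere) the offset saturates at the
    bracket edge, leaving E as close to delta as the logistic link allows.
    """
    q, cache = policy.forward()
    z = cache["z"]
    lo, hi = -16.0, 16.0

    def e_of(beta):
        return float(counts @ (1.0 / (1.0 + np.exp(-(z + beta)))))

    if e_of(lo) > delta:
        beta = lo
    elif e_of(hi) < delta:
        beta = hi
    else:
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if e_of(mid) < delta:
                lo = mid
            else:
                hi = mid
        beta = 0.5 * (lo + hi)
    if beta != 0.0:
        policy.params["b2"] = policy.params["b2"] + beta
        policy.invalidate()


def _init_logit(delta: float, n: int) -> float:
    """Start the retention probabilities near the feasible boundary delta/n."""
    p = min(max(delta / n, 0.05), 0.95)
    return float(np.log(p / (1.0 - p)))


def constraint_gap(policy: RetentionPolicy, corpus_or_contexts, delta: float) -> float:
    """expected retained words minus delta (positive = constraint violated)."""
    if isinstance(corpus_or_contexts, CorpusSample):
        contexts = [c for c, _ in training_windows(corpus_or_contexts, policy.n)]
    else:
        contexts = [pad_context(c, policy.n) for c in corpus_or_contexts]
    return expected_retained(policy, contexts) - delta


def evaluate_policy_objective(
    lm: LanguageModelPrior,
    policy: RetentionPolicy,
    examples: list[tuple[tuple, str]],
    settings: InferenceSettings = InferenceSettings(method="is", n_particles=128),
    n_masks: int = 16,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean lossy surprisal (nats/word) of a policy on (context, target)
    examples, with its Monte-Carlo standard error."""
    comp = lm.compiled
    vals = []
    for j, (ctx, target) in enumerate(examples):
        target_id = comp.index[target]
        ctx = pad_context(ctx, policy.n)
        q = policy.q_vector(ctx)
        rng = child_rng(seed, "eval", j)
        for k in range(n_masks):
            mask = rng.random(len(ctx)) < q
            vals.append(
                _mask_loss(lm, policy, ctx, target_id, mask, settings, rng)
            )
    vals = np.array(vals)
    return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(len(vals)))


def exact_policy_objective(
    lm: LanguageModelPrior,
    policy: RetentionPolicy,
    examples: list[tuple[tuple, str]],
    enumeration_budget: int = 10**6,
    mask_budget: int = 2**14,
) -> float:
    """Exact expected lossy surprisal (nats/word): all masks and all context
    completions enumerated. Tiny instances only."""
    from .inference import lossy_surprisal

    settings = InferenceSettings(
        method="exact", enumeration_budget=enumeration_budget, mask_budget=mask_budget
    )
    total = 0.0
    for ctx, target in examples:
        est = lossy_surprisal(
            lm, policy, tuple(ctx) + (target,), len(ctx), settings=settings
        )
        total += est.mean_nats
    return total / len(examples)


def matched_uniform_policy(
    policy: RetentionPolicy, contexts: list, n: int
) -> UniformPolicy:
    """Uniform policy with the same expected retention on the given contexts."""
    padded = [pad_context(c, n) for c in contexts]
    target = expected_retained(policy, padded)
    n_real = np.mean([sum(w != BOS for w in c) for c in padded])
    return UniformPolicy(min(1.0, target / n_real), n)


# ---------------------------------------------------------------------------
# brute-force oracle


@dataclass
class SearchResult:
    best_objective: float
    best_policy: TabularPolicy
    n_policies: int
    n_feasible: int


def exhaustive_policy_search(
    lm: LanguageModelPrior,
    corpus_or_examples,
    delta: float,
    grid: list[float],
    n: int = 3,
    max_policies: int = 10**6,
) -> SearchResult:
    """Exact objective for every (word x distance) tabular policy on a grid.

    The objective is evaluated by full mask x context enumeration, with the
    Bayesian posterior recomputed under each candidate policy (the channel
    term of erased cells depends on the policy). Only viable for tiny
    vocabularies and short windows.
    """
    if isinstance(corpus_or_examples, CorpusSample):
        examples = training_windows(corpus_or_examples, n)
    else:
        examples = list(corpus_or_examples)
    comp = lm.compiled
    vocab = list(lm.vocabulary)
    vidx = {w: i for i, w in enumerate(vocab)}
    n_cells = len(vocab) * n
    n_pol = len(grid) ** n_cells
    if n_pol > max_policies:
        raise ConfigurationError(
            f"{len(grid)}^{n_cells} = {n_pol} grid policies exceed the budget {max_policies}"
        )
    grid = np.asarray(grid, dtype=float)
    assign = np.array(
        list(itertools.product(range(len(grid)), repeat=n_cells)), dtype=np.int8
    )
    a = grid[assign]  # (P, cells): q value per policy per (word, distance) cell
    with np.errstate(divide="ignore"):
        log_a = np.log(a)
        log_1ma = np.log1p(-a)

    objective = np.zeros(n_pol)
    counts = np.zeros(n_cells)
    v = len(vocab)
    for ctx, target in examples:
        ctx = pad_context(ctx, n)
        target_id = comp.index[target]
        real_idx = [i for i, w in enumerate(ctx) if w != BOS]
        cells = np.array([vidx[ctx[i]] * n + (len(ctx) - i - 1) for i in real_idx])
        counts[cells] += 1.0

        # enumerate candidate completions once per erased-set (mask)
        ctx_obj = np.zeros(n_pol)
        for bits in itertools.product([True, False], repeat=len(real_idx)):
            bits = np.array(bits)
            # mask probability per policy
            log_pm = np.where(bits, log_a[:, cells], log_1ma[:, cells]).sum(axis=1)
            finite = log_pm > -np.inf
            if not finite.any():
                continue
            erased = [real_idx[j] for j in range(len(real_idx)) if not bits[j]]
            n_cand = v ** len(erased)
            ids = np.zeros((n_cand, len(real_idx)), dtype=np.int32)
            for j, i in enumerate(real_idx):
                ids[:, j] = vidx[ctx[i]]
            if erased:
                fill = np.array(
                    list(itertools.product(range(v), repeat=len(erased))), dtype=np.int32
                )
                for j, i in enumerate(erased):
                    ids[:, real_idx.index(i)] = fill[:, j]
            logprior, states = comp.walk(ids)
            p_next = comp.dist[states, target_id]
            # channel term per candidate per policy: erased cells only
            logw = np.broadcast_to(logprior, (n_pol, n_cand)).copy()
            for j, i in enumerate(erased):
                cell_ids = ids[:, real_idx.index(i)] * n + (len(ctx) - i - 1)
                logw = logw + log_1ma[:, cell_ids]
            with np.errstate(divide="ignore", invalid="ignore"):
                logz = logsumexp(logw, axis=1)
                lognum = logsumexp(logw, axis=1, b=np.maximum(p_next, 1e-300))
                loss = -(lognum - logz)
            contrib = np.where(finite & np.isfinite(loss), np.exp(log_pm) * loss, 0.0)
            ctx_obj += contrib
        objective += ctx_obj / len(examples)

    e_retained = a @ (counts / len(examples))
    feasible = e_retained <= delta + 1e-9
    if not feasible.any():
        nearest = np.argsort(e_retained)[:3]
        raise ConfigurationError(
            "no feasible policy in grid for delta="
            f"{delta}; smallest expected retentions: {e_retained[nearest].round(3)}"
        )
    masked = np.where(feasible, objective, np.inf)
    best = int(np.argmin(masked))
    table = a[best].reshape(v, n)
    return SearchResult(
        best_objective=float(objective[best]),
        best_policy=TabularPolicy(vocab, table, n),
        n_policies=n_pol,
        n_feasible=int(feasible.sum()),
    )
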