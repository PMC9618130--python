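# Methods

## The model

`lossyctx` implements resource-rational lossy-context surprisal: a model of
incremental processing difficulty in which the comprehender's memory of the
preceding context is an independently-erased trace, reconstruction of the
context is Bayesian under a language-model prior, and difficulty on a word is
its surprisal under the reconstruction-marginal predictive distribution.

Formally, a context is a fixed-length window c* = c*_1 … c*_N of the N most
recent tokens. A retention policy assigns each context word a probability
q(w, d) of surviving in memory, where d counts how many words have been
observed since it (d = 1 is the immediately preceding word). Erasure is
independent across cells and erased cells are replaced by a position-preserving
placeholder, so the trace c′ ∈ (V ∪ {⟨?⟩})^N records *where* material was lost
but not what it was. Given the prior P(c) and the channel p(c′|c) =
∏ᵢ q or (1−q), the comprehender's next-word distribution marginalizes over
contexts,

    P(w | c′) = Σ_c P(w | c) P(c | c′),      P(c | c′) ∝ P(c) p(c′ | c),

and the model's difficulty prediction for a word is the expected surprisal
E_{c′}[−log P(w | c′)], in nats.

The policy itself is *chosen*, not stipulated: q is parameterized by a small
network over (word representation, distance) and optimized to minimize the
corpus-average expected surprisal subject to a capacity bound on the expected
number of retained words,

    min_θ E_{c*,w} E_{c′}[−log P(w | c′)]   s.t.   E[#retained] ≤ δ.

δ (in words, 0 ≤ δ ≤ N) is the model's single resource parameter.

## Priors

Two exact desk-scale priors stand in for a large neural language model:

- **Enumerative grammar prior.** The default study language is a finite
  probabilistic grammar (below); the prior is the renewal process obtained by
  concatenating i.i.d. sentences of that language, compiled into dense
  state-transition tables (trie states; the terminator "." resets to the
  sentence-initial state, so windows may span sentence boundaries). It is
  interpolated with a uniform distribution at ε = 10⁻⁴ so that every sequence
  keeps nonzero probability — Bayesian reconstruction requires full-support
  priors, and the residual ε mass is the "smoothing leak" visible in the
  all-retain limit of the production experiment.
- **Add-k n-gram models** fit on a corpus stream, used for tiny hand-checkable
  instances and as the prior of the brute-force training oracle.

Windows are anchored at sentence starts (stimulus contexts shorter than N are
left-padded with an always-retained begin-of-sequence symbol) and run
rightward across "." boundaries. This keeps the prior exactly computable; the
corresponding limitation is that the model always conditions on the sentence
starting inside the window rather than marginalizing over unseen pre-window
material. The competing lower-depth analyses the theory depends on (e.g. "the
report **by** the doctor … annoyed the patient") exist as same-length
alternatives because prepositional modifiers can host relative clauses.

## The synthetic language

The default grammar emulates the statistical structure that drives difficulty
in nested English clauses, with a ~24-type vocabulary chosen so that exact
enumeration stays feasible:

- eight abstract nouns whose "that"-complement probabilities span 0.70 … 0.007
  (the *embedding bias* manipulation, matching the attested range for nouns
  like "fact" vs "report");
- human nouns and determinerless proper names filling subject, object and
  relative-clause slots (names keep the function-word share of the language
  closer to natural text);
- object relatives introduced by "that" or "who" (0.6/0.4), so the
  complementizer token is a genuinely frequent, hence forgettable, function
  word;
- prepositional post-nominal modifiers ("by"/"from", total 0.20) providing the
  surface-similar competitor structures that close with fewer verbs;
- hard selectional restrictions: some transitive verbs accept both abstract
  and human subjects ("annoyed", "pleased"), others only human subjects
  ("cured", "mistrusted") — the compatibility manipulation (a soft-violation
  option exists for robustness checks);
- mild selectional preferences (weight ×4) of nouns for characteristic
  predicates, paired so that preference is orthogonal to embedding bias.
  These emulate the lexical cohesion of natural text; without them distant
  content-word identity carries no predictive value and the rational policy
  correctly — but unrealistically for natural language — erases distant nouns
  outright.

Recursion is truncated at depth 3 by renormalizing rule probabilities at the
cap, making the language finite (~2×10⁵ sentences). Corpora are sampled
directly from the exact enumeration, so corpus statistics are provably
consistent with the analytic probabilities used for embedding bias and the
prior. Stimuli are a factorial crossing of 8 frames × 8 nouns ×
{One, Two, Three}, with verb compatibility crossed within Two/Three; every
item's critical context is extended to a full 12-token window by fixed
human-only filler sentences, so that all conditions present the same amount
of erasable material (and the zero-retention limit is condition-blind).

## Inference

- **Exact route** (oracle and small instances): enumerate all completions of
  the erased cells, weight by prior × channel; expectation over traces by
  enumerating all retention masks weighted by their channel probability.
- **Importance sampling** (general): erased cells are drawn autoregressively
  from the prior with retained cells forced; the self-normalized weight
  reduces to the prior terms of the forced cells times the channel likelihood.
  Effective sample size is reported, with a logged warning and a flag when
  ESS < 5% of the particle count. The sampler is validated against the exact
  route on randomized small instances (3 MC standard errors, ≥95% of
  instances).
- Reported difficulty is the expectation over traces; sampled-mask estimates
  carry the standard error across masks (each mask uses independent
  particles, so between-mask variance captures both noise sources).

## Policy optimization

- **Estimator.** Score-function (likelihood-ratio) gradients through the
  discrete masks, with a leave-one-out baseline across the masks of each
  example. The inner surprisal is re-estimated under the live policy at every
  step because the reconstruction posterior knows the retention probabilities
  (the channel term depends on the candidate policy).
- **Constraint.** Expected retention is an exactly computable, monotone
  function of a shared offset on the retention logits, and expected surprisal
  is weakly non-increasing in retention, so the bound binds at any attainable
  optimum. The trainer therefore eliminates the constraint: after every Adam
  step the offset is re-solved by bisection so the policy sits on the
  E[#retained] = δ manifold, and the gradient component normal to that
  manifold — whose magnitude is the constraint's shadow price, recorded in
  the trace — is projected out (otherwise it inflates the network weights
  until the hidden layer saturates).
- **Parameterization.** One hidden tanh layer (8 units) over a word
  representation plus a smooth distance basis (d/N, (d/N)², two exponential
  decays). The default word representation is low-dimensional — standardized
  log corpus frequency — rather than one-hot: with exact optimization over a
  two-dozen-type vocabulary, one-hot resolution lets the optimizer pin
  individual rare structure markers at q ≈ 1 (their count-weighted budget
  cost is negligible), a solution unreachable by stochastic fits over a
  50k-type vocabulary where retention must follow shared features. Weight
  decay (0.05) on the network weights similarly stands in for the implicit
  smoothness of large-scale stochastic training; without it the exact
  small-scale optimum is bang-bang in word identity. A one-hot representation
  remains available (`word_repr="onehot"`) and is used on tiny instances
  where the brute-force grid oracle defines the target.
- **Oracle.** `exhaustive_policy_search` evaluates every (word × distance)
  grid policy exactly, including the dependence of the posterior on the
  candidate policy, and certifies trained policies on tiny instances (within
  0.05 nats of the grid optimum; grid optimum non-increasing in δ).

## Experiments and statistics

The harness scores each stimulus's critical word under trained policies at
δ ∈ {2, 6, 12} (N = 12; the featured δ = N/2 mirrors the middle of the
three-phase regime), the retention-matched uniform and window baselines,
veridical surprisal, and DLT integration cost (1 + intervening new discourse
referents per resolved dependency; referents are nouns and finite verbs;
annotations come from the generator's known frame layouts, never from
parsing). Contrasts are:

- depth: paired Three − Two within frame × noun × compatibility cells;
- embedding-bias slopes: OLS within One; within-cell-demeaned OLS pooled over
  Two/Three;
- compatibility: paired Compatible − Incompatible;
- production: slope of the non-verb continuation mass at the obligatory-verb
  point on embedding bias (the model scores distributions rather than
  sampling free-text completions, so "ungrammatical completion" is the
  probability mass on non-verb continuations where the final verb is
  required).

Uncertainty is a seeded cluster bootstrap (250 resamples) over frame × noun
units, which preserves the pairing that the contrasts rely on; this replaces
the mixed-effects machinery appropriate for human data. Phase behavior is
summarized by the item-level correlation with veridical surprisal (→ 1 as
δ → N) and by the standard deviation of the Two/Three condition × noun cell
means, which covers both the depth gap and the bias slopes ("indistinctly
flat" at low δ means both collapse).

## Problem sizes and defaults

| quantity | default | note |
| --- | --- | --- |
| window length N | 12 | length of a Three-condition critical context |
| retention bound δ | {2, 6, 12} | featured value N/2 = 6 |
| corpus | 3000 sentences | sampled from the exact enumeration |
| training | 800 epochs × 24 examples × 4 masks | ~1 min/bound on one core |
| IS particles | 64 (training) / 128 (evaluation) / 10⁴ (oracle checks) | |
| masks per item | 48–64 | expectation over traces |
| bootstrap | 250 cluster resamples | |
| prior smoothing ε | 10⁻⁴ | full-support requirement |

## What the synthetic setting does and does not show

The generator reproduces the *relational* structure of the phenomenon —
graded embedding bias, depth rarity, selectional compatibility, competing
lower-depth surface analyses, recency- and frequency-structured optimal
retention — under a prior known exactly, which is what makes the oracle
validation and the brute-force policy search possible. It does not reproduce
the scale or heterogeneity of natural text: vocabulary is tiny, sentence
variety is enumerable, and several scale-dependent regularities (the
smoothness of fitted retention, the predictive value of distant content
words) must be imposed through the parameterization and the lexical-cohesion
preferences rather than emerging from data volume. Passing tests therefore
show that the mechanism produces the signature difficulty pattern under
faithfully-structured toy conditions, not that it would do so for arbitrary
natural-language corpora. Effect magnitudes are in nats under the toy prior
and are not comparable to human reading times; only signs, orderings, and
phase structure transfer.

## Known limitations

- Window anchoring at sentence starts conditions on known sentence onset
  rather than marginalizing over pre-window material.
- The importance-sampling proposal (prior-autoregressive with forced retained
  cells) can have low effective sample size when retained cells are unlikely
  under the proposal prefix; estimates remain oracle-validated but noisy, and
  low-ESS fractions are surfaced in the estimates.
- The retention policy is context-independent by design (q depends only on
  word identity and distance), so attention-like or whole-sequence policies
  are out of scope.
- Training is stochastic; with the default budgets the qualitative structure
  (recency, frequency, phases, signature pattern) is stable under the
  recorded seeds, but individual retention probabilities vary between runs.
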