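"""Experiment harness: difficulty contrasts, retention-bound phases, baseline
dissociations, and the production prediction.

The harness scores every stimulus item's critical word under a set of
predictors (trained lossy-context surprisal per retention bound, uniform and
window memory baselines, veridical surprisal, DLT), then summarizes the
contrasts the theory makes distinctive predictions about:

* depth: mean critical surprisal in Three minus Two;
* embedding-bias slopes: positive in One, negative in Two/Three;
* semantic compatibility: Compatible minus Incompatible within Two/Three;
* production: probability of an ungrammatical (verb-less) continuation at the
  obligatory-verb point, decreasing in embedding bias.

Uncertainty is quantified by a seeded bootstrap over items. Every summary is
a pure function of the persisted result table and the bootstrap seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import child_rng
from .exceptions import ConfigurationError
from .grammar import GrammarSpec, StimulusItem, annotate_stimuli
from .inference import (
    InferenceSettings,
    grammatical_continuation_prob,
    lossy_surprisal,
)
from .lm import LanguageModelPrior, embedding_bias, plain_surprisal
from .retention import RetentionPolicy, UniformPolicy, WindowPolicy
from .baselines import dlt_integration_cost

DEFAULT_SETTINGS = InferenceSettings(method="is", n_particles=128)


@dataclass
class ExperimentResult:
    """Long-format table of per-item critical-word difficulty values."""

    frame: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def save(self, path_tsv, path_meta=None):
        self.frame.to_csv(path_tsv, sep="\t", index=False)
        if path_meta:
            with open(path_meta, "w") as fh:
                json.dump(self.metadata, fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path_tsv, path_meta=None) -> "ExperimentResult":
        meta = {}
        if path_meta:
            with open(path_meta) as fh:
                meta = json.load(fh)
        frame = pd.read_csv(path_tsv, sep="\t", keep_default_na=False, na_values=[""])
        return cls(frame, meta)


@dataclass(frozen=True)
class Effect:
    estimate: float
    ci_low: float
    ci_high: float

    @property
    def sign(self) -> int:
        return int(np.sign(self.estimate))

    @property
    def excludes_zero(self) -> bool:
        return self.ci_low > 0 or self.ci_high < 0


@dataclass(frozen=True)
class EffectSummary:
    """Contrasts at the critical word for one predictor at one delta."""

    predictor: str
    delta: float | None
    depth_effect: Effect  # Three - Two
    bias_slope_one: Effect
    bias_slope_two_three: Effect
    compatibility_effect: Effect  # Compatible - Incompatible
    interaction_bias_by_thatclause: Effect  # slope(One) - slope(Two/Three)
    n_boot: int
    seed: int


def noun_biases(lm: LanguageModelPrior, nouns: Sequence[str]) -> dict[str, float]:
    return {n: embedding_bias(lm, n) for n in nouns}


def run_reading_time_experiment(
    lm: LanguageModelPrior,
    policies: Mapping[str, tuple[RetentionPolicy, float | None]],
    stimuli: Sequence[StimulusItem],
    settings: InferenceSettings = DEFAULT_SETTINGS,
    n_masks: int = 48,
    seed: int = 0,
    include_plain: bool = True,
    include_dlt: bool = True,
) -> ExperimentResult:
    """Critical-word difficulty for every item under every predictor."""
    biases = noun_biases(lm, sorted({it.noun_id for it in stimuli}))
    annotations = annotate_stimuli(stimuli) if include_dlt else {}
    rows = []

    def add(item, predictor, delta, value, se):
        rows.append(
            {
                "item_id": item.item_id,
                "condition": item.condition,
                "compatibility": item.compatibility,
                "noun_id": item.noun_id,
                "embedding_bias": biases[item.noun_id],
                "delta": np.nan if delta is None else delta,
                "predictor": predictor,
                "mean_nats": value,
                "se": se,
            }
        )

    for item in stimuli:
        if include_plain:
            add(item, "plain_surprisal", None,
                plain_surprisal(lm, item.scored_tokens, item.scored_index), 0.0)
        if include_dlt:
            add(item, "dlt", None,
                float(dlt_integration_cost(annotations[item.item_id], item.critical_index)),
                0.0)
        for name, (policy, delta) in policies.items():
            rng = child_rng(seed, "rt", name, item.item_id)
            est = lossy_surprisal(
                lm, policy, item.scored_tokens, item.scored_index,
                n_masks=n_masks, settings=settings, rng=rng,
            )
            add(item, name, delta, est.mean_nats, est.mc_standard_error)

    meta = {
        "seed": seed,
        "n_masks": n_masks,
        "n_particles": settings.n_particles,
        "predictors": sorted({r["predictor"] for r in rows}),
    }
    return ExperimentResult(pd.DataFrame(rows), meta)


# ---------------------------------------------------------------------------
# effect statistics


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0.0:
        return 0.0
    return float(x @ (y - y.mean()) / denom)


def _grouped_slope(df: pd.DataFrame) -> float:
    """Bias slope after removing condition x compatibility group means."""
    parts_x, parts_y = [], []
    for _, g in df.groupby(["condition", "compatibility"]):
        parts_x.append(g["embedding_bias"].to_numpy() - g["embedding_bias"].mean())
        parts_y.append(g["mean_nats"].to_numpy() - g["mean_nats"].mean())
    x = np.concatenate(parts_x)
    y = np.concatenate(parts_y)
    denom = float(x @ x)
    return 0.0 if denom == 0.0 else float(x @ y / denom)


def _cluster_of(item_id: str) -> str:
    """Frame x noun cluster: the paired unit across conditions."""
    parts = item_id.split(":")
    return ":".join(parts[:2]) if len(parts) >= 2 else item_id


def _stats(df: pd.DataFrame) -> dict[str, float]:
    one = df[df.condition == "One"]
    sub23 = df[df.condition != "One"]

    # depth contrast is paired within frame x noun x compatibility cells, so
    # lexical variation between stimuli does not enter the contrast
    wide = sub23.pivot_table(
        index=["cluster", "compatibility"], columns="condition",
        values="mean_nats", aggfunc="mean",
    )
    if {"Two", "Three"} <= set(wide.columns):
        depth = float((wide["Three"] - wide["Two"]).mean())
    else:
        depth = np.nan

    out = {
        "depth_effect": depth,
        "bias_slope_one": _ols_slope(
            one.embedding_bias.to_numpy(), one.mean_nats.to_numpy()
        ),
        "bias_slope_two_three": _grouped_slope(sub23),
    }
    if set(sub23.compatibility) >= {"Compatible", "Incompatible"}:
        cw = sub23.pivot_table(
            index=["cluster", "condition"], columns="compatibility",
            values="mean_nats", aggfunc="mean",
        )
        out["compatibility_effect"] = float((cw["Compatible"] - cw["Incompatible"]).mean())
    else:
        out["compatibility_effect"] = np.nan
    out["interaction_bias_by_thatclause"] = (
        out["bias_slope_one"] - out["bias_slope_two_three"]
    )
    return out


def _bootstrap(df: pd.DataFrame, n_boot: int, seed: int) -> dict[str, Effect]:
    df = df.assign(cluster=df.item_id.map(_cluster_of))
    point = _stats(df)
    clusters = df.cluster.unique()
    groups = {c: g for c, g in df.groupby("cluster")}
    rng = child_rng(seed, "boot")
    samples = {k: [] for k in point}
    for _ in range(n_boot):
        pick = rng.choice(clusters, size=len(clusters), replace=True)
        boot = pd.concat(
            [groups[c].assign(cluster=f"{c}#{j}") for j, c in enumerate(pick)],
            ignore_index=True,
        )
        s = _stats(boot)
        for k, v in s.items():
            samples[k].append(v)
    out = {}
    for k, v in point.items():
        arr = np.array(samples[k], dtype=float)
        arr = arr[~np.isnan(arr)]
        if np.isnan(v) or len(arr) == 0:
            out[k] = Effect(v, np.nan, np.nan)
        else:
            out[k] = Effect(v, float(np.percentile(arr, 2.5)), float(np.percentile(arr, 97.5)))
    return out


def summarize_effects(
    result: ExperimentResult,
    predictor: str,
    delta: float | None = None,
    n_boot: int = 250,
    seed: int = 0,
) -> EffectSummary:
    """Depth, bias-slope, and compatibility contrasts with bootstrap CIs."""
    df = result.frame
    sub = df[df.predictor == predictor]
    if delta is not None:
        sub = sub[np.isclose(sub.delta, delta)]
    if sub.empty:
        raise ConfigurationError(
            f"no rows for predictor {predictor!r}"
            + (f" at delta={delta}" if delta is not None else "")
        )
    for cond in ("One", "Two", "Three"):
        if (sub.condition == cond).sum() == 0:
            raise ConfigurationError(f"no items in condition {cond!r} for {predictor!r}")
    effects = _bootstrap(sub, n_boot, seed)
    return EffectSummary(
        predictor=predictor,
        delta=delta,
        depth_effect=effects["depth_effect"],
        bias_slope_one=effects["bias_slope_one"],
        bias_slope_two_three=effects["bias_slope_two_three"],
        compatibility_effect=effects["compatibility_effect"],
        interaction_bias_by_thatclause=effects["interaction_bias_by_thatclause"],
        n_boot=n_boot,
        seed=seed,
    )


def sign_table(summaries: Mapping[str, EffectSummary]) -> pd.DataFrame:
    rows = []
    for name, s in summaries.items():
        for eff_name in (
            "depth_effect",
            "bias_slope_one",
            "bias_slope_two_three",
            "compatibility_effect",
        ):
            eff: Effect = getattr(s, eff_name)
            rows.append(
                {
                    "predictor": name,
                    "effect": eff_name,
                    "estimate": eff.estimate,
                    "ci_low": eff.ci_low,
                    "ci_high": eff.ci_high,
                    "sign": eff.sign if not np.isnan(eff.estimate) else 0,
                    "excludes_zero": bool(eff.excludes_zero)
                    if not np.isnan(eff.estimate)
                    else False,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# phase behavior and baseline dissociations


def phase_metrics(result: ExperimentResult, predictor: str, delta: float | None = None) -> dict:
    """Item-level correlation with veridical surprisal, and the spread of the
    Two/Three condition x noun profile (its standard deviation of cell means:
    zero when the model is indistinctly flat across depth and embedding bias).
    """
    df = result.frame
    sub = df[df.predictor == predictor]
    if delta is not None:
        sub = sub[np.isclose(sub.delta, delta)]
    plain = df[df.predictor == "plain_surprisal"].set_index("item_id").mean_nats
    merged = sub.set_index("item_id")
    corr = float(np.corrcoef(merged.mean_nats, plain.loc[merged.index])[0, 1])
    cells = (
        merged[merged.condition != "One"]
        .groupby(["condition", "noun_id"])
        .mean_nats.mean()
    )
    return {
        "correlation_with_plain": corr,
        "two_three_spread": float(cells.std(ddof=0)),
    }


def matched_baseline_policies(delta: float, n: int) -> dict:
    """Uniform and window policies with expected retention matched to delta."""
    return {
        "uniform": (UniformPolicy(min(1.0, delta / n), n), delta),
        "window": (WindowPolicy(int(round(delta)), n), delta),
    }


def run_baseline_dissociation(
    lm: LanguageModelPrior,
    stimuli: Sequence[StimulusItem],
    delta: float,
    n: int,
    settings: InferenceSettings = DEFAULT_SETTINGS,
    n_masks: int = 48,
    n_boot: int = 250,
    seed: int = 0,
) -> tuple[dict[str, EffectSummary], pd.DataFrame]:
    """Effect summaries for the uniform and window memory models (plus DLT and
    veridical surprisal), with the sign-pattern table."""
    policies = matched_baseline_policies(delta, n)
    result = run_reading_time_experiment(
        lm, policies, stimuli, settings=settings, n_masks=n_masks, seed=seed
    )
    summaries = {
        name: summarize_effects(result, name, delta, n_boot=n_boot, seed=seed)
        for name in policies
    }
    summaries["plain_surprisal"] = summarize_effects(
        result, "plain_surprisal", n_boot=n_boot, seed=seed
    )
    summaries["dlt"] = summarize_effects(result, "dlt", n_boot=n_boot, seed=seed)
    return summaries, sign_table(summaries)


# ---------------------------------------------------------------------------
# production


@dataclass
class ProductionResult:
    frame: pd.DataFrame  # item_id, noun_id, embedding_bias, p_ungrammatical
    slope: Effect
    verb_tokens: tuple
    seed: int


def run_production_experiment(
    lm: LanguageModelPrior,
    policy: RetentionPolicy,
    stimuli: Sequence[StimulusItem],
    verb_tokens: Sequence[str],
    settings: InferenceSettings = DEFAULT_SETTINGS,
    n_masks: int = 48,
    n_boot: int = 250,
    seed: int = 0,
) -> ProductionResult:
    """Ungrammatical-continuation probability at the obligatory-verb point.

    Three-condition items are scored at the position of their final verb: the
    preamble plus the canonical embedded material leaves a clause that only a
    verb can grammatically continue, so the ungrammatical-completion rate is
    one minus the lossy probability mass on verb tokens there.
    """
    if not verb_tokens:
        raise ConfigurationError("verb_tokens: empty")
    three = [it for it in stimuli if it.condition == "Three"]
    if not three:
        raise ConfigurationError("no Three-condition items supplied")
    biases = noun_biases(lm, sorted({it.noun_id for it in three}))
    rows = []
    for item in three:
        rng = child_rng(seed, "prod", item.item_id)
        p_gram = grammatical_continuation_prob(
            lm, policy, item.critical_context, list(verb_tokens),
            settings=settings, n_masks=n_masks, rng=rng,
        )
        rows.append(
            {
                "item_id": item.item_id,
                "noun_id": item.noun_id,
                "embedding_bias": biases[item.noun_id],
                "p_ungrammatical": 1.0 - p_gram,
            }
        )
    df = pd.DataFrame(rows)
    point = _ols_slope(df.embedding_bias.to_numpy(), df.p_ungrammatical.to_numpy())
    rng = child_rng(seed, "prodboot")
    slopes = []
    for _ in range(n_boot):
        pick = rng.choice(len(df), size=len(df), replace=True)
        b = df.iloc[pick]
        slopes.append(_ols_slope(b.embedding_bias.to_numpy(), b.p_ungrammatical.to_numpy()))
    slope = Effect(
        point, float(np.percentile(slopes, 2.5)), float(np.percentile(slopes, 97.5))
    )
    return ProductionResult(df, slope, tuple(verb_tokens), seed)


def verb_tokens_of(grammar: GrammarSpec) -> list[str]:
    return grammar.verbs()
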