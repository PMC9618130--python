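"""Comparison difficulty predictors from prior theories.

* Veridical surprisal (expectation-based): -log P(w | full context) under the
  prior, with no memory loss.
* Dependency locality theory (DLT, memory-based): integration cost at a word
  grows with the number of new discourse referents (nouns and finite verbs)
  crossed by the dependencies resolved there. Only integration cost is
  modeled; the cost of one dependency is 1 + the number of intervening
  referents, and costs of dependencies resolved at the same word add.
* Uniform / windowed lossy surprisal: the noisy-memory model with
  structureless retention policies (equal retention probability everywhere,
  or a hard recency window).

DLT operates on dependency annotations supplied by the stimulus generator, so
its predictions are exactly invariant to lexical substitutions that preserve
structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import child_rng
from .exceptions import ConfigurationError
from .grammar import DependencyAnnotation, StimulusItem
from .inference import InferenceSettings, lossy_surprisal
from .lm import LanguageModelPrior, plain_surprisal
from .retention import RetentionPolicy

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DifficultyPrediction:
    item_id: str
    predictor: str
    value: float  # nats for surprisal-type predictors, cost units for DLT
    critical_index: int
    delta: float | None = None
    units: str = "nats"
    se: float = 0.0


def dlt_integration_cost(annotation: DependencyAnnotation, index: int) -> int:
    """Integration cost at a word: sum over leftward dependencies resolved
    there of (1 + number of new discourse referents strictly between the
    dependent and the integrating word)."""
    heads = annotation.heads
    if not (0 <= index < len(heads)):
        raise ConfigurationError(f"index {index} out of range")
    cost = 0
    for dep, head in enumerate(heads):
        if head == index and dep < index:
            interveners = sum(
                1 for j in range(dep + 1, index) if annotation.referent[j]
            )
            cost += 1 + interveners
    return cost


def predict_all(
    stimuli: Sequence[StimulusItem],
    lm: LanguageModelPrior,
    policies: Mapping[str, tuple[RetentionPolicy, float | None]],
    annotations: Mapping[str, DependencyAnnotation] | None = None,
    settings: InferenceSettings = InferenceSettings(method="is", n_particles=128),
    n_masks: int = 48,
    seed: int = 0,
) -> list[DifficultyPrediction]:
    """One difficulty prediction per item per predictor.

    ``policies`` maps predictor names to (policy, delta) pairs — e.g. trained
    policies per retention bound, a uniform policy, a window policy. Veridical
    surprisal is always included; DLT rows are included when annotations are
    supplied and skipped (with a logged warning) for items lacking one.
    """
    out = []
    for item in stimuli:
        out.append(
            DifficultyPrediction(
                item.item_id,
                "plain_surprisal",
                plain_surprisal(lm, item.scored_tokens, item.scored_index),
                item.critical_index,
            )
        )
        if annotations is not None:
            ann = annotations.get(item.item_id)
            if ann is None:
                log.warning("no dependency annotation for %s; DLT row skipped", item.item_id)
            else:
                out.append(
                    DifficultyPrediction(
                        item.item_id,
                        "dlt",
                        float(dlt_integration_cost(ann, item.critical_index)),
                        item.critical_index,
                        units="energy units",
                    )
                )
        for name, (policy, delta) in policies.items():
            rng = child_rng(seed, name, item.item_id)
            est = lossy_surprisal(
                lm, policy, item.scored_tokens, item.scored_index,
                n_masks=n_masks, settings=settings, rng=rng,
            )
            out.append(
                DifficultyPrediction(
                    item.item_id, name, est.mean_nats, item.critical_index,
                    delta=delta, se=est.mc_standard_error,
                )
            )
    return out


def predictions_frame(predictions: Sequence[DifficultyPrediction]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "item_id": [p.item_id for p in predictions],
            "predictor": [p.predictor for p in predictions],
            "delta": [np.nan if p.delta is None else p.delta for p in predictions],
            "value": [p.value for p in predictions],
            "units": [p.units for p in predictions],
            "se": [p.se for p in predictions],
        }
    )
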