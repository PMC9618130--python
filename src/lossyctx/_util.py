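"""Small shared helpers: digests, seeds, canonical JSON."""

from __future__ import annotations

import hashlib
import json

import numpy as np

MAX_SEED = 2**31 - 1


def canonical_json(obj) -> str:
    return json.dumps(obj, sort_keys=True, separators=(",", ":"), default=str)


def digest(obj) -> str:
    """Short stable checksum of a JSON-serializable object."""
    return hashlib.sha256(canonical_json(obj).encode()).hexdigest()[:16]


def spawn_seed(rng: np.random.Generator) -> int:
    """Derive a child seed below 2**31 from a generator."""
    return int(rng.integers(0, MAX_SEED))


def child_rng(seed: int, *tags) -> np.random.Generator:
    """Deterministic stream derived from an integer seed and hashable tags."""
    h = hashlib.sha256(repr((int(seed),) + tags).encode()).digest()
    return np.random.default_rng(int.from_bytes(h[:4], "big") % MAX_SEED)
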