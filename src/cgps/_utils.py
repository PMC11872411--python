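"""Shared helpers: seed fan-out and stable hashing of intermediates."""

from __future__ import annotations

import hashlib
import json
from typing import Any

import numpy as np

# Stage identifiers used when deriving per-stage seeds from a single global
# seed.  Keeping them in one table makes the fan-out auditable and lets a
# stage be rerun in isolation with the exact stream it saw in a full run.
STAGE_KEYS = {
    "simulate": 1,
    "preprocess": 2,
    "cluster": 3,
    "screen": 4,
    "validate": 5,
    "gates": 6,
    "thresholds": 7,
    "evaluate": 8,
}


def stage_seed(global_seed: int, stage: str, index: int = 0) -> int:
    """Deterministic child seed (< 2**31) for a named pipeline stage."""
    if stage not in STAGE_KEYS:
        raise KeyError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence(entropy=int(global_seed),
                                spawn_key=(STAGE_KEYS[stage], int(index)))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def rng_for(global_seed: int, stage: str, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(stage_seed(global_seed, stage, index))


def sha256_bytes(payload: bytes) -> str:
    return hashlib.sha256(payload).hexdigest()


def sha256_array(a: np.ndarray) -> str:
    a = np.ascontiguousarray(a)
    h = hashlib.sha256()
    h.update(str(a.dtype).encode())
    h.update(str(a.shape).encode())
    h.update(a.tobytes())
    return h.hexdigest()


def sha256_json(obj: Any) -> str:
    return sha256_bytes(json.dumps(obj, sort_keys=True, default=str).encode())
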