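"""Deterministic seed fan-out.

One global seed is expanded into independent per-stage streams by a
stable label hash, so adding a stage never perturbs the streams of
earlier stages.
"""

from __future__ import annotations

import zlib

import numpy as np


def child_seed_sequence(seed: int, label: str) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=int(seed),
                                  spawn_key=(zlib.crc32(label.encode()),))


def derive_rng(seed: int, label: str) -> np.random.Generator:
    """Independent Generator for stage ``label`` under global ``seed``."""
    return np.random.default_rng(child_seed_sequence(seed, label))


def derive_seed(seed: int, label: str) -> int:
    """A plain child integer seed (< 2**31) for stage ``label``."""
    return int(child_seed_sequence(seed, label).generate_state(1)[0] % (2**31))
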