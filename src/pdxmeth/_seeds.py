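"""Splittable seeding.

One master seed governs every stochastic stage.  Child generators are derived
through :class:`numpy.random.SeedSequence` spawn keys, so components draw from
independent streams and adding a consumer never perturbs the streams of the
others.  Keys are small integer tuples; each module documents the slots it
uses.
"""

from __future__ import annotations

import numpy as np

# top-level spawn-key slots, one per stochastic component
POOL = 0
PAIR = 1
MOUSE_QC = 2
READS = 3
ENRICH = 4
OVERLAP = 5
POWER = 6
ANNOTATION = 7


def child_rng(seed: int, *key: int) -> np.random.Generator:
    """Generator for component ``key`` under master ``seed``."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))
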