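"""Shared numeric helpers."""
from __future__ import annotations

import numpy as np


def round_half_away(x) -> np.ndarray:
    """Round to the nearest integer, halves away from zero.

    ``numpy.round`` rounds halves to even; reported gestational weeks and
    integer symptom scores are conventionally rounded with halves going up in
    magnitude (22.5 -> 23, -0.5 -> -1), so that convention is used everywhere
    a continuous value becomes an integer week or score.
    """
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def as_generator(rng) -> np.random.Generator:
    """Coerce an int seed, SeedSequence, or Generator into a Generator."""
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)
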