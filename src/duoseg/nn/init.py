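"""Seeded weight initialisation.

A single module-level generator feeds every layer constructor, so building the
same model after ``seed_all(seed)`` always yields identical weights.  Linear /
attention weights use a truncated normal (std 0.02, clipped at two standard
deviations); convolutions use Kaiming-normal fan-in scaling, the convention
for ReLU networks.
"""

from __future__ import annotations

import numpy as np

_rng = np.random.default_rng(0)


def seed_all(seed: int) -> None:
    """Reset the global initialisation/shuffling RNG."""
    global _rng
    _rng = np.random.default_rng(seed)


def get_rng() -> np.random.Generator:
    return _rng


def trunc_normal(shape, std: float = 0.02) -> np.ndarray:
    x = _rng.normal(0.0, std, size=shape)
    return np.clip(x, -2 * std, 2 * std)


def kaiming_normal(shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return _rng.normal(0.0, std, size=shape)
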