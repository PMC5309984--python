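"""Small shared helpers: printed-precision rounding and RNG plumbing."""

from __future__ import annotations

import math

import numpy as np

__all__ = ["round_half_away", "child_rng", "revcomp"]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (printed-table convention).

    Python's built-in ``round`` is banker's rounding; report tables
    use the arithmetic convention instead.
    """
    factor = 10.0**ndigits
    scaled = x * factor
    return math.copysign(math.floor(abs(scaled) + 0.5), scaled) / factor


def child_rng(master_seed: int, *keys: int | str) -> np.random.Generator:
    """Deterministic child generator derived from a master seed and keys.

    String keys are hashed stably (no dependence on PYTHONHASHSEED).
    """
    ints: list[int] = [int(master_seed)]
    for k in keys:
        if isinstance(k, str):
            h = 2166136261
            for ch in k.encode():
                h = ((h ^ ch) * 16777619) & 0xFFFFFFFF
            ints.append(h)
        else:
            ints.append(int(k) & 0xFFFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(ints))


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
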