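"""Shared helpers: deterministic RNG derivation and table rounding."""

from __future__ import annotations

import zlib
from decimal import ROUND_HALF_UP, Decimal

import numpy as np


def child_rng(seed: int, label: str) -> np.random.Generator:
    """Derive an independent RNG stream from a master seed and a label.

    The label is hashed with CRC32 (stable across platforms and runs), so
    adding a new labelled stream never perturbs existing ones.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(label.encode("utf-8"))])
    )


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding, used only when comparing against printed tables.

    Binary round-half-even would turn 0.625 into 0.62; printed tables use 0.63.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
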