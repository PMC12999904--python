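"""Shared helpers: deterministic sub-seeding, natural ordering, rounding."""

from __future__ import annotations

import re
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

_NAT_SPLIT = re.compile(r"(\d+)")


def natural_key(s: str) -> tuple:
    """Sort key comparing embedded integers numerically: chr2 < chr10."""
    return tuple(int(tok) if tok.isdigit() else tok for tok in _NAT_SPLIT.split(s))


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (2.675 -> 2.68), unlike banker's round()."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def subseed(seed: int, *tags: str) -> np.random.Generator:
    """A generator for one named stream, stably derived from the master seed.

    Each (seed, tags) pair yields an independent stream, so regenerating one
    file kind does not disturb the bytes of another.
    """
    ints = [seed] + [int.from_bytes(t.encode(), "little") % (2**32) for t in tags]
    return np.random.default_rng(np.random.SeedSequence(ints))
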