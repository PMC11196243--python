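"""Small shared helpers: reporting-grade rounding and named random substreams."""

from __future__ import annotations

import zlib
from decimal import ROUND_HALF_UP, Decimal

import numpy as np


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, matching printed report tables.

    Python's built-in ``round`` is banker's rounding; report tables in this
    field round 0.005 up, so all writers funnel through here.
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator derived from a root seed and a stream name.

    Every stochastic stage (simulator, null models, Mantel permutations)
    pulls its own named stream so changing one analysis cannot perturb
    another's draws.  The derived key stays below 2**31.
    """
    return np.random.default_rng([int(seed) % (2**31), zlib.crc32(name.encode())])
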