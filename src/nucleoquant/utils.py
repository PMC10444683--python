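"""Small shared helpers: rounding and seeded RNG derivation."""

from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = ["round_half_up", "rng_from_seed"]


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round ``value`` half-up to ``ndigits`` decimal places.

    The rounding is applied to the exact decimal expansion of the IEEE-754
    double, which is how chromatography reports round their printed values
    (a stored 92.45 sits just above the half and rounds to 92.5, while a
    stored 97.35 sits just below and rounds to 97.3).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(value).quantize(q, rounding=ROUND_HALF_UP))


def rng_from_seed(seed, stream: int = 0) -> np.random.Generator:
    """Derive an independent generator from an integer seed and stream index.

    Uses ``SeedSequence`` spawning so every stochastic component of the
    pipeline gets a reproducible, platform-independent integer stream.
    """
    return np.random.default_rng(np.random.SeedSequence(int(seed)).spawn(stream + 1)[stream])
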