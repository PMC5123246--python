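"""Fixed-precision helpers.

Binding probabilities are stored, and all derived scores are compared, at
eight decimal digits.  Working at a fixed precision makes tie-breaking
reproducible across platforms; ties that survive the rounding are resolved
alphabetically by the selection routines.
"""

from decimal import ROUND_HALF_EVEN, Decimal

import numpy as np

#: number of decimal digits kept for probabilities and compared scores
PROB_DECIMALS = 8

_QUANTUM = Decimal(1).scaleb(-PROB_DECIMALS)


def round8(x):
    """Round a float or array half-to-even at :data:`PROB_DECIMALS` digits."""
    return np.round(x, PROB_DECIMALS)


def round8_decimal(text: str) -> float:
    """Exact decimal round-half-even of a probability literal.

    Used when parsing text tables so that e.g. ``"0.123456789"`` becomes
    ``0.12345679`` by decimal (not binary) arithmetic.
    """
    return float(Decimal(text).quantize(_QUANTUM, rounding=ROUND_HALF_EVEN))
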