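"""Small shared numeric helpers."""

import math


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero.

    Python's built-in ``round`` uses banker's rounding; printed bioassay
    tables follow the hand-calculation convention where 0.5 rounds up.
    """
    if not math.isfinite(x):
        raise ValueError(f"cannot round non-finite value {x!r}")
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))
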