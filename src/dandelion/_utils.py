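"""Small shared helpers."""

from __future__ import annotations

import numpy as np


def derive_seed(base: int, *parts) -> int:
    """Deterministic child seed below 2**31 from a base seed and context parts.

    String parts are folded in via their bytes so that distinct pipeline
    stages get independent streams from one user-facing seed.
    """
    entropy = [int(base) & 0x7FFFFFFF]
    for p in parts:
        if isinstance(p, str):
            entropy.extend(p.encode())
        else:
            entropy.append(int(p) & 0x7FFFFFFF)
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))
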