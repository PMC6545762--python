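"""Seed plumbing: every stochastic stage draws its seed from a master seed."""

from __future__ import annotations

import numpy as np


def spawn_seeds(master: int, k: int) -> list[int]:
    """Derive k independent 31-bit child seeds from a master seed."""
    ss = np.random.SeedSequence(master)
    return [int(s) for s in ss.generate_state(k) % (2**31 - 1)]
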