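"""Small shared numerics."""

from __future__ import annotations

import numpy as np

__all__ = ["wrap_to_pi"]


def wrap_to_pi(x):
    """Wrap phase to the half-open interval (-pi, pi].

    Uses modular arithmetic with a negative divisor so the boundary lands on
    +pi exactly (the convention of ``numpy.angle``).
    """
    return np.mod(np.asarray(x, dtype=float) - np.pi, -2.0 * np.pi) + np.pi
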