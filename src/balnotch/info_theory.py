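"""Per-trial information of psychophysical task designs.

A Yes/No trial can deliver up to 1 bit; catch trials dilute that in
proportion to their share.  An n-interval forced-choice trial is modelled as
a binary channel whose input is whether the tone was heard: a heard tone is
always reported correctly, an unheard one is guessed correctly with
probability 1/n.  The per-trial mutual information is then

    I(p_h) = H_b(p_h + (1 - p_h)/n) - (1 - p_h) * H_b(1/n)

with H_b the binary entropy.  For n = 2 this is a Z-channel with crossover
1/2, whose capacity of about 0.32 bits (at p_h = 0.60) motivates preferring
the Yes/No task for adaptive testing.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "binary_entropy",
    "info_yes_no",
    "info_nafc",
    "channel_capacity",
    "channel_capacity_grid",
]


def binary_entropy(p):
    """Binary entropy H_b(p) in bits; the p log p limit at {0, 1} is 0."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p must lie in [0, 1]")
    out = np.zeros_like(p)
    interior = (p > 0) & (p < 1)
    q = p[interior]
    out[interior] = -q * np.log2(q) - (1 - q) * np.log2(1 - q)
    return out if out.ndim else float(out)


def info_yes_no(catch_fraction: float) -> float:
    """Upper bound on bits per average trial of a Yes/No task with catch trials."""
    if not 0.0 <= catch_fraction < 0.5:
        raise ValueError("catch_fraction must lie in [0, 0.5)")
    return 1.0 - catch_fraction


def info_nafc(p_h, n: int = 2):
    """Bits per trial of an n-alternative forced-choice task.

    ``p_h`` is the probability the tone is actually heard; unheard tones are
    guessed correctly with probability 1/n.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    p_h = np.asarray(p_h, dtype=float)
    if np.any((p_h < 0) | (p_h > 1)):
        raise ValueError("p_h must lie in [0, 1]")
    c = p_h + (1.0 - p_h) / n
    return binary_entropy(c) - (1.0 - p_h) * binary_entropy(1.0 / n)


def channel_capacity(n: int = 2) -> tuple[float, float]:
    """Capacity of the n-AFC response channel and the maximizing p_h.

    Closed form: stationarity of I in p_h gives
    ``log2((1-c)/c) = -H_b(1/n) / (1 - 1/n)`` for the correct-response
    probability c, from which p_h = (c - 1/n) / (1 - 1/n).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    hb = binary_entropy(1.0 / n)
    c = 1.0 / (1.0 + 2.0 ** (-hb / (1.0 - 1.0 / n)))
    p_h = (c - 1.0 / n) / (1.0 - 1.0 / n)
    return float(info_nafc(p_h, n)), float(p_h)


def channel_capacity_grid(n: int = 2, step: float = 1e-4) -> tuple[float, float]:
    """Grid-search version of :func:`channel_capacity` (independent route)."""
    p = np.arange(step, 1.0, step)
    info = info_nafc(p, n)
    i = int(np.argmax(info))
    return float(info[i]), float(p[i])
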