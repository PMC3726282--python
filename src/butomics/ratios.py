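"""Signed fold-change conventions shared across the omics layers.

Down-regulation of x-fold is written as -x, so every defined value lies in
(-inf, -1] or [1, +inf) and never inside the open interval (-1, 1).  The
same convention is used for RPKM fold changes, qPCR expression ratios and
GC-MS replicate ratios; detection in only one condition is carried as an
infinite sentinel, and a pair of zeros as NaN ("undetected in both").
"""

from __future__ import annotations

import math

__all__ = ["signed_ratio", "to_signed", "ternary_code", "sign"]


def signed_ratio(treated: float, control: float) -> float:
    """Signed ratio of two non-negative abundances.

    Returns ``treated/control`` when treated >= control > 0, and
    ``-control/treated`` when control > treated > 0.  If exactly one side
    is zero the change is infinitely strong in that direction (``+inf`` /
    ``-inf``); if both are zero the ratio is undefined (NaN).
    """
    if treated < 0 or control < 0:
        raise ValueError(
            f"abundances must be non-negative, got ({treated}, {control})"
        )
    if treated == 0.0 and control == 0.0:
        return math.nan
    if control == 0.0:
        return math.inf
    if treated == 0.0:
        return -math.inf
    return treated / control if treated >= control else -control / treated


def to_signed(ratio: float) -> float:
    """Convert a plain positive ratio to the signed convention."""
    if ratio <= 0:
        raise ValueError(f"plain ratio must be positive, got {ratio}")
    return ratio if ratio >= 1.0 else -1.0 / ratio


def ternary_code(r: float, threshold: float = 1.5) -> int:
    """Code a signed ratio as +1 / 0 / -1 by a strict +-threshold cutoff.

    ``r > threshold`` codes +1, ``r < -threshold`` codes -1, and everything
    in between — including a ratio of exactly +-threshold and the undefined
    (NaN) case — codes 0.  Infinite sentinels code +-1.
    """
    if math.isnan(r):
        return 0
    if r > threshold:
        return 1
    if r < -threshold:
        return -1
    return 0


def sign(x: float) -> int:
    """Sign of a score: -1, 0 or +1."""
    return (x > 0) - (x < 0)
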