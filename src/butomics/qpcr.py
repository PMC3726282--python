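"""Absolute-standard-curve qPCR quantification and RNA-seq concordance.

A dilution series of genomic DNA of known quantity defines a standard curve
Ct = intercept + slope * log10(quantity); unknowns are interpolated back to
quantities, normalized by a reference gene (rnpB), and expressed as signed
treated/control ratios.  Agreement with RNA-seq is judged by direction
only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .ratios import to_signed

__all__ = [
    "StandardCurve",
    "fit_standard_curve",
    "quantify",
    "predict_ct",
    "expression_ratio",
    "sign_concordance",
    "slope_for_efficiency",
]


@dataclass(frozen=True)
class StandardCurve:
    """Linear fit of Ct on log10(template quantity)."""

    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError(
                f"standard-curve slope must be negative (Ct falls as template "
                f"rises), got {self.slope}"
            )

    @property
    def efficiency(self) -> float:
        """Amplification efficiency, 1.0 = perfect doubling per cycle."""
        return 10.0 ** (-1.0 / self.slope) - 1.0


def slope_for_efficiency(efficiency: float) -> float:
    """Slope of an ideal curve with the given amplification efficiency."""
    if not 0 < efficiency <= 1:
        raise ValueError(f"efficiency must be in (0, 1], got {efficiency}")
    return -1.0 / math.log10(1.0 + efficiency)


def fit_standard_curve(dilutions: Sequence[tuple[float, float]]) -> StandardCurve:
    """Ordinary least squares of Ct on log10(known quantity).

    ``dilutions`` is a sequence of (known_quantity, ct) pairs with at least
    3 distinct quantities.
    """
    if len(dilutions) < 3:
        raise ValueError("need at least 3 dilution points")
    q = np.array([d[0] for d in dilutions], dtype=float)
    ct = np.array([d[1] for d in dilutions], dtype=float)
    if (q <= 0).any():
        raise ValueError("known quantities must be positive")
    if len(np.unique(q)) < 3:
        raise ValueError("need at least 3 distinct dilution quantities")
    res = stats.linregress(np.log10(q), ct)
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
    )


def quantify(ct: float, curve: StandardCurve) -> float:
    """Template quantity interpolated from a Ct value: 10^((ct - b) / m)."""
    return 10.0 ** ((ct - curve.intercept) / curve.slope)


def predict_ct(quantity: float, curve: StandardCurve) -> float:
    """Ct expected for a known template quantity (inverse of quantify)."""
    if quantity <= 0:
        raise ValueError("quantity must be positive")
    return curve.intercept + curve.slope * math.log10(quantity)


def expression_ratio(
    target_treated: float,
    target_control: float,
    reference_treated: float,
    reference_control: float,
) -> float:
    """Reference-normalized treated/control ratio in the signed convention.

    ratio = (q_target,treated / q_ref,treated) / (q_target,control /
    q_ref,control); values below 1 are reported as their negative
    reciprocal.
    """
    for name, q in (
        ("target_treated", target_treated),
        ("target_control", target_control),
        ("reference_treated", reference_treated),
        ("reference_control", reference_control),
    ):
        if q <= 0:
            raise ValueError(f"{name} quantity must be positive, got {q}")
    plain = (target_treated / reference_treated) / (
        target_control / reference_control
    )
    return to_signed(plain)


def sign_concordance(
    pairs: Sequence[tuple[float, float]]
) -> tuple[int, float]:
    """Direction agreement between paired signed ratios.

    A pair is concordant when both ratios are >= +1 or both <= -1.
    Returns (concordant count, concordant fraction).
    """
    if not pairs:
        raise ValueError("no ratio pairs supplied")
    n_conc = sum(
        1
        for a, b in pairs
        if (a >= 1 and b >= 1) or (a <= -1 and b <= -1)
    )
    return n_conc, n_conc / len(pairs)
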