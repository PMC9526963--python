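"""Sobel (first-order delta method) test of the indirect effect a3*b3.

The indirect effect is estimated as the product of the X->M and M_B->Y_B
path estimates; its standard error follows from the first-order delta
method, ``se_ab = sqrt(a^2 se_b^2 + b^2 se_a^2)``, and ``z = ab / se_ab`` is
referred to the standard normal.  One-sided decisions are an algebraic
transformation of the stored two-sided z: reject iff ``direction * z``
exceeds the one-sided normal critical value, so no refitting is needed.
A z exactly at a critical value counts as a rejection (fixed tie-break).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["SobelResult", "sobel", "one_sided_from_two"]


@dataclass(frozen=True)
class SobelResult:
    ab_hat: float
    se_ab: float
    z: float
    p_two: float
    p_one: float
    alpha: float
    direction: int
    reject_two: bool
    reject_one: bool


def sobel(
    a_hat: float,
    se_a: float,
    b3_hat: float,
    se_b3: float,
    alpha: float = 0.05,
    direction: int = 1,
) -> SobelResult:
    """Delta-method z-test of H0: a3*b3 = 0.

    ``direction`` is the hypothesized sign of the indirect effect for the
    one-sided decision (+1 or -1).
    """
    if se_a <= 0 or se_b3 <= 0:
        raise ValueError("standard errors must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if direction not in (1, -1):
        raise ValueError("direction must be +1 or -1")
    ab = a_hat * b3_hat
    se_ab = float(np.sqrt(a_hat ** 2 * se_b3 ** 2 + b3_hat ** 2 * se_a ** 2))
    z = ab / se_ab if se_ab > 0 else 0.0
    p_two = float(2 * sps.norm.sf(abs(z)))
    p_one = float(sps.norm.sf(direction * z))
    crit_two = sps.norm.isf(alpha / 2)
    crit_one = sps.norm.isf(alpha)
    return SobelResult(
        ab_hat=ab,
        se_ab=se_ab,
        z=z,
        p_two=p_two,
        p_one=p_one,
        alpha=alpha,
        direction=direction,
        reject_two=bool(abs(z) >= crit_two),
        reject_one=bool(direction * z >= crit_one),
    )


def one_sided_from_two(z, direction: int = 1, alpha: float = 0.05):
    """One-sided rejection decision from a stored two-sided z (vectorized)."""
    if direction not in (1, -1):
        raise ValueError("direction must be +1 or -1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return np.asarray(direction * np.asarray(z) >= sps.norm.isf(alpha))


def sobel_z_batched(a_hat, se_a, b3_hat, se_b3):
    """Vectorized Sobel z; invalid (non-positive SE) entries yield NaN."""
    a_hat = np.asarray(a_hat, float)
    b3_hat = np.asarray(b3_hat, float)
    se_a = np.asarray(se_a, float)
    se_b3 = np.asarray(se_b3, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        se_ab = np.sqrt(a_hat ** 2 * se_b3 ** 2 + b3_hat ** 2 * se_a ** 2)
        z = np.where(se_ab > 0, a_hat * b3_hat / np.where(se_ab > 0, se_ab, 1.0), 0.0)
    bad = ~((se_a > 0) & (se_b3 > 0))
    return np.where(bad, np.nan, z)
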