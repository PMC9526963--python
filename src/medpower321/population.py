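"""Map standardized design inputs to the raw generating model.

The generating model is a three-level random-intercept structure with the
treatment X varying only between clusters (coded -1/+1, half the clusters per
arm, so var(X) = 1), the mediator M observed at level 2 with variance at
levels 2 and 3, and the outcome Y observed at level 1 with variance at all
three levels.  Total variances of M and Y are normalized to 1, so the ICC
inputs are also the absolute variance shares per level.

Standardization convention: the level-3 paths a3, b3, c3p are *between-level*
standardized coefficients — they act on the level-3 latent components of M and
Y scaled to unit variance (the MSEM convention).  b2 is standardized within
level 2.  Under this convention every cell of the default grid maps to a valid
(non-negative) variance decomposition, which would not hold if paths were
standardized against total variance.

The resulting mapping, with var(X) = 1:

    a_raw        = a3 * sqrt(icc_m3)
    var_mB_resid = icc_m3 * (1 - a3^2)
    var_mW       = 1 - icc_m3
    b3_raw       = b3 * sqrt(icc_y3 / icc_m3)
    c_raw        = c3p * sqrt(icc_y3)
    R2_B         = b3^2 + c3p^2 + 2 a3 b3 c3p      (level-3 explained share)
    var_yB_resid = icc_y3 * (1 - R2_B)
    b2_raw       = b2 * sqrt(icc_y2 / (1 - icc_m3))
    var_y2_resid = icc_y2 * (1 - b2^2)
    var_y1       = 1 - icc_y2 - icc_y3
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .design import DesignSpec

__all__ = ["PopulationParams", "derive_components", "ParameterizationError"]


class ParameterizationError(ValueError):
    """A design implies a negative variance component."""


@dataclass(frozen=True)
class PopulationParams:
    """Raw coefficients and variance components of the generating model."""

    a_raw: float          # X -> M (level 3)
    b3_raw: float         # latent M_B -> latent Y_B
    b2_raw: float         # within-cluster M deviation -> Y level-2 component
    c_raw: float          # X -> latent Y_B (direct)
    var_mB_resid: float   # level-3 residual variance of M
    var_mW: float         # level-2 variance of M
    var_yB_resid: float   # level-3 residual variance of Y
    var_y2_resid: float   # level-2 residual variance of Y
    var_y1: float         # level-1 variance of Y
    x_codes: tuple[float, float] = (-1.0, 1.0)

    def __post_init__(self) -> None:
        for name in ("var_mB_resid", "var_mW", "var_yB_resid",
                     "var_y2_resid", "var_y1"):
            v = getattr(self, name)
            if v < 0:
                raise ParameterizationError(f"{name} is negative: {v}")

    # Implied totals; both equal 1 when built by derive_components.
    @property
    def var_m_total(self) -> float:
        return self.a_raw ** 2 + self.var_mB_resid + self.var_mW

    @property
    def var_y_total(self) -> float:
        var_mB = self.a_raw ** 2 + self.var_mB_resid
        var_yB = (self.b3_raw ** 2 * var_mB + self.c_raw ** 2
                  + 2 * self.b3_raw * self.c_raw * self.a_raw
                  + self.var_yB_resid)
        var_y2 = self.b2_raw ** 2 * self.var_mW + self.var_y2_resid
        return var_yB + var_y2 + self.var_y1


def derive_components(spec: DesignSpec) -> PopulationParams:
    """Convert a standardized :class:`DesignSpec` into raw generating parameters.

    Raises :class:`ParameterizationError` naming the violated constraint when
    the standardized inputs imply a negative variance anywhere in the
    decomposition (e.g. level-3 explained share of Y at or above 1).
    """
    r2b = spec.b3 ** 2 + spec.c3p ** 2 + 2 * spec.a3 * spec.b3 * spec.c3p
    if r2b >= 1.0:
        raise ParameterizationError(
            f"level-3 R^2 of Y is {r2b:.6f} >= 1 (b3, c3p, a3 too large jointly)"
        )
    if spec.a3 ** 2 >= 1.0:
        raise ParameterizationError("a3^2 >= 1 leaves no level-3 residual for M")
    if spec.b2 ** 2 >= 1.0:
        raise ParameterizationError("b2^2 >= 1 leaves no level-2 residual for Y")
    var_y1 = 1.0 - spec.icc_y2 - spec.icc_y3
    if var_y1 < 0:
        raise ParameterizationError("icc_y2 + icc_y3 > 1 leaves negative level-1 variance")

    return PopulationParams(
        a_raw=spec.a3 * math.sqrt(spec.icc_m3),
        var_mB_resid=spec.icc_m3 * (1.0 - spec.a3 ** 2),
        var_mW=1.0 - spec.icc_m3,
        b3_raw=spec.b3 * math.sqrt(spec.icc_y3 / spec.icc_m3),
        c_raw=spec.c3p * math.sqrt(spec.icc_y3),
        var_yB_resid=spec.icc_y3 * (1.0 - r2b),
        b2_raw=spec.b2 * math.sqrt(spec.icc_y2 / (1.0 - spec.icc_m3)),
        var_y2_resid=spec.icc_y2 * (1.0 - spec.b2 ** 2),
        var_y1=var_y1,
    )


def mvm_between_slope_limit(params: PopulationParams, n2: int) -> float:
    """Large-n3 probability limit of the manifest between-cluster M->Y slope.

    Observed cluster means of M carry within-cluster sampling error with
    variance var_mW / n2, which attenuates the between slope toward the
    within slope:

        plim b3_hat = (b3_raw * tau + b2_raw * var_mW / n2) / (tau + var_mW / n2)

    with tau = var_mB_resid (the X-adjusted level-3 variance of M).
    """
    tau = params.var_mB_resid
    s = params.var_mW / n2
    return (params.b3_raw * tau + params.b2_raw * s) / (tau + s)


def mvm_direct_slope_limit(params: PopulationParams, n2: int) -> float:
    """Large-n3 probability limit of the manifest direct-effect slope.

    The sampling error in the observed cluster mean of M pushes the part of
    the between slope it absorbs onto the X coefficient:

        plim c_hat = c_raw + (b3_raw - b2_raw) * a_raw * s / (tau + s)

    with tau = var_mB_resid and s = var_mW / n2.
    """
    tau = params.var_mB_resid
    s = params.var_mW / n2
    return params.c_raw + (params.b3_raw - params.b2_raw) * params.a_raw * s / (tau + s)
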