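"""Generate balanced 3-level mediation datasets.

Two representations are produced:

* :class:`MediationDataset` — the full long-format dataset (one row per
  level-1 observation), written/read as CSV.
* :class:`SufficientStats` — per-cluster sufficient statistics (cluster means
  of M and Y, within-cluster cross-products of M and unit means of Y, and the
  pooled level-1 sum of squares).  Every estimator in this package is a
  function of these statistics alone, so the power engine samples them
  directly: unit means of Y absorb a Normal(0, var_y1/n1) term and the level-1
  sum of squares is drawn as var_y1 * chi2(n2*(n1-1)) per cluster.  This
  collapse is exact (sufficiency), not an approximation.

All random effects and residuals are Gaussian.  Treatment X is assigned
-1 to the first half of the clusters and +1 to the rest; under exchangeable
cluster effects the ordering is irrelevant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .population import PopulationParams

__all__ = [
    "MediationDataset",
    "SufficientStats",
    "generate",
    "generate_sufficient",
    "write_csv",
    "read_csv",
]

CSV_COLUMNS = ["cluster_id", "unit_id", "obs_id", "x", "m", "y"]


@dataclass(frozen=True)
class MediationDataset:
    """Balanced 3-level data in long arrays keyed by (cluster, unit, observation).

    ``x`` has one entry per cluster; ``m`` one per (cluster, unit); ``y`` one
    per (cluster, unit, observation); shapes (n3,), (n3, n2), (n3, n2, n1).
    """

    x: np.ndarray
    m: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        n3, n2, n1 = self.dims
        if self.x.shape != (n3,) or self.m.shape != (n3, n2):
            raise ValueError("inconsistent array shapes for a balanced design")
        arms = np.unique(self.x)
        if arms.size == 2:
            if (self.x == arms[0]).sum() != (self.x == arms[1]).sum():
                raise ValueError("arm counts must be equal")
        elif arms.size > 2:
            raise ValueError("x must take at most two values")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.y.shape

    def to_frame(self) -> pd.DataFrame:
        """Long format, one row per level-1 observation; M repeated within unit."""
        n3, n2, n1 = self.dims
        idx = np.indices((n3, n2, n1)).reshape(3, -1)
        return pd.DataFrame({
            "cluster_id": idx[0],
            "unit_id": idx[1],
            "obs_id": idx[2],
            "x": self.x[idx[0]],
            "m": self.m[idx[0], idx[1]],
            "y": self.y.ravel(),
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MediationDataset":
        df = df.sort_values(["cluster_id", "unit_id", "obs_id"], kind="mergesort")
        n3 = df.cluster_id.nunique()
        n2 = df.unit_id.nunique()
        n1 = df.obs_id.nunique()
        if len(df) != n3 * n2 * n1:
            raise ValueError("dataset is not balanced")
        y = df.y.to_numpy(float).reshape(n3, n2, n1)
        m = df.m.to_numpy(float).reshape(n3, n2, n1)[:, :, 0]
        x = df.x.to_numpy(float).reshape(n3, n2, n1)[:, 0, 0]
        return cls(x=x, m=m, y=y)


@dataclass(frozen=True)
class SufficientStats:
    """Per-cluster sufficient statistics, optionally batched over replications.

    Trailing axis indexes clusters; an optional leading axis indexes
    replications.  Fields:

    ``x``      cluster treatment codes
    ``m_bar``  cluster means of M
    ``y_bar``  cluster means of Y
    ``s_mm``   sum_j (M_jk - Mbar_k)^2
    ``s_my``   sum_j (M_jk - Mbar_k)(Ybar_jk - Ybar_k)   [unit means of Y]
    ``s_yy``   sum_j (Ybar_jk - Ybar_k)^2
    ``ss1``    sum_{ij} (Y_ijk - Ybar_jk)^2              [level-1 SS]
    """

    x: np.ndarray
    m_bar: np.ndarray
    y_bar: np.ndarray
    s_mm: np.ndarray
    s_my: np.ndarray
    s_yy: np.ndarray
    ss1: np.ndarray
    n2: int
    n1: int

    @property
    def n3(self) -> int:
        return self.x.shape[-1]

    @classmethod
    def from_dataset(cls, ds: MediationDataset) -> "SufficientStats":
        n3, n2, n1 = ds.dims
        ybar_unit = ds.y.mean(axis=2)                      # (n3, n2)
        ss1 = ((ds.y - ybar_unit[:, :, None]) ** 2).sum(axis=(1, 2))
        m_bar = ds.m.mean(axis=1)
        y_bar = ybar_unit.mean(axis=1)
        m_dev = ds.m - m_bar[:, None]
        y_dev = ybar_unit - y_bar[:, None]
        return cls(
            x=ds.x.astype(float),
            m_bar=m_bar,
            y_bar=y_bar,
            s_mm=(m_dev ** 2).sum(axis=1),
            s_my=(m_dev * y_dev).sum(axis=1),
            s_yy=(y_dev ** 2).sum(axis=1),
            ss1=ss1,
            n2=n2,
            n1=n1,
        )


def _x_codes(n3: int, codes: tuple[float, float]) -> np.ndarray:
    if n3 % 2:
        raise ValueError(f"n3 must be even for balanced two-arm assignment, got {n3}")
    return np.repeat(np.asarray(codes, dtype=float), n3 // 2)


def generate(
    params: PopulationParams,
    n3: int,
    n2: int,
    n1: int,
    seed: int | np.random.SeedSequence | np.random.Generator,
) -> MediationDataset:
    """Draw one balanced 3-level dataset from the generating model.

    Draw order (fixed for determinism): cluster M effects u, unit M deviations
    w, cluster Y residuals, unit Y residuals, observation Y residuals.
    Identical seed yields a byte-identical dataset.
    """
    rng = np.random.default_rng(seed)
    x = _x_codes(n3, params.x_codes)

    u = rng.normal(0.0, np.sqrt(params.var_mB_resid), size=n3)
    m_b = params.a_raw * x + u                       # latent cluster component of M
    w = rng.normal(0.0, np.sqrt(params.var_mW), size=(n3, n2))
    m = m_b[:, None] + w

    e_b = rng.normal(0.0, np.sqrt(params.var_yB_resid), size=n3)
    v = params.b3_raw * m_b + params.c_raw * x + e_b   # cluster component of Y
    e2 = rng.normal(0.0, np.sqrt(params.var_y2_resid), size=(n3, n2))
    s = params.b2_raw * w + e2                         # unit component of Y
    e1 = rng.normal(0.0, np.sqrt(params.var_y1), size=(n3, n2, n1))
    y = v[:, None, None] + s[:, :, None] + e1
    return MediationDataset(x=x, m=m, y=y)


def generate_sufficient(
    params: PopulationParams,
    n3: int,
    n2: int,
    n1: int,
    seed: int | np.random.SeedSequence | np.random.Generator,
    reps: int = 1,
) -> SufficientStats:
    """Draw sufficient statistics for ``reps`` datasets at once (batched).

    Level 1 is collapsed exactly: unit means of Y get an extra
    Normal(0, var_y1/n1) term and the per-cluster level-1 sum of squares is
    var_y1 * chi2(n2*(n1-1)).  The joint law of the returned statistics equals
    that of :func:`generate` followed by :meth:`SufficientStats.from_dataset`.
    """
    rng = np.random.default_rng(seed)
    x = _x_codes(n3, params.x_codes)

    u = rng.normal(0.0, np.sqrt(params.var_mB_resid), size=(reps, n3))
    m_b = params.a_raw * x + u
    w = rng.normal(0.0, np.sqrt(params.var_mW), size=(reps, n3, n2))

    e_b = rng.normal(0.0, np.sqrt(params.var_yB_resid), size=(reps, n3))
    v = params.b3_raw * m_b + params.c_raw * x + e_b
    # unit means of Y around the cluster component
    var_unit = params.var_y2_resid + params.var_y1 / n1
    e_u = rng.normal(0.0, np.sqrt(var_unit), size=(reps, n3, n2))
    ybar_unit = v[:, :, None] + params.b2_raw * w + e_u

    df1 = n2 * (n1 - 1)
    if df1 > 0 and params.var_y1 > 0:
        ss1 = params.var_y1 * rng.chisquare(df1, size=(reps, n3))
    else:
        ss1 = np.zeros((reps, n3))

    m = m_b[:, :, None] + w
    m_bar = m.mean(axis=2)
    y_bar = ybar_unit.mean(axis=2)
    m_dev = m - m_bar[:, :, None]
    y_dev = ybar_unit - y_bar[:, :, None]
    return SufficientStats(
        x=np.broadcast_to(x, (reps, n3)).copy(),
        m_bar=m_bar,
        y_bar=y_bar,
        s_mm=(m_dev ** 2).sum(axis=2),
        s_my=(m_dev * y_dev).sum(axis=2),
        s_yy=(y_dev ** 2).sum(axis=2),
        ss1=ss1,
        n2=n2,
        n1=n1,
    )


def write_csv(ds: MediationDataset, path) -> None:
    """Write long-format CSV; floats use repr-precision so round-trip is lossless."""
    df = ds.to_frame()
    df.to_csv(path, index=False, float_format="%.17g")


def read_csv(path) -> MediationDataset:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"dataset CSV is missing columns: {sorted(missing)}")
    return MediationDataset.from_frame(df)
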