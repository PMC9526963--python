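"""Latent between/within decomposition (MSEM-style) estimation.

Observed cluster means of M and Y contain within-cluster sampling error; a
multilevel SEM instead regresses the *latent* level-3 components on each
other, removing that error and hence the attenuation that affects manifest
between-cluster slopes.  Here the latent level-3 covariance matrix of
(X, M_B, Y_B) is estimated by unbiased method-of-moments on the balanced
data:

* level-2 (co)variances come from within-cluster deviations of
  (M_jk, mean_i Y_ijk), with the level-1 contribution var_y1/n1 removed from
  the Y variance using the level-1 mean square;
* latent level-3 (co)variances are between-cluster-mean (co)variances minus
  (level-2 component)/n2 (the level-1 part of Y cancels in that correction);
* covariances with X need no correction since X is constant within cluster.

Paths are partial regression coefficients solved from the latent matrices.
Standard errors come from a nonparametric cluster bootstrap (clusters
resampled with replacement, stratified by arm), which operates on per-cluster
sufficient statistics and is fully vectorized.  Because the latent slope is a
ratio whose denominator (the latent M_B variance) can come arbitrarily close
to zero in a resample, the bootstrap distribution is heavy-tailed and its raw
standard deviation is dominated by a few degenerate draws; the SE is
therefore the normal-consistent interquartile scale of the bootstrap
distribution, IQR/1.349.  The moment estimator of the latent M_B variance can
go negative outright in small samples; such fits (and bootstrap draws) are
flagged as non-converged, mirroring the lower completion rates of full-ML
multilevel SEM.
"""

from __future__ import annotations

import numpy as np

from .mvm import FitResult
from .simulate import MediationDataset, SufficientStats

__all__ = ["latent_between_cov", "fit_msem"]


def _moments(st: SufficientStats):
    """Raw between/within moment aggregates; batched over leading axes."""
    n3, n2, n1 = st.n3, st.n2, st.n1
    dfw = n3 * (n2 - 1)
    Sw_mm = st.s_mm.sum(axis=-1) / dfw
    Sw_my = st.s_my.sum(axis=-1) / dfw
    Sw_yy = st.s_yy.sum(axis=-1) / dfw
    df1 = n3 * n2 * (n1 - 1)
    s1sq = st.ss1.sum(axis=-1) / df1 if df1 > 0 else np.zeros_like(Sw_mm)

    def cov(u, v):
        um = u.mean(axis=-1, keepdims=True)
        vm = v.mean(axis=-1, keepdims=True)
        return ((u - um) * (v - vm)).sum(axis=-1) / (n3 - 1)

    x, mb, yb = st.x, st.m_bar, st.y_bar
    Sb = {
        "xx": cov(x, x), "xm": cov(x, mb), "xy": cov(x, yb),
        "mm": cov(mb, mb), "my": cov(mb, yb), "yy": cov(yb, yb),
    }
    return Sb, Sw_mm, Sw_my, Sw_yy, s1sq


def latent_between_cov(
    data: MediationDataset | SufficientStats,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Estimate the latent level-3 covariance of (X, M_B, Y_B) and the
    level-2 covariance of (M_w, Y_w2).

    Returns ``(between3, within2, var_y1_hat)`` where ``between3`` is the
    3x3 latent level-3 matrix in (X, M_B, Y_B) order and ``within2`` the 2x2
    level-2 matrix in (M_w, Y_w2) order with the level-1 contribution
    removed from the Y variance.
    """
    st = data if isinstance(data, SufficientStats) else SufficientStats.from_dataset(data)
    if st.n3 < 4:
        raise ValueError("need at least 2 clusters per arm")
    n2, n1 = st.n2, st.n1
    Sb, Sw_mm, Sw_my, Sw_yy, s1sq = _moments(st)

    within2 = np.array([
        [Sw_mm, Sw_my],
        [Sw_my, Sw_yy - s1sq / n1],
    ], dtype=float)
    # between-mean covariances minus within contamination; the level-1 part
    # of Y's correction cancels: (Sw_yy - s1sq/n1)/n2 + s1sq/(n1 n2) = Sw_yy/n2
    between3 = np.array([
        [Sb["xx"], Sb["xm"], Sb["xy"]],
        [Sb["xm"], Sb["mm"] - Sw_mm / n2, Sb["my"] - Sw_my / n2],
        [Sb["xy"], Sb["my"] - Sw_my / n2, Sb["yy"] - Sw_yy / n2],
    ], dtype=float)
    return between3, within2, float(s1sq)


def _point_estimates(Sb, Sw_mm, Sw_my, n2):
    """Latent-path point estimates from moment aggregates (batched)."""
    B_mm = Sb["mm"] - Sw_mm / n2
    B_my = Sb["my"] - Sw_my / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        a_hat = Sb["xm"] / Sb["xx"]
        det = B_mm * Sb["xx"] - Sb["xm"] ** 2
        b3_hat = (B_my * Sb["xx"] - Sb["xm"] * Sb["xy"]) / det
        c_hat = (B_mm * Sb["xy"] - Sb["xm"] * B_my) / det
        b2_hat = Sw_my / Sw_mm
    ok = (B_mm > 0) & (det > 0) & (Sw_mm > 0)
    return a_hat, b3_hat, c_hat, b2_hat, B_mm, ok


def fit_msem(
    data: MediationDataset | SufficientStats,
    bootstrap_reps: int = 200,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> FitResult:
    """Latent-decomposition fit with cluster-bootstrap standard errors.

    ``converged`` is False when the latent M_B variance estimate is
    non-positive or the latent predictor covariance is singular.
    """
    if bootstrap_reps < 50:
        raise ValueError("bootstrap_reps must be >= 50 for stable SEs")
    st = data if isinstance(data, SufficientStats) else SufficientStats.from_dataset(data)
    if st.x.ndim != 1:
        raise ValueError("fit_msem expects a single replication")
    n3, n2, n1 = st.n3, st.n2, st.n1

    Sb, Sw_mm, Sw_my, Sw_yy, s1sq = _moments(st)
    a_hat, b3_hat, c_hat, b2_hat, B_mm, ok = _point_estimates(Sb, Sw_mm, Sw_my, n2)

    # --- stratified cluster bootstrap over per-cluster statistics ---------
    rng = np.random.default_rng(seed)
    arms = [np.flatnonzero(st.x == v) for v in np.unique(st.x)]
    B = bootstrap_reps
    idx = np.concatenate(
        [arm[rng.integers(0, arm.size, size=(B, arm.size))] for arm in arms],
        axis=1,
    )  # (B, n3)
    boot = SufficientStats(
        x=st.x[idx], m_bar=st.m_bar[idx], y_bar=st.y_bar[idx],
        s_mm=st.s_mm[idx], s_my=st.s_my[idx], s_yy=st.s_yy[idx],
        ss1=st.ss1[idx], n2=n2, n1=n1,
    )
    Sb_b, Sw_mm_b, Sw_my_b, _, _ = _moments(boot)
    a_b, b3_b, c_b, b2_b, _, ok_b = _point_estimates(Sb_b, Sw_mm_b, Sw_my_b, n2)

    def boot_se(v):
        vv = v[ok_b & np.isfinite(v)]
        return _robust_scale(vv)

    se_a, se_b3, se_c, se_b2 = (boot_se(v) for v in (a_b, b3_b, c_b, b2_b))
    converged = bool(ok) and np.isfinite(se_a) and np.isfinite(se_b3)

    between3, within2, _ = latent_between_cov(st)
    return FitResult(
        a_hat=float(a_hat), se_a=se_a,
        b3_hat=float(b3_hat), se_b3=se_b3,
        b2_hat=float(b2_hat), se_b2=se_b2,
        c_hat=float(c_hat), se_c=se_c,
        var_m3=float(max(B_mm - a_hat ** 2 * Sb["xx"], 0.0)) if np.isfinite(a_hat) else np.nan,
        var_m2=float(Sw_mm),
        var_y3=float(between3[2, 2]),
        var_y2=float(within2[1, 1]),
        var_y1=float(s1sq),
        loglik=np.nan,           # moment estimator: no likelihood evaluated
        converged=converged,
        truncated=False,
        estimator_tag="MSEM",
    )


_IQR_TO_SD = 1.3489795003921634   # IQR of the standard normal


def _robust_scale(v: np.ndarray) -> float:
    """Normal-consistent IQR scale; NaN when fewer than 2 usable draws."""
    if v.size < 2:
        return float("nan")
    q75, q25 = np.percentile(v, [75.0, 25.0])
    s = (q75 - q25) / _IQR_TO_SD
    return float(s) if s > 0 else float("nan")


def fit_msem_batched(
    st: SufficientStats,
    bootstrap_reps: int,
    seeds: list,
) -> dict[str, np.ndarray]:
    """MSEM fits for a batch of replications (leading axis of ``st``).

    ``seeds`` supplies one bootstrap seed per replication.  Only the
    quantities needed for the Sobel test (paths + SEs + convergence) are
    returned.
    """
    R = st.x.shape[0]
    n2 = st.n2
    Sb, Sw_mm, Sw_my, _, _ = _moments(st)
    a_hat, b3_hat, c_hat, b2_hat, _, ok = _point_estimates(Sb, Sw_mm, Sw_my, n2)

    se_a = np.full(R, np.nan)
    se_b3 = np.full(R, np.nan)
    for r in range(R):
        if not ok[r]:
            continue
        one = SufficientStats(
            x=st.x[r], m_bar=st.m_bar[r], y_bar=st.y_bar[r],
            s_mm=st.s_mm[r], s_my=st.s_my[r], s_yy=st.s_yy[r],
            ss1=st.ss1[r], n2=st.n2, n1=st.n1,
        )
        rng = np.random.default_rng(seeds[r])
        arms = [np.flatnonzero(one.x == v) for v in np.unique(one.x)]
        idx = np.concatenate(
            [arm[rng.integers(0, arm.size, size=(bootstrap_reps, arm.size))]
             for arm in arms], axis=1)
        boot = SufficientStats(
            x=one.x[idx], m_bar=one.m_bar[idx], y_bar=one.y_bar[idx],
            s_mm=one.s_mm[idx], s_my=one.s_my[idx], s_yy=one.s_yy[idx],
            ss1=one.ss1[idx], n2=st.n2, n1=st.n1,
        )
        Sb_b, Sw_mm_b, Sw_my_b, _, _ = _moments(boot)
        a_b, b3_b, _, _, _, ok_b = _point_estimates(Sb_b, Sw_mm_b, Sw_my_b, n2)
        se_a[r] = _robust_scale(a_b[ok_b & np.isfinite(a_b)])
        se_b3[r] = _robust_scale(b3_b[ok_b & np.isfinite(b3_b)])

    converged = ok & np.isfinite(se_a) & np.isfinite(se_b3) & (se_a > 0) & (se_b3 > 0)
    return {
        "a_hat": a_hat, "se_a": se_a,
        "b3_hat": b3_hat, "se_b3": se_b3,
        "b2_hat": b2_hat, "c_hat": c_hat,
        "converged": converged,
    }
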