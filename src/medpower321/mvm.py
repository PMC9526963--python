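"""Manifest-variable multilevel (MVM) estimation of the 3-2-1 mediation model.

Two models are fitted by maximum likelihood:

* **M-model** (2 levels): ``M_jk = g0 + a * X_k + u_k + r_jk`` — the X->M path.
* **Y-model** (3 levels), with the mediator decomposed *centered within
  context with means reintroduced*: the observed cluster mean of M enters at
  level 3 and the within-cluster deviation at level 2::

      Y_ijk = g0 + b3 * mean_k(M) + b2 * (M_jk - mean_k(M)) + c * X_k
              + v_k + u_jk + e_ijk

For a balanced design with level-appropriate predictors, the Gaussian
likelihood factorizes over three mutually orthogonal strata (within-unit
contrasts, between-unit-within-cluster contrasts, cluster means), each an
ordinary regression with its own residual eigen-variance.  ML therefore has a
closed form: stratum-wise OLS for the fixed effects and SS/df for the
eigen-variances, followed by isotonic (pool-adjacent-violators) projection to
keep the implied variance components non-negative.  Standard errors are
model-based ML (inverse information).  Everything is a function of the
per-cluster sufficient statistics and is vectorized over replications.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import MediationDataset, SufficientStats

__all__ = ["FitResult", "decompose_cwc", "fit_mvm"]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class FitResult:
    """Estimated paths, SEs and variance components for one dataset."""

    a_hat: float
    se_a: float
    b3_hat: float
    se_b3: float
    b2_hat: float
    se_b2: float
    c_hat: float
    se_c: float
    var_m3: float      # level-3 variance of M (residual, given X)
    var_m2: float      # level-2 variance of M
    var_y3: float      # level-3 residual variance of Y
    var_y2: float      # level-2 residual variance of Y
    var_y1: float      # level-1 variance of Y
    loglik: float
    converged: bool
    truncated: bool    # a variance component was truncated at zero
    estimator_tag: str


def decompose_cwc(ds: MediationDataset) -> pd.DataFrame:
    """Long-format frame with the CWC decomposition of the mediator added.

    ``m_mean3`` is the observed cluster mean of M (reintroduced at level 3),
    ``m_dev`` the within-cluster deviation; deviations sum to zero within
    each cluster by construction.
    """
    df = ds.to_frame()
    m_mean3 = ds.m.mean(axis=1)
    df["m_mean3"] = m_mean3[df.cluster_id.to_numpy()]
    df["m_dev"] = df.m - df.m_mean3
    return df


def _pava2(lam_a, m_a, ss_a, lam_b, m_b, ss_b):
    """Project (lam_a <= lam_b) onto the constraint by pooling when violated."""
    viol = lam_b < lam_a
    pooled = (ss_a + ss_b) / (m_a + m_b)
    return np.where(viol, pooled, lam_a), np.where(viol, pooled, lam_b), viol


def fit_mvm_batched(st: SufficientStats, se_method: str = "robust") -> dict[str, np.ndarray]:
    """Closed-form ML fit on (batched) sufficient statistics.

    ``se_method`` selects the fixed-effect standard errors:

    * ``"robust"`` (default) — cluster-level sandwich (HC0) estimator, the
      analogue of maximum likelihood with robust standard errors (MLR) for
      this balanced design: point estimates are ML; each cluster contributes
      an independent score, and the empirical outer product of cluster
      scores replaces the model-based information in the middle of the
      sandwich.
    * ``"ml"`` — model-based inverse-information SEs at the ML solution.

    Returns a dict of arrays with one entry per replication (scalar arrays
    for a single dataset).
    """
    if se_method not in ("robust", "ml"):
        raise ValueError("se_method must be 'robust' or 'ml'")
    n3, n2, n1 = st.n3, st.n2, st.n1
    x = st.x
    sum_x2 = (x ** 2).sum(axis=-1)           # = n3 for -1/+1 coding

    # ---- M-model: OLS on cluster means + within SS ----------------------
    mb = st.m_bar
    mb_mean = mb.mean(axis=-1, keepdims=True)
    a_hat = ((mb - mb_mean) * x).sum(axis=-1) / sum_x2
    ssb_m = ((mb - mb_mean - a_hat[..., None] * x) ** 2).sum(axis=-1)
    ssw_m = st.s_mm.sum(axis=-1)
    m_w = n3 * (n2 - 1)                      # within df
    m_b_df = n3                              # ML divisor for the mean stratum
    with np.errstate(divide="ignore", invalid="ignore"):
        lam_w = ssw_m / m_w                  # sigma^2 within
        lam_b = n2 * ssb_m / m_b_df          # sigma^2 + n2 * tau
    lam_w_e, lam_b_e, trunc_m = _pava2(lam_w, m_w, ssw_m, lam_b, m_b_df, n2 * ssb_m)
    var_m2 = lam_w_e
    var_m3 = (lam_b_e - lam_w_e) / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        se_a = np.sqrt(lam_b_e / (n2 * sum_x2))
        ll_m = -0.5 * (m_w * np.log(lam_w_e) + ssw_m / np.maximum(lam_w_e, 1e-300)
                       + m_b_df * np.log(lam_b_e) + n2 * ssb_m / np.maximum(lam_b_e, 1e-300)
                       + n3 * n2 * _LOG2PI)

    # ---- Y-model stratum 1: within-unit ---------------------------------
    ss1 = st.ss1.sum(axis=-1)
    m1 = n3 * n2 * (n1 - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        lam1 = ss1 / m1 if m1 > 0 else np.zeros_like(ss1)

    # ---- Y-model stratum 2: between-unit within-cluster -----------------
    S_mm = st.s_mm.sum(axis=-1)
    S_my = st.s_my.sum(axis=-1)
    S_yy = st.s_yy.sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        b2_hat = S_my / S_mm
    rss2 = S_yy - np.where(S_mm > 0, S_my ** 2 / np.maximum(S_mm, 1e-300), 0.0)
    ss2 = n1 * rss2
    m2_df = n3 * (n2 - 1)
    lam2 = ss2 / m2_df

    # ---- Y-model stratum 3: cluster means -------------------------------
    yb = st.y_bar
    yb_mean = yb.mean(axis=-1, keepdims=True)
    mc = mb - mb_mean
    yc = yb - yb_mean
    Sc_mm = (mc ** 2).sum(axis=-1)
    Sc_mx = (mc * x).sum(axis=-1)
    Sc_my = (mc * yc).sum(axis=-1)
    Sc_xy = (x * yc).sum(axis=-1)
    det = Sc_mm * sum_x2 - Sc_mx ** 2
    bad = ~(det > 1e-10 * (Sc_mm + 1e-12) * sum_x2)
    det_safe = np.where(bad, 1.0, det)
    b3_hat = (Sc_my * sum_x2 - Sc_mx * Sc_xy) / det_safe
    c_hat = (Sc_mm * Sc_xy - Sc_mx * Sc_my) / det_safe
    rss3 = (yc ** 2).sum(axis=-1) - b3_hat * Sc_my - c_hat * Sc_xy
    rss3 = np.maximum(rss3, 0.0)
    ss3 = n1 * n2 * rss3
    m3_df = n3
    lam3 = ss3 / m3_df

    # ---- isotonic projection lam1 <= lam2 <= lam3 (3-point PAVA) --------
    if m1 > 0:
        lam1_e, lam2_e, lam3_e, trunc_y = _pava3(lam1, m1, ss1, lam2, m2_df, ss2,
                                                 lam3, m3_df, ss3)
    else:
        lam1_e = np.zeros_like(lam2)
        lam2_e, lam3_e, trunc_y = _pava2(lam2, m2_df, ss2, lam3, m3_df, ss3)

    sig1 = lam1_e
    sig2 = np.maximum((lam2_e - lam1_e) / n1, 0.0)
    sig3 = np.maximum((lam3_e - lam2_e) / (n1 * n2), 0.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        se_b2 = np.sqrt(lam2_e / (n1 * np.maximum(S_mm, 1e-300)))
        se_b3 = np.sqrt(lam3_e / (n1 * n2) * sum_x2 / det_safe)
        se_c = np.sqrt(lam3_e / (n1 * n2) * Sc_mm / det_safe)
        ll_y = -(m1 * np.log(np.maximum(lam1_e, 1e-300)) + ss1 / np.maximum(lam1_e, 1e-300)
                 + m2_df * np.log(np.maximum(lam2_e, 1e-300)) + ss2 / np.maximum(lam2_e, 1e-300)
                 + m3_df * np.log(np.maximum(lam3_e, 1e-300)) + ss3 / np.maximum(lam3_e, 1e-300)
                 + n3 * n2 * n1 * _LOG2PI) / 2.0

    if se_method == "robust":
        # Cluster-level sandwich: clusters are independent; the fixed effects
        # of each stratum see one score per cluster, and the balanced-design
        # factorization makes the sandwich the HC0 estimator of the
        # corresponding cluster-level regression (variance scalars cancel
        # between bread and meat).
        with np.errstate(divide="ignore", invalid="ignore"):
            e_m = mc - a_hat[..., None] * x                       # M-model residuals
            se_a = np.sqrt(((e_m ** 2) * x ** 2).sum(axis=-1)) / sum_x2
            eps = yc - b3_hat[..., None] * mc - c_hat[..., None] * x
            Mmm = ((eps ** 2) * mc ** 2).sum(axis=-1)
            Mmx = ((eps ** 2) * mc * x).sum(axis=-1)
            Mxx = ((eps ** 2) * x ** 2).sum(axis=-1)
            se_b3 = np.sqrt(sum_x2 ** 2 * Mmm - 2 * sum_x2 * Sc_mx * Mmx
                            + Sc_mx ** 2 * Mxx) / np.abs(det_safe)
            se_c = np.sqrt(Sc_mx ** 2 * Mmm - 2 * Sc_mx * Sc_mm * Mmx
                           + Sc_mm ** 2 * Mxx) / np.abs(det_safe)
            u2 = st.s_my - b2_hat[..., None] * st.s_mm            # b2 scores
            se_b2 = np.sqrt((u2 ** 2).sum(axis=-1)) / np.maximum(S_mm, 1e-300)

    # convergence = the cluster-level system is full rank; a degenerate
    # within-cluster M (S_mm == 0) only leaves b2 undefined (NaN)
    converged = ~bad & np.isfinite(a_hat) & np.isfinite(b3_hat)
    return {
        "a_hat": a_hat, "se_a": se_a,
        "b3_hat": b3_hat, "se_b3": se_b3,
        "b2_hat": b2_hat, "se_b2": se_b2,
        "c_hat": c_hat, "se_c": se_c,
        "var_m3": np.maximum(var_m3, 0.0), "var_m2": var_m2,
        "var_y3": sig3, "var_y2": sig2, "var_y1": sig1,
        "loglik": ll_m + ll_y,
        "converged": converged,
        "truncated": trunc_m | trunc_y,
    }


def _pava3(l1, m1, s1, l2, m2, s2, l3, m3, s3):
    """Weighted isotonic projection of three stratum variances (ML on the
    boundary of the variance-component parameter space)."""
    trunc = (l2 < l1) | (l3 < l2)
    # case A: pool 1&2 first
    p12 = (s1 + s2) / (m1 + m2)
    pall = (s1 + s2 + s3) / (m1 + m2 + m3)
    p23 = (s2 + s3) / (m2 + m3)
    # start from unconstrained; resolve the 5 possible configurations
    v12 = l2 < l1
    # after pooling 1&2 (where violated), check against 3
    a1 = np.where(v12, p12, l1)
    a2 = np.where(v12, p12, l2)
    v23 = l3 < a2
    b2_ = np.where(v23, np.where(v12, pall, p23), a2)
    b3_ = np.where(v23, b2_, l3)
    b1_ = np.where(v23 & v12, pall, a1)
    # pooling 2&3 may now violate 1<=2
    v12b = b2_ < b1_
    c_ = np.where(v12b, pall, np.nan)
    f1 = np.where(v12b, c_, b1_)
    f2 = np.where(v12b, c_, b2_)
    f3 = np.where(v12b, c_, b3_)
    return f1, f2, f3, trunc


def fit_mvm(data: MediationDataset | SufficientStats,
            se_method: str = "robust") -> FitResult:
    """Fit the MVM mediation model to one dataset (or its sufficient stats)."""
    st = data if isinstance(data, SufficientStats) else SufficientStats.from_dataset(data)
    out = fit_mvm_batched(st, se_method=se_method)
    scal = {k: (np.asarray(v).item() if np.asarray(v).ndim == 0
                else np.asarray(v).ravel()[0]) for k, v in out.items()}
    return FitResult(
        a_hat=scal["a_hat"], se_a=scal["se_a"],
        b3_hat=scal["b3_hat"], se_b3=scal["se_b3"],
        b2_hat=scal["b2_hat"], se_b2=scal["se_b2"],
        c_hat=scal["c_hat"], se_c=scal["se_c"],
        var_m3=scal["var_m3"], var_m2=scal["var_m2"],
        var_y3=scal["var_y3"], var_y2=scal["var_y2"], var_y1=scal["var_y1"],
        loglik=scal["loglik"],
        converged=bool(scal["converged"]),
        truncated=bool(scal["truncated"]),
        estimator_tag="MVM",
    )
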