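"""MVM estimator: CWC decomposition, closed-form ML, and oracle agreement."""

import numpy as np
import pytest

from medpower321 import (
    DesignSpec,
    MediationDataset,
    PopulationParams,
    decompose_cwc,
    derive_components,
    fit_mvm,
    generate,
)
from medpower321.population import mvm_between_slope_limit, mvm_direct_slope_limit
from medpower321.simulate import SufficientStats


class TestDecomposeCWC:
    def test_arithmetic_example(self):
        ds = MediationDataset(
            x=np.array([-1.0, 1.0]),
            m=np.array([[1.0, 2.0, 3.0], [4.0, 4.0, 4.0]]),
            y=np.zeros((2, 3, 1)),
        )
        df = decompose_cwc(ds)
        c0 = df[df.cluster_id == 0].drop_duplicates("unit_id")
        assert c0.m_mean3.unique() == [2.0]
        assert list(c0.m_dev) == [-1.0, 0.0, 1.0]
        c1 = df[df.cluster_id == 1]
        assert (c1.m_dev == 0).all()  # constant M -> zero deviations

    def test_deviations_sum_to_zero_per_cluster(self, small_dataset):
        df = decompose_cwc(small_dataset)
        sums = df.drop_duplicates(["cluster_id", "unit_id"]).groupby("cluster_id").m_dev.sum()
        assert (sums.abs() < 1e-10).all()


class TestFitMVM:
    def test_large_n_consistency(self, large_effect_params):
        p = large_effect_params
        ds = generate(p, 2000, 20, 12, seed=11)
        fr = fit_mvm(ds)
        assert fr.converged
        assert fr.a_hat == pytest.approx(p.a_raw, abs=0.01)
        assert fr.b2_hat == pytest.approx(p.b2_raw, abs=0.01)
        # manifest direct effect converges to its own (inflated) limit
        assert fr.c_hat == pytest.approx(mvm_direct_slope_limit(p, 20), abs=0.02)

    def test_between_slope_attenuates_to_derived_limit(self, large_effect_params):
        p = large_effect_params
        ds = generate(p, 2000, 5, 3, seed=12)
        fr = fit_mvm(ds)
        assert fr.b3_hat == pytest.approx(mvm_between_slope_limit(p, 5), abs=0.02)

    def test_noise_free_y_model_exact_recovery(self):
        """Y deterministic given (M_B, X) and var_mW=0: no attenuation, exact fit."""
        p = PopulationParams(a_raw=0.3, b3_raw=0.5, b2_raw=0.0, c_raw=0.2,
                             var_mB_resid=0.1, var_mW=0.0, var_yB_resid=0.0,
                             var_y2_resid=0.0, var_y1=0.0)
        ds = generate(p, 10, 4, 2, seed=3)
        fr = fit_mvm(ds)
        assert fr.converged
        assert fr.b3_hat == pytest.approx(0.5, abs=1e-8)
        assert fr.c_hat == pytest.approx(0.2, abs=1e-8)

    def test_noise_free_m_model_exact_recovery(self):
        """M deterministic given X: exact a path; Y-model is then collinear."""
        p = PopulationParams(a_raw=0.3, b3_raw=0.5, b2_raw=0.0, c_raw=0.2,
                             var_mB_resid=0.0, var_mW=0.0, var_yB_resid=0.0,
                             var_y2_resid=0.0, var_y1=0.1)
        ds = generate(p, 10, 4, 2, seed=3)
        fr = fit_mvm(ds)
        assert fr.a_hat == pytest.approx(0.3, abs=1e-10)
        assert not fr.converged  # cluster mean of M collinear with X

    def test_m_model_equals_ols_on_cluster_means(self, small_dataset):
        """Balanced-design shortcut: ML fixed effects = OLS on cluster means."""
        fr = fit_mvm(small_dataset)
        mb = small_dataset.m.mean(axis=1)
        x = small_dataset.x
        slope = np.cov(mb, x, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert fr.a_hat == pytest.approx(slope, abs=1e-8)

    def test_scale_equivariance_and_sobel_invariance(self, small_dataset):
        from medpower321 import sobel
        fr = fit_mvm(small_dataset, se_method="ml")
        scaled = MediationDataset(x=small_dataset.x, m=small_dataset.m,
                                  y=small_dataset.y * 3.0)
        fs = fit_mvm(scaled, se_method="ml")
        for name in ("b3", "b2", "c"):
            assert getattr(fs, f"{name}_hat") == pytest.approx(
                3.0 * getattr(fr, f"{name}_hat"), rel=1e-9)
            assert getattr(fs, f"se_{name}") == pytest.approx(
                3.0 * getattr(fr, f"se_{name}"), rel=1e-9)
        z0 = sobel(fr.a_hat, fr.se_a, fr.b3_hat, fr.se_b3).z
        z1 = sobel(fs.a_hat, fs.se_a, fs.b3_hat, fs.se_b3).z
        assert z1 == pytest.approx(z0, rel=1e-9)

    def test_se_shrinks_at_root_n3_rate(self, large_effect_params):
        """log-log slope of SE(b3) vs n3 is -0.5 within 0.05 (averaged fits)."""
        from medpower321.mvm import fit_mvm_batched
        from medpower321.simulate import generate_sufficient
        ses = []
        for n3 in (20, 80, 320):
            st = generate_sufficient(large_effect_params, n3, 5, 3,
                                     seed=100 + n3, reps=300)
            f = fit_mvm_batched(st, se_method="ml")
            ses.append(np.mean(f["se_b3"]))
        slope = np.polyfit(np.log([20, 80, 320]), np.log(ses), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.05)

    def test_degenerate_constant_cluster_means_flagged(self):
        ds = MediationDataset(
            x=np.array([-1.0, -1.0, 1.0, 1.0]),
            m=np.tile([[0.5, -0.5]], (4, 1)),      # every cluster mean = 0
            y=np.random.default_rng(0).normal(size=(4, 2, 2)),
        )
        fr = fit_mvm(ds)
        assert not fr.converged


class TestAgainstMixedLMOracle:
    """Independent oracle: statsmodels MixedLM maximum likelihood."""

    @pytest.fixture(scope="class")
    def fits(self, small_dataset):
        import statsmodels.formula.api as smf
        fr = fit_mvm(small_dataset, se_method="ml")
        df = decompose_cwc(small_dataset)
        dfu = df.drop_duplicates(["cluster_id", "unit_id"])
        mm = smf.mixedlm("m ~ x", dfu, groups=dfu.cluster_id).fit(reml=False)
        df["unit"] = df.cluster_id.astype(str) + "_" + df.unit_id.astype(str)
        ym = smf.mixedlm("y ~ m_mean3 + m_dev + x", df, groups=df.cluster_id,
                         re_formula="1",
                         vc_formula={"unit": "0 + C(unit)"}).fit(reml=False)
        return fr, mm, ym

    def test_point_estimates_match(self, fits):
        fr, mm, ym = fits
        assert fr.a_hat == pytest.approx(mm.params["x"], abs=1e-8)
        assert fr.b3_hat == pytest.approx(ym.params["m_mean3"], abs=1e-7)
        assert fr.b2_hat == pytest.approx(ym.params["m_dev"], abs=1e-7)
        assert fr.c_hat == pytest.approx(ym.params["x"], abs=1e-7)

    # tolerances reflect MixedLM's iterative optimizer precision; the
    # closed-form solution is the exact optimum (it attains a loglik at
    # least as high — asserted below)

    def test_model_based_ses_match(self, fits):
        fr, mm, ym = fits
        assert fr.se_a == pytest.approx(mm.bse["x"], rel=2e-3)
        assert fr.se_b3 == pytest.approx(ym.bse["m_mean3"], rel=2e-3)
        assert fr.se_b2 == pytest.approx(ym.bse["m_dev"], rel=2e-3)
        assert fr.se_c == pytest.approx(ym.bse["x"], rel=2e-3)

    def test_loglik_matches_and_closed_form_is_optimal(self, fits):
        fr, mm, ym = fits
        assert fr.loglik == pytest.approx(mm.llf + ym.llf, abs=1e-3)
        assert fr.loglik >= mm.llf + ym.llf - 1e-8

    def test_variance_components_match(self, fits):
        fr, mm, ym = fits
        assert fr.var_m2 == pytest.approx(mm.scale, abs=2e-3)
        assert fr.var_m3 == pytest.approx(float(mm.cov_re.iloc[0, 0]), abs=2e-3)
        assert fr.var_y1 == pytest.approx(ym.scale, abs=2e-3)
        assert fr.var_y2 == pytest.approx(float(ym.vcomp[0]), abs=2e-3)
        assert fr.var_y3 == pytest.approx(float(ym.cov_re.iloc[0, 0]), abs=2e-3)


def test_fit_accepts_sufficient_stats(small_dataset):
    st = SufficientStats.from_dataset(small_dataset)
    a = fit_mvm(small_dataset)
    b = fit_mvm(st)
    assert a.b3_hat == pytest.approx(b.b3_hat, abs=1e-12)
    assert a.se_b3 == pytest.approx(b.se_b3, abs=1e-12)
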