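"""Mixed-model engine: ML/REML fits, LRT, fast family path, ACE decomposition."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from twinage.exceptions import ContractError, ValidationError
from twinage.lmm import (
    FamilyRotation,
    FitResult,
    LOG2PI,
    age_scan_batch,
    conditional_residuals_batch,
    fit_ace,
    fit_lmm,
    lrt_nested,
)

from conftest import make_twin_samples


def _stub_fit(loglik, method="ML", n=100):
    z = np.zeros(1)
    return FitResult(
        beta=z, beta_se=z, beta_names=["i"], varcomps={}, sigma2_resid=1.0,
        loglik=loglik, method=method, converged=True, residuals_marginal=z,
        residuals_conditional=z, n=n, n_fixed=1,
    )


class TestFitLmm:
    def test_singleton_groups_reduce_to_ols(self):
        rng = np.random.default_rng(0)
        n = 80
        x = rng.normal(size=n)
        y = 1.0 + 2.0 * x + rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        fit = fit_lmm(y, X, random={"fam": np.arange(n)}, method="ML")
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(fit.beta, ols, atol=1e-6)
        assert fit.varcomps["fam"] < 1e-6

    def test_recovers_simulated_effects(self):
        # y = 2 + 0.5 x + family(sigma2=1) + noise(sigma2=1), 500 families x 2;
        # the generating parameters are the oracle, with Monte-Carlo tolerance
        # on the mean over replicates (this engine matches lme4 to 6 decimals
        # on single datasets, verified during development)
        rng = np.random.default_rng(1)
        errs_beta, errs_vf, errs_ve = [], [], []
        for _ in range(5):
            nf = 500
            fam = np.repeat(np.arange(nf), 2)
            n = 2 * nf
            x = rng.normal(size=n)
            y = 2.0 + 0.5 * x + rng.normal(size=nf)[fam] + rng.normal(size=n)
            fit = fit_lmm(y, np.column_stack([np.ones(n), x]), random={"family": fam},
                          method="REML", names=["intercept", "x"])
            errs_beta.append(fit.coef("x") - 0.5)
            errs_vf.append(fit.varcomps["family"] - 1.0)
            errs_ve.append(fit.sigma2_resid - 1.0)
        assert abs(np.mean(errs_beta)) < 0.1
        assert abs(np.mean(errs_vf)) < 0.1
        assert abs(np.mean(errs_ve)) < 0.1

    def test_exact_fit(self):
        rng = np.random.default_rng(2)
        n = 60
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        fit = fit_lmm(x, X, random={"fam": np.repeat(np.arange(30), 2)})
        assert fit.sigma2_resid < 1e-10
        np.testing.assert_allclose(fit.coef("x1"), 1.0, atol=1e-6)

    def test_conditional_residuals_orthogonal_to_fixed(self):
        rng = np.random.default_rng(3)
        nf = 100
        fam = np.repeat(np.arange(nf), 2)
        n = 2 * nf
        x = rng.normal(size=n)
        y = 0.3 * x + rng.normal(size=nf)[fam] + rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        fit = fit_lmm(y, X, random={"family": fam})
        for j in range(2):
            assert abs(X[:, j] @ fit.residuals_conditional) < 1e-6 * n
        # conditional residuals sum to ~0 with an intercept
        assert abs(fit.residuals_conditional.sum()) < 1e-6 * n

    def test_crossed_random_factors(self):
        # two crossed factors, both with real variance, recovered roughly
        rng = np.random.default_rng(4)
        n = 600
        f1 = rng.integers(0, 20, n)
        f2 = rng.integers(0, 15, n)
        y = rng.normal(0, 1, 20)[f1] + rng.normal(0, 1, 15)[f2] + rng.normal(size=n)
        fit = fit_lmm(y, np.ones((n, 1)), random={"a": f1, "b": f2}, method="REML")
        assert 0.3 < fit.varcomps["a"] < 2.5
        assert 0.3 < fit.varcomps["b"] < 2.5
        assert 0.7 < fit.sigma2_resid < 1.4

    def test_aliased_column_dropped(self):
        rng = np.random.default_rng(5)
        n = 40
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x, 2.0 * x])
        fit = fit_lmm(x, X, names=["i", "x", "x2"])
        assert len(fit.beta_names) == 2


class TestLrt:
    def test_identical_models_give_zero(self):
        f = _stub_fit(-100.0)
        stat, p = lrt_nested(f, f)
        assert stat == 0.0 and p == 1.0

    def test_quantile_anchor(self):
        # a statistic of 3.841 sits at the chi2(1) 5% tail
        stat, p = lrt_nested(_stub_fit(-100.0 + 3.841 / 2), _stub_fit(-100.0))
        assert stat == pytest.approx(3.841)
        assert p == pytest.approx(0.050, abs=5e-4)

    def test_reml_fits_rejected(self):
        with pytest.raises(ContractError):
            lrt_nested(_stub_fit(-1.0, method="REML"), _stub_fit(-2.0, method="REML"))

    def test_null_statistic_is_chi2(self):
        # moderate-size version; the large-n check lives in the acceptance suite
        rng = np.random.default_rng(6)
        nf = 100
        fam = np.repeat(np.arange(nf), 2)
        n = 2 * nf
        age = rng.uniform(39, 85, nf)[fam]
        Y = rng.normal(size=(300, n)) + 0.7 * rng.normal(size=(300, nf))[:, fam]
        res = age_scan_batch(Y, np.ones((n, 1)), age, fam)
        ks = stats.kstest(res["lrt"], stats.chi2(df=1).cdf)
        assert ks.pvalue > 0.01


class TestFamilyFastPath:
    def test_matches_dense_engine(self):
        rng = np.random.default_rng(7)
        nf = 120
        fam = np.repeat(np.arange(nf), 2)
        n = 2 * nf
        age = rng.uniform(39, 85, nf)[fam]
        Y = rng.normal(size=(4, n)) + 0.8 * rng.normal(size=(4, nf))[:, fam]
        res = age_scan_batch(Y, np.ones((n, 1)), age, fam)
        for i in range(4):
            full = fit_lmm(Y[i], np.column_stack([np.ones(n), age]), random={"family": fam})
            red = fit_lmm(Y[i], np.ones((n, 1)), random={"family": fam})
            stat, _ = lrt_nested(full, red)
            assert res["lrt"][i] == pytest.approx(stat, abs=1e-4)
            assert res["full"].loglik[i] == pytest.approx(full.loglik, abs=1e-5)

    def test_conditional_residuals_match_dense(self):
        rng = np.random.default_rng(8)
        nf = 60
        fam = np.repeat(np.arange(nf), 2)
        n = 2 * nf
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        Y = rng.normal(size=(2, n)) + rng.normal(size=(2, nf))[:, fam]
        cr = conditional_residuals_batch(Y, X, fam)
        fit = fit_lmm(Y[0], X, random={"family": fam})
        np.testing.assert_allclose(cr[0], fit.residuals_conditional, atol=1e-5)

    def test_rotation_preserves_norms(self):
        rng = np.random.default_rng(9)
        samples = make_twin_samples(10, 10, 3)
        rot = FamilyRotation(samples.families)
        v = rng.normal(size=len(samples.data))
        assert np.linalg.norm(rot.rotate(v)) == pytest.approx(np.linalg.norm(v))


def _simulate_ace(samples, A, C, E, beta_age=0.0, rng=None):
    rng = rng or np.random.default_rng(0)
    fam = samples.families
    fidx = pd.factorize(fam)[0]
    nfam = fidx.max() + 1
    n = len(samples.data)
    ismz = samples.data["zygosity"].to_numpy() == "MZ"
    a_sh = rng.normal(size=nfam)[fidx]
    a_own = rng.normal(size=n)
    a = np.where(ismz, a_sh * np.sqrt(A), a_sh * np.sqrt(A / 2) + a_own * np.sqrt(A / 2))
    c = rng.normal(size=nfam)[fidx] * np.sqrt(C)
    e = rng.normal(size=n) * np.sqrt(E)
    return beta_age * samples.ages + a + c + e


class TestAce:
    def test_independent_twins_are_all_e(self):
        samples = make_twin_samples(800, 800, seed=10)
        y = _simulate_ace(samples, 0.0, 0.0, 1.0, rng=np.random.default_rng(10))
        vc = fit_ace(y, samples)
        assert vc.sigma2_a < 0.06
        assert vc.sigma2_c < 0.06
        assert vc.sigma2_e == pytest.approx(1.0, abs=0.1)

    def test_equal_correlation_limit_is_common_environment(self):
        # r_MZ = r_DZ = c  ->  A ~ 0, C ~ c * total (Falconer 2(r_MZ - r_DZ) = 0)
        samples = make_twin_samples(800, 800, seed=11)
        y = _simulate_ace(samples, 0.0, 0.4, 0.6, rng=np.random.default_rng(11))
        vc = fit_ace(y, samples)
        assert vc.sigma2_a < 0.08
        assert vc.sigma2_c == pytest.approx(0.4, abs=0.08)

    def test_single_zygosity_rejected(self):
        samples = make_twin_samples(50, 0, seed=12)
        with pytest.raises(ValidationError, match="MZ and DZ"):
            fit_ace(np.random.default_rng(0).normal(size=len(samples.data)), samples)

    def test_too_few_pairs_rejected(self):
        samples = make_twin_samples(5, 5, seed=13)
        with pytest.raises(ValidationError, match=">= 20"):
            fit_ace(np.zeros(len(samples.data)), samples)

    def test_components_never_negative(self):
        # data engineered toward negative A (r_DZ > r_MZ): box constraint binds
        samples = make_twin_samples(200, 200, seed=14)
        rng = np.random.default_rng(14)
        fidx = pd.factorize(samples.families)[0]
        isdz = samples.data["zygosity"].to_numpy() == "DZ"
        shared = rng.normal(size=fidx.max() + 1)[fidx]
        y = np.where(isdz, shared * 0.9, 0.0) + rng.normal(size=len(samples.data)) * 0.5
        vc = fit_ace(y, samples)
        assert vc.sigma2_a >= 0.0 and vc.sigma2_c >= 0.0 and vc.sigma2_e > 0.0
        props = vc.proportions
        assert all(0 <= v <= 1 for v in props.values())
        assert sum(props.values()) == pytest.approx(1.0, abs=1e-6)

    def test_blockwise_reml_equals_dense_oracle(self):
        # the blockwise likelihood must equal a dense-matrix REML evaluation
        samples = make_twin_samples(6, 4, seed=15)
        y = _simulate_ace(samples, 0.5, 0.2, 0.3, beta_age=0.05,
                          rng=np.random.default_rng(15))
        vc = fit_ace(y, samples, min_pairs=10)

        mz = samples.complete_pairs("MZ")
        dz = samples.complete_pairs("DZ")
        pairs = np.array(mz + dz)
        idx = pairs.ravel()
        yv = y[idx]
        ages = samples.ages[idx]
        n = yv.size
        X = np.column_stack([np.ones(n), ages])
        V = np.zeros((n, n))
        t = vc.sigma2_a + vc.sigma2_c + vc.sigma2_e
        for k in range(len(pairs)):
            off = (1.0 if k < len(mz) else 0.5) * vc.sigma2_a + vc.sigma2_c
            V[2 * k, 2 * k] = V[2 * k + 1, 2 * k + 1] = t
            V[2 * k, 2 * k + 1] = V[2 * k + 1, 2 * k] = off
        Vi = np.linalg.inv(V)
        XtViX = X.T @ Vi @ X
        beta = np.linalg.solve(XtViX, X.T @ Vi @ yv)
        r = yv - X @ beta
        neg2 = (
            np.linalg.slogdet(V)[1]
            + np.linalg.slogdet(XtViX)[1]
            + float(r @ Vi @ r)
            + (n - 2) * LOG2PI
        )
        assert -0.5 * neg2 == pytest.approx(vc.loglik, abs=1e-8)
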