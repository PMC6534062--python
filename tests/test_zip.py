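import numpy as np
import pytest

from hwukit.containers import ValidationError
from hwukit.zip_model import fit_zip, stratified_snp_effects, zip_loglik, zip_score


def _zip_data(n=800, beta=(np.log(2.0), -0.3), gamma=(-1.0,), seed=0):
    rng = np.random.default_rng(seed)
    dose = rng.binomial(2, 0.3, size=n).astype(float)
    X = np.column_stack([np.ones(n), dose])
    Z = np.ones((n, 1))
    lam = np.exp(X @ np.asarray(beta))
    pi = 1.0 / (1.0 + np.exp(-(Z @ np.asarray(gamma))))
    y = np.where(rng.random(n) < pi, 0, rng.poisson(lam))
    return y.astype(float), X, Z


class TestLoglik:
    def test_reduces_to_poisson_when_zero_inflation_vanishes(self):
        from scipy.stats import poisson

        y, X, Z = _zip_data(n=200)
        beta = np.array([0.3, -0.2])
        ll = zip_loglik(y, X, Z, beta, np.array([-30.0]))
        lam = np.exp(X @ beta)
        ll_pois = poisson.logpmf(y, lam).sum()
        assert ll == pytest.approx(ll_pois, abs=1e-6)

    def test_single_zero_observation_closed_form(self):
        # y = 0, lambda = 1, pi = 0.5 -> log(0.5 + 0.5 e^{-1})
        ll = zip_loglik(np.array([0.0]), np.ones((1, 1)), np.ones((1, 1)),
                        np.array([0.0]), np.array([0.0]))
        # intercept-only with zero coefficients: lambda = 1, pi = 0.5
        assert ll == pytest.approx(np.log(0.5 + 0.5 * np.exp(-1.0)))

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValidationError):
            zip_loglik(np.array([0.5]), np.ones((1, 1)), np.ones((1, 1)),
                       np.zeros(1), np.zeros(1))

    def test_analytic_gradient_matches_finite_differences(self):
        y, X, Z = _zip_data(n=150, seed=1)
        rng = np.random.default_rng(2)
        theta = rng.normal(0, 0.3, size=3)
        grad = zip_score(y, X, Z, theta[:2], theta[2:])
        eps = 1e-6
        for j in range(3):
            tp, tm = theta.copy(), theta.copy()
            tp[j] += eps
            tm[j] -= eps
            fd = (zip_loglik(y, X, Z, tp[:2], tp[2:])
                  - zip_loglik(y, X, Z, tm[:2], tm[2:])) / (2 * eps)
            assert grad[j] == pytest.approx(fd, abs=1e-4)

    def test_gradient_near_zero_at_optimum(self):
        y, X, Z = _zip_data(seed=3)
        fit = fit_zip(y, X, Z)
        grad = zip_score(y, X, Z, fit.beta, fit.gamma)
        assert np.abs(grad).max() < 1e-3


class TestFit:
    def test_matches_poisson_glm_when_no_inflation(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        n = 1500
        dose = rng.binomial(2, 0.3, size=n).astype(float)
        X = np.column_stack([np.ones(n), dose])
        y = rng.poisson(np.exp(X @ np.array([0.5, -0.25]))).astype(float)
        fit = fit_zip(y, X)
        glm = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        assert abs(fit.beta[1] - glm.params[1]) < 2 * glm.bse[1]

    def test_cross_checked_against_statsmodels_zip(self):
        from statsmodels.discrete.count_model import ZeroInflatedPoisson

        y, X, Z = _zip_data(n=2000, seed=5)
        fit = fit_zip(y, X, Z)
        ref = ZeroInflatedPoisson(y, X, exog_infl=Z).fit(disp=0)
        # statsmodels orders params as (inflation, count)
        assert fit.beta[0] == pytest.approx(ref.params[1], abs=1e-3)
        assert fit.beta[1] == pytest.approx(ref.params[2], abs=1e-3)
        assert fit.gamma[0] == pytest.approx(ref.params[0], abs=1e-3)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-4)

    def test_row_permutation_invariant(self):
        y, X, Z = _zip_data(seed=6)
        rng = np.random.default_rng(7)
        perm = rng.permutation(y.size)
        f1 = fit_zip(y, X, Z)
        f2 = fit_zip(y[perm], X[perm], Z[perm])
        assert np.allclose(f1.beta, f2.beta, atol=1e-6)
        assert np.allclose(f1.gamma, f2.gamma, atol=1e-6)

    def test_no_zeros_triggers_advisory(self):
        rng = np.random.default_rng(8)
        n = 200
        X = np.ones((n, 1))
        y = rng.poisson(5.0, size=n) + 1.0
        with pytest.warns(UserWarning, match="Poisson"):
            fit_zip(y, X)

    def test_loglik_below_saturated_poisson_bound(self):
        from scipy.stats import poisson

        y, X, Z = _zip_data(seed=9)
        fit = fit_zip(y, X, Z)
        saturated = poisson.logpmf(y, np.clip(y, 1e-12, None)).sum()
        assert fit.loglik <= saturated


class TestStratified:
    def test_male_only_effect_pattern(self, small_cohort):
        sim = small_cohort
        causal = sim.truth["causal_snps"]["GENE01"][0]
        from hwukit.qc import impute_missing_mean

        G = impute_missing_mean(sim.genotype)
        fits = stratified_snp_effects(G, sim.cohort, causal)
        by = {f.stratum: f for f in fits}
        assert set(by) == {"male", "female"}
        # male-only liability effect: male dosage coefficient larger in magnitude
        assert abs(by["male"].beta[1]) > abs(by["female"].beta[1])
        assert by["male"].wald_p_beta[1] < 0.05

    def test_gender_alias_in_covariates_rejected(self, small_cohort):
        sim = small_cohort
        from hwukit.qc import impute_missing_mean

        G = impute_missing_mean(sim.genotype)
        gender_col = sim.cohort.gender[:, None]
        with pytest.raises(ValidationError, match="gender"):
            stratified_snp_effects(G, sim.cohort, G.variant_ids[0],
                                   covariates=gender_col)

    def test_small_stratum_skipped_with_warning(self, small_cohort):
        sim = small_cohort
        from hwukit.qc import impute_missing_mean

        G = impute_missing_mean(sim.genotype)
        with pytest.warns(UserWarning, match="skipped"):
            fits = stratified_snp_effects(G, sim.cohort, G.variant_ids[0],
                                          min_stratum_n=10_000)
        assert fits == []
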