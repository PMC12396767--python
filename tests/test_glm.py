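import numpy as np
import pytest
from scipy import stats

from latentgxe.glm import FitResult, fit_binary_glm, wald_test
from latentgxe.model import (
    SnpAssociationModel,
    additive_test,
    conditional_nonadditive_test,
    interaction_test,
    joint_test,
    nonadditive_test,
)


def _simulate(rng, n=4000, maf=0.3, betaG=0.4, betaD=0.0, link="logit",
              beta0=-1.0):
    g = rng.binomial(2, maf, n).astype(float)
    het = (g == 1).astype(float)
    eta = beta0 + betaG * g + betaD * het
    cdf = stats.logistic.cdf if link == "logit" else stats.norm.cdf
    y = (rng.random(n) < cdf(eta)).astype(float)
    return y, g


class TestFitBinaryGlm:
    def test_balanced_intercept_is_zero(self):
        y = np.r_[np.ones(50), np.zeros(50)]
        fit = fit_binary_glm(y, np.ones((100, 1)), link="logit")
        assert fit.params[0] == pytest.approx(0.0, abs=1e-10)

    def test_intercept_is_logit_of_prevalence(self):
        y = np.r_[np.ones(121), np.zeros(879)]
        fit = fit_binary_glm(y, np.ones((1000, 1)), link="logit")
        assert fit.params[0] == pytest.approx(np.log(0.121 / 0.879), abs=1e-8)

    def test_saturated_fit_reproduces_class_rates(self, class_data):
        y, g = class_data([400, 300, 100], [60, 90, 40])
        res = SnpAssociationModel(y, g).fit()
        X, _ = res.model._design_full()
        eta = X @ res.fit_full.params
        mu = 1.0 / (1.0 + np.exp(-eta))
        for k, rate in zip(range(3), [60 / 400, 90 / 300, 40 / 100]):
            assert np.allclose(mu[g == k], rate, atol=1e-10)

    @pytest.mark.parametrize("link", ["logit", "probit"])
    def test_agrees_with_statsmodels(self, link, rng):
        import statsmodels.api as sm

        y, g = _simulate(rng, link=link)
        cov = rng.standard_normal((y.size, 2))
        X = np.column_stack([np.ones(y.size), g, (g == 1).astype(float), cov])
        fit = fit_binary_glm(y, X, link=link)
        family = sm.families.Binomial(
            sm.families.links.Logit() if link == "logit"
            else sm.families.links.Probit()
        )
        ref = sm.GLM(y, X, family=family).fit()
        assert fit.params == pytest.approx(ref.params, abs=1e-6)
        assert fit.llf == pytest.approx(ref.llf, abs=1e-6)
        # covariances agree (identically for the canonical logit link;
        # to asymptotic accuracy for probit where observed != expected)
        tol = 1e-6 if link == "logit" else 0.05
        assert fit.bse == pytest.approx(ref.bse, rel=tol)

    def test_separation_detected(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        y = x.copy()
        X = np.column_stack([np.ones(40), x])
        fit = fit_binary_glm(y, X)
        assert fit.status == "separated"
        assert np.isnan(fit.params).all()

    def test_rank_deficiency_names_column(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(50)
        y = (rng.random(50) < 0.5).astype(float)
        X = np.column_stack([np.ones(50), x, 2.0 * x])
        fit = fit_binary_glm(y, X, names=["const", "x", "x_dup"])
        assert fit.status == "inestimable"
        assert "rank deficient" in fit.message

    def test_single_class_outcome_inestimable(self):
        fit = fit_binary_glm(np.ones(30), np.ones((30, 1)))
        assert fit.status == "inestimable"


class TestWald:
    def test_zero_coefficient_gives_zero_statistic(self):
        fit = FitResult(
            params=np.array([0.5, 0.0]),
            information=np.eye(2), cov_params=np.eye(2),
            llf=0.0, converged=True, status="ok", n=10, link="logit",
            names=["a", "b"],
        )
        res = wald_test(fit, [[0.0, 1.0]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_one_df_equals_z_squared(self, rng):
        y, g = _simulate(rng)
        res = SnpAssociationModel(y, g).fit()
        t = res.nonadditive_test()
        j = res.fit_full.names.index("G_D")
        z = res.fit_full.params[j] / res.fit_full.bse[j]
        assert t.statistic == pytest.approx(z * z, rel=1e-12)

    def test_block_diagonal_joint_is_sum_of_marginals(self):
        # constructed fit with exactly block-diagonal covariance
        cov = np.diag([0.1, 0.04, 0.09])
        fit = FitResult(
            params=np.array([-1.0, 0.3, 0.2]),
            information=np.linalg.inv(cov), cov_params=cov,
            llf=0.0, converged=True, status="ok", n=100, link="logit",
            names=["const", "G_A", "G_D"],
        )
        t_a = wald_test(fit, [[0, 1, 0]]).statistic
        t_d = wald_test(fit, [[0, 0, 1]]).statistic
        t_joint = wald_test(fit, [[0, 1, 0], [0, 0, 1]]).statistic
        assert t_joint == pytest.approx(t_a + t_d, rel=1e-12)

    def test_dependent_constraints_rejected(self, rng):
        y, g = _simulate(rng, n=500)
        res = SnpAssociationModel(y, g).fit()
        out = wald_test(res.fit_full, [[0, 1, 0], [0, 2, 0]])
        assert out.status == "inestimable"


class TestEncodingInvariance:
    """Dominance and joint statistics are invariant to the saturated
    parameterization (Fisher-orthogonal, over-dominance, genotypic)."""

    @pytest.mark.parametrize("betaD", [0.0, 0.4])
    def test_statistics_match(self, betaD, rng):
        y, g = _simulate(rng, n=2500, betaD=betaD)
        stats_ = {}
        for scheme in ("fisher_orthogonal", "overdominance", "genotypic"):
            res = SnpAssociationModel(y, g, scheme=scheme).fit()
            stats_[scheme] = (
                res.nonadditive_test().statistic,
                res.joint_test().statistic,
            )
        base = stats_["fisher_orthogonal"]
        for scheme in ("overdominance", "genotypic"):
            assert stats_[scheme][0] == pytest.approx(base[0], rel=1e-10)
            assert stats_[scheme][1] == pytest.approx(base[1], rel=1e-10)


class TestWaldLrtAgreement:
    def test_dominance_wald_close_to_lrt_under_null(self, rng):
        for _ in range(5):
            y, g = _simulate(rng, n=20_000, betaD=0.0)
            res = SnpAssociationModel(y, g).fit()
            wald = res.nonadditive_test().statistic
            lrt = 2.0 * (res.fit_full.llf - res.fit_additive.llf)
            assert abs(wald - lrt) < 0.5


class TestTestWrappers:
    def test_null_dominance_large_p(self, class_data):
        # class case rates in exact arithmetic progression on the logit scale
        mu = stats.logistic.cdf([-1.0, -0.5, 0.0])
        totals = np.array([98000, 42000, 9000]) // 10
        cases = np.round(totals * mu).astype(int)
        y, g = class_data(totals, cases)
        res = nonadditive_test(y, g)
        assert res.p_value > 0.4

    def test_joint_fallback_with_two_classes(self, rng):
        g = rng.binomial(1, 0.3, 800).astype(float)  # classes 0/1 only
        y = (rng.random(800) < 0.3).astype(float)
        res = joint_test(y, g)
        assert res.status == "additive_fallback"
        assert res.df == 1 and np.isfinite(res.p_value)
        dom = nonadditive_test(y, g)
        assert dom.status == "inestimable"

    def test_additive_test_matches_score_test_asymptotically(self, rng):
        import statsmodels.api as sm

        y, g = _simulate(rng, n=50_000, betaG=0.1)
        wald = additive_test(y, g)
        X0 = np.ones((y.size, 1))
        fit0 = sm.GLM(y, X0, family=sm.families.Binomial()).fit()
        mu0 = fit0.fittedvalues
        # score test of adding g to the intercept-only model
        X = np.column_stack([np.ones(y.size), g])
        score = X.T @ (y - mu0)
        info = (X * (mu0 * (1 - mu0))[:, None]).T @ X
        t_score = float(score @ np.linalg.solve(info, score))
        assert abs(wald.statistic - t_score) < 0.5

    def test_interaction_symmetry(self, rng):
        n = 3000
        g1 = rng.binomial(2, 0.3, n).astype(float)
        g2 = rng.binomial(2, 0.4, n).astype(float)
        y = (rng.random(n) < stats.logistic.cdf(-1 + 0.2 * g1 * g2)).astype(float)
        a = interaction_test(y, g1, g2)
        b = interaction_test(y, g2, g1)
        assert a.statistic == pytest.approx(b.statistic, rel=1e-10)

    def test_interaction_recovers_planted_effect(self, rng):
        n = 50_000
        beta_ge = 0.15
        g1 = rng.binomial(2, 0.3, n).astype(float)
        g2 = rng.binomial(2, 0.4, n).astype(float)
        eta = -1.0 + 0.1 * g1 + 0.1 * g2 + beta_ge * g1 * g2
        y = (rng.random(n) < stats.logistic.cdf(eta)).astype(float)
        res = interaction_test(y, g1, g2)
        assert abs(res.estimates[0] - beta_ge) < 2.0 * res.stderrs[0]

    def test_interaction_monomorphic_inestimable(self, rng):
        n = 200
        g1 = np.zeros(n)
        g2 = rng.binomial(2, 0.3, n).astype(float)
        y = (rng.random(n) < 0.4).astype(float)
        assert interaction_test(y, g1, g2).status == "inestimable"

    def test_conditional_test_attenuates_induced_dominance(self, rng):
        # candidate's dominance arises purely from interaction with the index
        n = 30_000
        g = rng.binomial(2, 0.3, n).astype(float)
        idx = rng.binomial(2, 0.3, n).astype(float)
        eta = -1.0 + 0.4 * g * idx
        y = (rng.random(n) < stats.logistic.cdf(eta)).astype(float)
        base, adj = conditional_nonadditive_test(y, g, idx)
        assert base.status == adj.status == "ok"
        assert abs(adj.estimates[0]) < abs(base.estimates[0])

    def test_conditional_test_keeps_biological_dominance(self, rng):
        # planted pure dominance, independent index: no systematic shrinkage
        n = 30_000
        g = rng.binomial(2, 0.3, n).astype(float)
        idx = rng.binomial(2, 0.3, n).astype(float)
        eta = -1.0 + 0.3 * (g == 1)
        y = (rng.random(n) < stats.logistic.cdf(eta)).astype(float)
        base, adj = conditional_nonadditive_test(y, g, idx)
        assert abs(adj.estimates[0]) > 0.5 * abs(base.estimates[0])

    def test_missing_dropped_and_counted(self, rng):
        y, g = _simulate(rng, n=500)
        g[:25] = np.nan
        model = SnpAssociationModel(y, g)
        assert model.n_dropped == 25
        assert model.y.size == 475

    def test_summary_renders(self, rng):
        y, g = _simulate(rng, n=800)
        text = SnpAssociationModel(y, g).fit().summary()
        assert "non-additive" in text and "joint" in text
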