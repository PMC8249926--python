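import numpy as np
import pytest
from scipy import stats as sps
from scipy.optimize import minimize

from wchc.comparators import (
    _shom_prefix_stats,
    manova_test,
    multiphen_test,
    obrien_test,
    shet_test,
    tates_test,
    univariate_stats,
)
from wchc.simulate import model_config, simulate_dataset

from conftest import random_polymorphic_genotype


def random_corr(rng, m):
    a = rng.standard_normal((m, m + 3))
    c = np.corrcoef(a)
    return c


class TestUnivariateStats:
    def test_null_statistics_are_standard_normal(self):
        rng = np.random.default_rng(0)
        zs = []
        for _ in range(400):
            g = rng.binomial(2, 0.3, size=300)
            y = rng.standard_normal((300, 1))
            zs.append(univariate_stats(g, y).t[0])
        zs = np.asarray(zs)
        assert abs(zs.mean()) <= 0.1
        assert zs.std() == pytest.approx(1.0, abs=0.1)

    def test_perfect_fit_is_capped_not_infinite(self, rng):
        g = random_polymorphic_genotype(rng, 30)
        us = univariate_stats(g, g[:, None].astype(float))
        assert np.isfinite(us.t).all()
        assert abs(us.t[0]) >= 1e6

    def test_duplicated_phenotypes_give_unit_correlation(self, rng):
        g = random_polymorphic_genotype(rng, 30)
        y = rng.standard_normal(30)
        us = univariate_stats(g, np.column_stack([y, y]))
        assert us.Corr[0, 1] == pytest.approx(1.0)


class TestOBrien:
    def test_identity_covariance_equal_stats(self, rng):
        g = random_polymorphic_genotype(rng, 30)
        us = univariate_stats(g, rng.standard_normal((30, 4)))
        t0 = 1.3
        us.t = np.full(4, t0)
        us.Sigma = np.eye(4)
        z, p = obrien_test(us)
        assert z == pytest.approx(np.sqrt(4) * t0)

    def test_cancellation_gives_p_one(self, rng):
        g = random_polymorphic_genotype(rng, 30)
        us = univariate_stats(g, rng.standard_normal((30, 4)))
        us.t = np.array([2.0, -2.0, 1.0, -1.0])
        us.Sigma = np.eye(4)
        z, p = obrien_test(us)
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_explicit_solve_oracle(self, rng):
        g = random_polymorphic_genotype(rng, 50)
        us = univariate_stats(g, rng.standard_normal((50, 3)))
        us.t = rng.standard_normal(3)
        us.Sigma = random_corr(rng, 3)
        z, _ = obrien_test(us)
        inv = np.linalg.inv(us.Sigma)
        ones = np.ones(3)
        expect = (ones @ inv @ us.t) / np.sqrt(ones @ inv @ ones)
        assert z == pytest.approx(expect, abs=1e-10)

    def test_global_sign_flip_invariance(self, rng):
        # flipping every statistic's sign (counting the other allele) leaves
        # |z| unchanged; OB is deliberately sensitive to per-phenotype flips
        g = random_polymorphic_genotype(rng, 50)
        us = univariate_stats(g, rng.standard_normal((50, 3)))
        us.t = rng.standard_normal(3)
        us.Sigma = random_corr(rng, 3)
        z1, p1 = obrien_test(us)
        us.t = -us.t
        z2, p2 = obrien_test(us)
        assert abs(z1) == pytest.approx(abs(z2), abs=1e-10)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_singular_sigma_raises(self, rng):
        g = random_polymorphic_genotype(rng, 30)
        y = rng.standard_normal(30)
        us = univariate_stats(g, np.column_stack([y, y]))
        with pytest.raises(ValueError, match="singular"):
            obrien_test(us)


def brute_force_shet(t, corr, w, thresholds):
    best = -np.inf
    for tau in thresholds:
        sel = np.flatnonzero(np.abs(t) > tau)
        if sel.size == 0:
            continue
        ts, cs = t[sel], corr[np.ix_(sel, sel)]
        ws = np.diag(np.diag(w)[sel])
        num = np.ones(sel.size) @ np.linalg.inv(cs @ ws) @ ts
        den = np.ones(sel.size) @ np.linalg.inv(ws @ cs @ ws) @ np.ones(sel.size)
        best = max(best, num**2 / den)
    return best


class TestSHet:
    def test_formula_reduction_identity_corr(self, rng):
        g = random_polymorphic_genotype(rng, 40)
        us = univariate_stats(g, rng.standard_normal((40, 3)))
        us.t = np.array([1.0, 2.0, -0.5])
        us.Corr = np.eye(3)
        s, _ = shet_test(us, thresholds=[0.0], n_mc=10, seed=0)
        assert s == pytest.approx((us.t.sum()) ** 2 / 3)

    def test_max_rule_dominates_single_threshold(self, rng):
        g = random_polymorphic_genotype(rng, 40)
        us = univariate_stats(g, rng.standard_normal((40, 3)))
        us.t = np.array([3.0, 0.1, 0.1])
        us.Corr = np.eye(3)
        s_grid, _ = shet_test(us, thresholds=[0.0, 1.0], n_mc=10, seed=0)
        s_zero, _ = shet_test(us, thresholds=[0.0], n_mc=10, seed=0)
        assert s_grid >= s_zero

    def test_prefix_machinery_matches_brute_force(self, rng):
        for _ in range(10):
            m = int(rng.integers(2, 7))
            corr = random_corr(rng, m)
            t = rng.standard_normal(m)
            w = np.eye(m)
            thresholds = np.concatenate([[0.0], np.unique(np.abs(t))])
            g = random_polymorphic_genotype(rng, 40)
            us = univariate_stats(g, rng.standard_normal((40, m)))
            us.t, us.Corr, us.W = t, corr, w
            s, _ = shet_test(us, thresholds=thresholds, n_mc=10, seed=0)
            assert s == pytest.approx(
                brute_force_shet(t, corr, w, thresholds), rel=1e-8
            )

    def test_nonidentity_weights_match_brute_force(self, rng):
        m = 4
        corr = random_corr(rng, m)
        t = rng.standard_normal(m)
        w = np.diag(rng.uniform(0.5, 2.0, size=m))
        g = random_polymorphic_genotype(rng, 40)
        us = univariate_stats(g, rng.standard_normal((40, m)))
        us.t, us.Corr, us.W = t, corr, w
        thresholds = np.concatenate([[0.0], np.unique(np.abs(t))])
        s, _ = shet_test(us, thresholds=thresholds, n_mc=10, seed=0)
        assert s == pytest.approx(brute_force_shet(t, corr, w, thresholds), rel=1e-8)

    def test_mc_pvalue_reproducible(self, null_dataset):
        g, y = null_dataset
        us = univariate_stats(g, y)
        _, p1 = shet_test(us, n_mc=500, seed=4)
        _, p2 = shet_test(us, n_mc=500, seed=4)
        assert p1 == p2
        assert 0 <= p1 <= 1


class TestTATES:
    def test_simes_reduction_hand_computed(self):
        # independent phenotypes: min(2*0.02/1, 2*0.80/2) = 0.04
        p = tates_test(np.array([0.02, 0.80]), np.eye(2))
        assert p == pytest.approx(0.04)

    def test_simes_reduction_general(self, rng):
        p = np.sort(rng.uniform(0.001, 1, size=5))
        got = tates_test(p, np.eye(5))
        simes = min(5 * p[j] / (j + 1) for j in range(5))
        assert got == pytest.approx(simes, rel=1e-10)

    def test_single_phenotype_passthrough(self):
        assert tates_test(np.array([0.3]), np.eye(1)) == pytest.approx(0.3)

    def test_rank_one_limit_duplicated_phenotypes(self):
        corr = np.full((4, 4), 0.9999)
        np.fill_diagonal(corr, 1.0)
        p = np.array([0.04, 0.041, 0.042, 0.043])
        got = tates_test(p, corr)
        # the published polynomial maps r=1 to ~0.98, not exactly 1, so the
        # effective number in the duplicate limit is ~1.06 rather than 1
        assert got == pytest.approx(p.min(), rel=0.10)
        assert got < 2 * p.min()  # far from the Simes value M * min p

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            tates_test(np.array([0.0, 0.5]), np.eye(2))

    def test_polynomial_matches_empirical_pvalue_correlation(self):
        # the mapping r -> corr(p_i, p_j) must agree with the correlation of
        # two-sided p-values of correlated null z-scores
        from wchc.comparators import _TATES_POLY

        rng = np.random.default_rng(3)
        for r in (0.2, 0.5, 0.8):
            L = np.linalg.cholesky([[1, r], [r, 1]])
            z = rng.standard_normal((200_000, 2)) @ L.T
            p = 2 * sps.norm.sf(np.abs(z))
            emp = np.corrcoef(p, rowvar=False)[0, 1]
            assert np.polyval(_TATES_POLY, r) == pytest.approx(emp, abs=0.02)


class TestMANOVA:
    def test_univariate_reduction_matches_f_test(self, rng):
        g = random_polymorphic_genotype(rng, 100)
        y = 0.2 * g + rng.standard_normal(100)
        _, p = manova_test(g, y[:, None])
        lin = sps.linregress(g.astype(float), y)
        assert p == pytest.approx(lin.pvalue, abs=1e-10)

    def test_matches_statsmodels_manova(self, rng):
        from statsmodels.multivariate.manova import MANOVA

        g = random_polymorphic_genotype(rng, 80).astype(float)
        y = rng.standard_normal((80, 3)) + 0.3 * g[:, None]
        lam, p = manova_test(g, y)
        x = np.column_stack([np.ones(80), g])
        mv = MANOVA(y, x)
        tab = mv.mv_test([("g", np.array([[0.0, 1.0]]))]).results["g"]["stat"]
        assert lam == pytest.approx(tab.loc["Wilks' lambda", "Value"], abs=1e-8)
        assert p == pytest.approx(tab.loc["Wilks' lambda", "Pr > F"], abs=1e-8)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(5)
        ps = []
        for _ in range(2000):
            g = rng.binomial(2, 0.3, size=60)
            if g.min() == g.max():
                continue
            ps.append(manova_test(g, rng.standard_normal((60, 3)))[1])
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_duplicated_phenotype_is_error_not_crash(self, rng):
        g = random_polymorphic_genotype(rng, 50)
        y = rng.standard_normal(50)
        with pytest.raises(ValueError, match="singular"):
            manova_test(g, np.column_stack([y, y]))


def hand_rolled_ordinal_lrt(g, y):
    """Independent proportional-odds fit by direct likelihood maximisation."""
    y = y.ravel()
    levels, inv = np.unique(g, return_inverse=True)
    ncat = levels.size
    n = g.size

    def negll(params):
        cuts = np.concatenate([[-np.inf], np.cumsum(
            np.concatenate([[params[0]], np.exp(params[1 : ncat - 1])])
        ), [np.inf]])
        xb = y * params[-1]
        upper = sps.logistic.cdf(cuts[inv + 1] - xb)
        lower = sps.logistic.cdf(cuts[inv] - xb)
        return -np.sum(np.log(np.clip(upper - lower, 1e-300, None)))

    x0 = np.concatenate([[-1.0], np.zeros(ncat - 2), [0.0]])
    res = minimize(negll, x0, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
    freqs = np.bincount(inv) / n
    llf0 = np.sum(np.bincount(inv) * np.log(freqs))
    return 2 * (-res.fun - llf0)


class TestMultiPhen:
    def test_single_predictor_matches_hand_rolled_fit(self, rng):
        g = random_polymorphic_genotype(rng, 120)
        y = 0.3 * g + rng.standard_normal(120)
        lrt, p = multiphen_test(g, y[:, None])
        expect = hand_rolled_ordinal_lrt(g, y)
        assert lrt == pytest.approx(expect, abs=1e-5)

    def test_two_level_genotype_reduces_to_binary_logistic(self, rng):
        import statsmodels.api as sm

        g = rng.binomial(1, 0.4, size=150)
        g[:2] = [0, 1]
        y = 0.4 * g + rng.standard_normal(150)
        lrt, p = multiphen_test(g, y[:, None])
        logit = sm.Logit(g, sm.add_constant(y)).fit(disp=False)
        expect = 2 * (logit.llf - logit.llnull)
        assert lrt == pytest.approx(expect, abs=1e-5)

    def test_null_lrt_has_chi2_mean(self):
        # mean of a chi^2_M is M; check the LRT's first moment under the null
        rng = np.random.default_rng(21)
        m, reps = 3, 250
        lrts = []
        for _ in range(reps):
            g = rng.binomial(2, 0.3, size=250)
            if g.min() == g.max():
                continue
            lrt, _ = multiphen_test(g, rng.standard_normal((250, m)))
            if np.isfinite(lrt):
                lrts.append(lrt)
        se = np.sqrt(2 * m / len(lrts))
        assert np.mean(lrts) == pytest.approx(m, abs=3 * se)

    def test_monomorphic_rejected(self, rng):
        with pytest.raises(ValueError, match="monomorphic"):
            multiphen_test(np.zeros(50, dtype=int), rng.standard_normal((50, 2)))
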