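"""PGLS regression, Bartlett variance tests, disparity indices."""

import warnings

import numpy as np
import pandas as pd
import pytest

from termevol import (
    PGLS,
    Phylogeny,
    bartlett_test,
    caste_correlation,
    disparity,
    intercept_tests,
    pgls_best,
    simulate_trait,
)
from termevol.pgls import PhylogenyIgnoredWarning

from conftest import random_tree

pytestmark = pytest.mark.filterwarnings("ignore::UserWarning")


def gls_whole_matrix_oracle(y, X, V):
    """Textbook GLS with explicit inverses (brute force)."""
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    r = y - X @ beta
    n, p = X.shape
    s2 = (r @ Vi @ r) / (n - p)
    se = np.sqrt(np.diag(s2 * np.linalg.inv(X.T @ Vi @ X)))
    return beta, se


class TestDisparity:
    @pytest.mark.parametrize("a, b, expected", [(2.0, 1.0, 1.0), (1.5, 1.5, 0.0),
                                                (2.6, 1.2, 7 / 6)])
    def test_values(self, a, b, expected):
        assert disparity(a, b) == pytest.approx(expected)

    def test_sign_tracks_which_caste_is_larger(self):
        assert disparity(2.0, 1.5) > 0 > disparity(1.5, 2.0)

    def test_more_than_double_exceeds_one(self):
        # Microtermes-like: imago more than twice the worker width
        assert disparity(2.1, 1.0) > 1.0

    def test_positive_inputs_required(self):
        with pytest.raises(ValueError):
            disparity(-1.0, 1.0)


class TestBartlett:
    def test_identical_groups_give_zero(self):
        g = [1.0, 2.0, 3.0, 4.0]
        K, df, p = bartlett_test(g, list(g))
        assert K == pytest.approx(0.0, abs=1e-12)
        assert df == 1 and p == pytest.approx(1.0)

    def test_hand_evaluated_formula(self):
        """Two groups, n=10 each, sample variances exactly 1 and 4 -> K ~ 3.805."""
        base = np.arange(10, dtype=float)
        g1 = base / base.std(ddof=1)  # sample variance 1
        g2 = 2.0 * g1  # sample variance 4
        K, df, p = bartlett_test(g1, g2)
        # independent hand evaluation of the statistic
        n1 = n2 = 10
        sp2 = ((n1 - 1) * 1.0 + (n2 - 1) * 4.0) / (n1 + n2 - 2)
        num = (n1 + n2 - 2) * np.log(sp2) - 9 * np.log(1.0) - 9 * np.log(4.0)
        corr = 1 + (1 / 9 + 1 / 9 - 1 / 18) / 3
        assert K == pytest.approx(num / corr, rel=1e-10)
        assert K == pytest.approx(3.805, abs=5e-3)
        assert df == 1

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=12), rng.normal(size=15) * 2
        K1, _, _ = bartlett_test(a, b)
        K2, _, _ = bartlett_test(a * 7.3, b * 7.3)
        assert K1 == pytest.approx(K2)

    def test_zero_variance_flagged_infinite(self):
        K, df, p = bartlett_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isinf(K) and p == 0.0

    def test_warns_about_phylogeny(self):
        with pytest.warns(PhylogenyIgnoredWarning):
            warnings.simplefilter("always")
            bartlett_test([1.0, 2.0], [3.0, 4.0])


class TestPGLS:
    def test_identity_covariance_reproduces_ols(self):
        """On a star tree the GLS projection is exactly OLS (coefs, t, F)."""
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        n = 20
        star = Phylogeny.from_newick(
            "(" + ",".join(f"t{i}:1" for i in range(n)) + ");"
        )
        x = rng.standard_normal(n)
        y = 0.5 + 0.8 * x + rng.standard_normal(n) * 0.3
        fit = PGLS(y, x[:, None], star, transform="BM").fit()
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        np.testing.assert_allclose(fit.params, ols.params, atol=1e-10)
        np.testing.assert_allclose(fit.bse, ols.bse, atol=1e-10)
        np.testing.assert_allclose(fit.tvalues, ols.tvalues, atol=1e-8)
        assert fit.fvalue == pytest.approx(ols.fvalue, abs=1e-8)
        assert fit.f_pvalue == pytest.approx(ols.f_pvalue, abs=1e-10)

    def test_lambda_one_equals_bm(self):
        t = random_tree(2, n_extant=10)
        rng = np.random.default_rng(2)
        x = rng.standard_normal(t.n_tips)
        y = simulate_trait(t, "BM", {"sigma2": 0.3, "z0": 0.0}, rng=rng) + 0.4 * x
        bm = PGLS(y, x[:, None], t, transform="BM").fit()
        lam = PGLS(y, x[:, None], t, transform="lambda").fit(fixed_param=1.0)
        np.testing.assert_allclose(lam.params, bm.params, atol=1e-10)
        assert lam.loglik == pytest.approx(bm.loglik, abs=1e-10)

    @pytest.mark.parametrize("transform, param", [("lambda", 0.6), ("kappa", 0.4),
                                                  ("delta", 1.7)])
    def test_matches_whole_matrix_gls_oracle(self, transform, param):
        t = random_tree(7, n_extant=8)
        rng = np.random.default_rng(7)
        x = rng.standard_normal(t.n_tips)
        y = rng.standard_normal(t.n_tips)
        fit = PGLS(y, x[:, None], t, transform=transform).fit(fixed_param=param)
        model = PGLS(y, x[:, None], t, transform=transform)
        V = model._V0(param)
        beta, se = gls_whole_matrix_oracle(y, model.X, V)
        np.testing.assert_allclose(fit.params, beta, atol=1e-8)
        np.testing.assert_allclose(fit.bse, se, atol=1e-8)

    def test_best_transform_lambda_aic_bounded_by_bm(self):
        """lambda nests BM, so its AIC can exceed BM's only by the 2-unit
        parameter penalty."""
        for seed in range(5):
            t = random_tree(seed, n_extant=12)
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(t.n_tips)
            y = simulate_trait(t, "BM", {"sigma2": 0.2, "z0": 0.0}, rng=rng)
            bm = PGLS(y, x[:, None], t, transform="BM").fit()
            lam = PGLS(y, x[:, None], t, transform="lambda").fit()
            assert lam.aic <= bm.aic + 2.0 + 1e-6

    def test_best_fit_tie_goes_to_bm(self):
        # on a star tree every transform is equivalent -> BM chosen
        star = Phylogeny.from_newick("(A:1,B:1,C:1,D:1,E:1,F:1);")
        rng = np.random.default_rng(1)
        x = rng.standard_normal(6)
        y = rng.standard_normal(6)
        fit = pgls_best(y, x[:, None], star)
        assert fit.comparison is not None
        near = fit.comparison[
            fit.comparison["AIC"] <= fit.comparison["AIC"].min() + 1e-9
        ]
        if "BM" in set(near["transform"]):
            assert fit.transform == "BM"

    def test_slope_recovery_on_lambda_zero_structure(self):
        """Star-structured residuals: slope estimates unbiased over reps."""
        star = Phylogeny.from_newick(
            "(" + ",".join(f"t{i}:1" for i in range(40)) + ");"
        )
        rng = np.random.default_rng(10)
        slopes = []
        for _ in range(50):
            x = rng.standard_normal(40)
            y = 1.0 + 0.5 * x + rng.standard_normal(40) * 0.5
            slopes.append(pgls_best(y, x[:, None], star).params[1])
        assert np.mean(slopes) == pytest.approx(0.5, abs=0.05)


class TestInterceptTests:
    def test_zero_response_zero_t(self):
        t = random_tree(3, n_extant=10, retention=0.0)
        groups = pd.Series(
            ["a" if i % 2 else "b" for i in range(t.n_tips)],
            index=t.tip_labels,
        )
        out = intercept_tests(np.zeros(t.n_tips), groups, t)
        assert np.allclose(out["t"], 0.0, atol=1e-6)

    def test_baseline_swap_reparameterization(self):
        """Level means agree whichever level is the baseline."""
        t = random_tree(4, n_extant=12, retention=0.0)
        rng = np.random.default_rng(4)
        groups = pd.Series(
            rng.permutation(["a"] * 6 + ["b"] * (t.n_tips - 6)),
            index=t.tip_labels,
        )
        y = np.where(groups == "a", 0.3, -0.2) + rng.standard_normal(t.n_tips) * 0.1
        out = intercept_tests(y, groups, t)
        assert set(out.index) == {"a", "b"}
        # each level's intercept approximates its group mean shift
        assert out.loc["a", "intercept"] == pytest.approx(0.3, abs=0.15)
        assert out.loc["b", "intercept"] == pytest.approx(-0.2, abs=0.15)

    def test_shifted_level_detected(self):
        """A +0.5 shift at sigma=0.1 is significant for that level."""
        hits = 0
        for seed in range(10):
            t = random_tree(seed, n_extant=50, retention=0.0)
            rng = np.random.default_rng(seed + 500)
            groups = pd.Series(
                rng.permutation(["shift"] * 25 + ["null"] * (t.n_tips - 25)),
                index=t.tip_labels,
            )
            y = np.where(groups == "shift", 0.5, 0.0) + rng.normal(
                0, 0.1, t.n_tips
            )
            out = intercept_tests(y, groups, t)
            hits += out.loc["shift", "p"] < 0.01
        assert hits >= 9

    def test_single_level_rejected(self):
        t = random_tree(5, n_extant=6)
        groups = pd.Series(["a"] * t.n_tips, index=t.tip_labels)
        with pytest.raises(ValueError):
            intercept_tests(np.zeros(t.n_tips), groups, t)


class TestCasteCorrelation:
    def _records(self, tree, f):
        rows = []
        rng = np.random.default_rng(0)
        for label in tree.tip_labels:
            im = float(np.exp(rng.normal(0.5, 0.4)))
            rows.append(dict(species=f"{label}_sp1", genus=label, family="F",
                             caste="imago", head_width_mm=im, status="modern"))
            rows.append(dict(species=f"{label}_sp1", genus=label, family="F",
                             caste="soldier", head_width_mm=f(im),
                             status="modern"))
        return pd.DataFrame(rows)

    def test_identical_castes_slope_one(self):
        t = random_tree(6, n_extant=12, retention=0.0)
        fit = caste_correlation(self._records(t, lambda im: im), "imago",
                                "soldier", t)
        assert fit.params[1] == pytest.approx(1.0, abs=1e-6)
        assert fit.params[0] == pytest.approx(0.0, abs=1e-6)

    def test_power_law_slope_two(self):
        # soldier = imago^2 in mm means slope 2 on the ln scale
        t = random_tree(6, n_extant=12, retention=0.0)
        fit = caste_correlation(self._records(t, lambda im: im**2), "imago",
                                "soldier", t)
        assert fit.params[1] == pytest.approx(2.0, abs=1e-6)

    def test_independent_traits_nonsignificant_at_nominal_rate(self):
        rejections = 0
        n_rep = 40
        for seed in range(n_rep):
            t = random_tree(seed, n_extant=15, retention=0.0)
            rngA = np.random.default_rng(seed * 2 + 1)
            rows = []
            for label in t.tip_labels:
                rows.append(dict(species=f"{label}_s", genus=label, family="F",
                                 caste="imago",
                                 head_width_mm=float(np.exp(rngA.normal(0, 0.3))),
                                 status="modern"))
                rows.append(dict(species=f"{label}_s", genus=label, family="F",
                                 caste="worker",
                                 head_width_mm=float(np.exp(rngA.normal(0, 0.3))),
                                 status="modern"))
            fit = caste_correlation(pd.DataFrame(rows), "imago", "worker", t)
            rejections += fit.pvalues[1] < 0.05
        assert rejections <= 0.20 * n_rep
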