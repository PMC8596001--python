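"""ML fitting, AICc comparison, and the genus-subsampling pipeline."""

import numpy as np
import pandas as pd
import pytest

from termevol import (
    ContinuousTraitModel,
    Phylogeny,
    aicc,
    akaike_weights,
    fit_all_models,
    replicate_fit,
    simulate_trait,
)
from termevol.fitting import ConfoundedModelError
from termevol.tree import paint_clade

from conftest import random_tree


class TestInformationCriteriaProperties:
    """Structural invariants of the AICc/weight arithmetic."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        st.lists(st.floats(-500, 500), min_size=1, max_size=8),
        st.floats(-100, 100),
    )
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_weights_sum_to_one_and_shift_invariant(self, values, shift):
        w = akaike_weights(values)
        assert w.sum() == pytest.approx(1.0)
        assert np.all(w >= 0)
        np.testing.assert_allclose(
            akaike_weights([v + shift for v in values]), w, atol=1e-9
        )

    @given(st.floats(-50, 50), st.integers(1, 5), st.integers(10, 500))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_aicc_exceeds_aic_and_penalizes_parameters(self, lnl, k, n):
        assert aicc(lnl, k, n) >= -2 * lnl + 2 * k
        if n > k + 2:
            assert aicc(lnl, k + 1, n) > aicc(lnl, k, n)


class TestInformationCriteria:
    def test_aicc_arithmetic(self):
        assert aicc(0.0, 2, 10) == pytest.approx(4 + 12 / 7)
        assert aicc(0.0, 0, 10) == 0.0
        # AICc -> AIC as n grows
        assert aicc(-5.0, 3, 10**7) == pytest.approx(10 + 6, abs=1e-4)
        with pytest.raises(ValueError):
            aicc(0.0, 3, 4)

    def test_akaike_weights(self):
        np.testing.assert_allclose(akaike_weights([10.0, 10.0]), [0.5, 0.5])
        w = akaike_weights([0.0, 2.0])
        np.testing.assert_allclose(w, [0.73106, 0.26894], atol=1e-5)
        np.testing.assert_allclose(akaike_weights([0.0, np.inf]), [1.0, 0.0])
        assert akaike_weights([3.0, 5.0, 9.0]).sum() == pytest.approx(1.0)
        with pytest.raises(ValueError):
            akaike_weights([np.inf, np.inf])


class TestSingleModelFits:
    def test_bm_two_tip_star_closed_form(self):
        # x = (0, 2) on branches of length 1: GLS root = 1,
        # sigma2_ML = mean squared deviation = 1
        t = Phylogeny.from_newick("(A:1,B:1);")
        fit = ContinuousTraitModel(t, [0.0, 2.0], model="BM").fit()
        assert fit.params["z0"] == pytest.approx(1.0)
        assert fit.params["sigma2"] == pytest.approx(1.0)
        assert fit.loglik == pytest.approx(-(np.log(2 * np.pi) + 1))
        assert fit.k == 2 and fit.n == 2

    @pytest.mark.parametrize("seed", range(4))
    def test_bm_optimum_beats_dense_grid(self, seed):
        """Optimizer lnL is never worse than a dense (sigma2, z0) grid."""
        t = random_tree(seed, n_extant=6)
        rng = np.random.default_rng(seed)
        x = simulate_trait(t, "BM", {"sigma2": 0.5, "z0": 1.0}, rng=rng)
        est = ContinuousTraitModel(t, x, model="BM")
        fit = est.fit()
        from termevol.models import model_mean_design_cov, mvn_loglik

        D, V0 = model_mean_design_cov("BM", t)
        best_grid = -np.inf
        for s2 in np.geomspace(0.05, 5.0, 40):
            for z0 in np.linspace(x.min(), x.max(), 40):
                best_grid = max(
                    best_grid, mvn_loglik(x, np.full(t.n_tips, z0), s2 * V0)
                )
        assert fit.loglik >= best_grid - 1e-4

    def test_lambda_ml_never_below_bm(self):
        """BM is the lambda=1 boundary point, so lambda's ML dominates."""
        for seed in range(6):
            t = random_tree(seed, n_extant=8)
            rng = np.random.default_rng(100 + seed)
            x = rng.standard_normal(t.n_tips)
            bm = ContinuousTraitModel(t, x, model="BM").fit()
            lam = ContinuousTraitModel(t, x, model="lambda").fit()
            assert lam.loglik >= bm.loglik - 1e-6

    def test_trend_confounded_on_ultrametric(self, cherry3):
        est = ContinuousTraitModel(cherry3, [0.1, 0.2, 0.3], model="trend")
        with pytest.raises(ConfoundedModelError):
            est.fit()
        fit = est.fit(on_confounded="reduce")
        bm = ContinuousTraitModel(cherry3, [0.1, 0.2, 0.3], model="BM").fit()
        assert fit.loglik == pytest.approx(bm.loglik, abs=1e-9)
        assert fit.params["mu"] == 0.0

    def test_kappa_recovers_speciational_change(self):
        """Data generated at kappa=0 yield small kappa estimates."""
        hits = 0
        for seed in range(10):
            t = random_tree(seed, n_extant=60, death=0.4)
            x = simulate_trait(
                t, "kappa", {"sigma2": 0.1, "z0": 0.0, "kappa": 0.0},
                rng=seed + 1,
            )
            fit = ContinuousTraitModel(t, x, model="kappa").fit()
            hits += fit.params["kappa"] < 0.2
        assert hits >= 8

    def test_seed_determinism(self):
        t = random_tree(11, n_extant=10)
        x = simulate_trait(t, "BM", {"sigma2": 0.2, "z0": 0.5}, rng=0)
        a = ContinuousTraitModel(t, x, model="delta").fit(seed=5)
        b = ContinuousTraitModel(t, x, model="delta").fit(seed=5)
        assert a.params == b.params and a.loglik == b.loglik


class TestComparison:
    def test_single_model_weight_one(self):
        t = random_tree(0, n_extant=6)
        x = simulate_trait(t, "BM", {"sigma2": 0.1, "z0": 0.0}, rng=0)
        comp = fit_all_models(t, x, model_set=["BM"])
        assert comp.weights["BM"] == pytest.approx(1.0)

    def test_trend_dropped_on_ultrametric_by_default(self):
        t = random_tree(0, n_extant=12, retention=0.0)
        assert t.is_ultrametric()
        x = simulate_trait(t, "BM", {"sigma2": 0.1, "z0": 0.0}, rng=0)
        comp = fit_all_models(t, x, model_set=["BM", "trend", "OU"])
        assert "trend" in comp.dropped and "trend" not in comp.fits

    def test_weights_sum_to_one_and_table_sorted(self):
        t = random_tree(1, n_extant=10)
        x = simulate_trait(t, "BM", {"sigma2": 0.1, "z0": 0.0}, rng=1)
        p = paint_clade(t, t.tip_labels[:2])
        comp = fit_all_models(t, x, painting=p)
        tab = comp.table()
        assert tab["weight"].sum() == pytest.approx(1.0)
        assert tab["AICc"].is_monotonic_increasing

    def test_bm_data_prefer_bm_over_any_single_k3_model(self):
        """The only k=2 model wins on average on data it generated."""
        weights = []
        for seed in range(20):
            t = random_tree(seed, n_extant=110, death=0.5)
            x = simulate_trait(t, "BM", {"sigma2": 0.1, "z0": 0.0}, rng=seed)
            comp = fit_all_models(
                t, x, model_set=["BM", "OU", "lambda", "kappa", "delta"]
            )
            weights.append(comp.weights)
        mean_w = pd.concat(weights, axis=1).mean(axis=1)
        assert mean_w["BM"] == mean_w.max()


class TestReplicatePipeline:
    @pytest.fixture
    def genus_setup(self):
        tree = random_tree(21, n_extant=15, death=0.4)
        rng = np.random.default_rng(21)
        x = simulate_trait(tree, "BM", {"sigma2": 0.05, "z0": 0.8}, rng=rng)
        rows = []
        for j, label in enumerate(tree.tip_labels):
            fossil = "_" in label
            n_sp = 1 if fossil else 3
            for s in range(n_sp):
                rows.append(dict(
                    species=label if fossil else f"{label}_sp{s+1}",
                    genus=label.split("_")[0], family="F", caste="imago",
                    head_width_mm=float(np.exp(x[j] + (0 if fossil else 0.1 * s))),
                    status="fossil" if fossil else "modern",
                ))
        return tree, pd.DataFrame(rows)

    def test_replicates_vary_and_summarize(self, genus_setup):
        tree, records = genus_setup
        out = replicate_fit(records, tree, n_rep=4, seed=0,
                            model_set=["BM", "OU"])
        assert out.table["replicate"].nunique() == 4
        s = out.summary()
        assert set(s.index) == {"BM", "OU"}
        # weights per replicate sum to one
        per_rep = out.table.groupby("replicate")["weight"].sum()
        np.testing.assert_allclose(per_rep, 1.0)

    def test_no_sampling_variation_when_one_species_per_genus(self, genus_setup):
        tree, records = genus_setup
        one_each = records.groupby(["genus"], as_index=False).first()
        out = replicate_fit(one_each, tree, n_rep=3, seed=1, model_set=["BM"])
        assert out.summary()["AICc_sd"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_single_replicate_sd_reported_zero(self, genus_setup):
        tree, records = genus_setup
        out = replicate_fit(records, tree, n_rep=1, seed=2, model_set=["BM"])
        assert out.summary()["AICc_sd"].iloc[0] == 0.0

    def test_identical_seeds_identical_summaries(self, genus_setup):
        tree, records = genus_setup
        a = replicate_fit(records, tree, n_rep=3, seed=9, model_set=["BM", "kappa"])
        b = replicate_fit(records, tree, n_rep=3, seed=9, model_set=["BM", "kappa"])
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_n_rep_zero_rejected(self, genus_setup):
        tree, records = genus_setup
        with pytest.raises(ValueError):
            replicate_fit(records, tree, n_rep=0, seed=0)
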