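"""Mixed models, bootstrap inference, variance partitioning, PCA, selection."""

import warnings

import numpy as np
import pandas as pd
import pytest

from woodfrac.lmm import RandomInterceptLMM
from woodfrac.stats import (MixedModelSpec, fit_mixed_model, group_ttest,
                            kruskal_within_species, parametric_bootstrap_p,
                            pca_summary, stepwise_backward_aic,
                            variance_partition, variance_partition_recovery)
from woodfrac.synthesis import LinkSpec, TraitSpec, generate_field_dataset


def _sim(beta=0.0, seed=0, s2_sp=0.5, s2_e=0.5):
    return generate_field_dataset(
        traits={"x": TraitSpec(0.0, 0.5, 0.5)},
        link=LinkSpec(predictor="x", response="y", alpha=0.0, beta=beta,
                      sigma2_species=s2_sp, sigma2_residual=s2_e,
                      positive=False),
        seed=seed)


FULL = MixedModelSpec(response="y", predictors=("x",))
NULL = FULL.with_predictors(())


class TestMixedModelEngine:
    def test_matches_statsmodels_mixedlm(self):
        """REML and ML fits agree with the general-purpose optimiser."""
        import statsmodels.formula.api as smf

        ds = _sim(beta=0.7, seed=4)
        df = ds.data.rename(columns={"species": "g"})
        for reml in (True, False):
            mine = fit_mixed_model(ds, FULL, reml=reml)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ref = smf.mixedlm("y ~ x", df, groups=df["g"]).fit(reml=reml)
            assert mine.coefficients["x"] == pytest.approx(ref.fe_params["x"],
                                                           abs=1e-5)
            assert mine.sigma2_random == pytest.approx(
                float(ref.cov_re.iloc[0, 0]), abs=1e-4)
            assert mine.sigma2_residual == pytest.approx(ref.scale, abs=1e-4)

    def test_r2_formulas_direct_ratio(self):
        """sigma2_f=1, sigma2_r=1, sigma2_e=2 give R2m=0.25, R2c=0.50."""
        from woodfrac.lmm import LMMFit

        fit = LMMFit(beta=np.zeros(1), sigma2_e=2.0, sigma2_b=1.0,
                     sigma2_f=1.0, lam=0.5, deviance=0.0, method="reml",
                     n=80, p=1, singular=False)
        assert fit.r2_marginal == 0.25
        assert fit.r2_conditional == 0.50

    def test_r2_ordering_invariant(self):
        for seed in range(5):
            fit = fit_mixed_model(_sim(beta=0.5, seed=seed), FULL)
            assert 0.0 <= fit.r2_marginal <= fit.r2_conditional <= 1.0

    def test_null_slope_r2m_near_zero(self):
        """With beta=0, R2 marginal averages below 0.05 at n=80."""
        r2s = [fit_mixed_model(_sim(beta=0.0, seed=i), FULL).r2_marginal
               for i in range(100)]
        assert np.mean(r2s) <= 0.05

    def test_r2c_recovers_species_share(self):
        """Null-slope model with a 0.74 species share of response variance
        has R2 conditional near 0.74."""
        r2cs = []
        for i in range(60):
            ds = _sim(beta=0.0, seed=300 + i, s2_sp=0.74, s2_e=0.26)
            r2cs.append(fit_mixed_model(ds, NULL).r2_conditional)
        assert np.mean(r2cs) == pytest.approx(0.74, abs=0.03)

    def test_singular_fit_flagged(self):
        ds = _sim(beta=0.0, seed=1, s2_sp=0.0, s2_e=1.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fits = [fit_mixed_model(_sim(beta=0.0, seed=i, s2_sp=0.0), NULL)
                    for i in range(10)]
        assert any(f.singular for f in fits)

    def test_requires_replicated_groups(self):
        ds = generate_field_dataset(n_species=4, n_individuals=2, seed=0)
        df = ds.data.iloc[::2]  # one individual per species
        with pytest.raises(ValueError):
            fit_mixed_model(df, MixedModelSpec(response="SLA_cm2_g"))


class TestParametricBootstrap:
    def test_identical_models_p_near_one(self):
        p = parametric_bootstrap_p(FULL, FULL, _sim(beta=0.4, seed=2),
                                   reps=199, seed=0)
        assert p == 1.0

    def test_non_nested_rejected(self):
        other = MixedModelSpec(response="y", predictors=("x", "z"))
        with pytest.raises(ValueError):
            parametric_bootstrap_p(FULL, other, _sim(), reps=199, seed=0)

    def test_strong_effect_detected(self):
        """Standardised slope 1.0 at n=80: p <= 0.05 in >= 90 % of seeds."""
        hits = 0
        n_seeds = 30
        for i in range(n_seeds):
            ds = _sim(beta=1.0, seed=1000 + i)
            p = parametric_bootstrap_p(FULL, NULL, ds, reps=199, seed=i)
            hits += p <= 0.05
        assert hits >= 0.9 * n_seeds

    def test_minimum_reps_enforced(self):
        with pytest.raises(ValueError):
            parametric_bootstrap_p(FULL, NULL, _sim(), reps=50, seed=0)


class TestVariancePartition:
    def test_zero_within_variance_is_pure_species(self):
        df = pd.DataFrame({"species": np.repeat(list("abcd"), 5),
                           "t": np.repeat([1.0, 2.0, 3.0, 4.0], 5)})
        vp = variance_partition(df, "t")
        assert vp.percent["species"] == pytest.approx(100.0)

    def test_shares_sum_to_100(self):
        ds = generate_field_dataset(seed=3)
        vp = variance_partition(ds, "SLA_cm2_g")
        assert sum(vp.percent.values()) == pytest.approx(100.0)

    def test_single_species_rejected(self):
        df = pd.DataFrame({"species": ["a"] * 5, "t": np.arange(5.0)})
        with pytest.raises(ValueError):
            variance_partition(df, "t")

    def test_null_share_recovery_small(self):
        assert variance_partition_recovery(0.0, n_replicates=100,
                                           seed=5) <= 5.0

    @pytest.mark.parametrize("share", [0.3, 0.7, 0.9])
    def test_recovery_unbiased_on_grid(self, share):
        rec = variance_partition_recovery(share, n_replicates=200,
                                          seed=int(share * 100))
        assert rec == pytest.approx(100 * share, abs=2.0)


class TestGroupTTest:
    def test_identical_groups(self):
        vals = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        cls = np.array(["low"] * 3 + ["high"] * 3)
        t, p = group_ttest(vals, cls)
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_large_separation_significant(self):
        rng = np.random.default_rng(0)
        low = rng.normal(10.0, 1.0, 8)
        high = rng.normal(0.0, 1.0, 8)
        vals = np.concatenate([low, high])
        cls = np.array(["low"] * 8 + ["high"] * 8)
        t, p = group_ttest(vals, cls)
        assert t > 0 and p < 0.001

    def test_sign_convention_antisymmetric(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=16) + np.r_[np.ones(8), np.zeros(8)]
        cls = np.array(["low"] * 8 + ["high"] * 8)
        t1, _ = group_ttest(vals, cls, convention="low_minus_high")
        t2, _ = group_ttest(vals, cls, convention="high_minus_low")
        assert t1 > 0 and t2 == pytest.approx(-t1)


class TestPCA:
    def test_perfect_correlation_one_axis(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        df = pd.DataFrame({"a": x, "b": 2.0 * x + 1.0})
        res = pca_summary(df, ["a", "b"])
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_isotropic_noise_equal_axes(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(1000, 4)), columns=list("abcd"))
        res = pca_summary(df, list("abcd"))
        assert np.allclose(res.explained_variance_ratio, 0.25, atol=0.05)
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_loadings_orthonormal(self):
        ds = generate_field_dataset(seed=1)
        res = pca_summary(ds, ["parenchyma_fraction_stem", "SLA_cm2_g",
                               "wood_density_g_cm3", "sapwood_N_mg_g"])
        L = res.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-8)

    def test_constant_variable_rejected(self):
        df = pd.DataFrame({"a": np.arange(10.0), "b": np.ones(10)})
        with pytest.raises(ValueError, match="constant"):
            pca_summary(df, ["a", "b"])


class TestStepwiseAIC:
    def _noise_dataset(self, seed, beta=0.0):
        return generate_field_dataset(
            traits={"x1": TraitSpec(0.0, 0.5, 0.5),
                    "x2": TraitSpec(0.0, 0.5, 0.5)},
            link=LinkSpec(predictor="x1", response="y", alpha=0.0, beta=beta,
                          sigma2_species=0.5, sigma2_residual=0.5,
                          positive=False),
            seed=seed)

    def test_selected_aic_never_above_full(self):
        for seed in range(5):
            ds = self._noise_dataset(seed)
            full = MixedModelSpec(response="y", predictors=("x1", "x2"))
            sel = stepwise_backward_aic(ds, full)
            full_fit = fit_mixed_model(ds, full)
            assert sel.aic_ml <= full_fit.aic_ml + 1e-9

    def test_pure_noise_mostly_empties_model(self):
        """With both predictors pure noise the empty fixed-effects model is
        selected in the majority of seeds."""
        empty = 0
        n_seeds = 40
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for seed in range(n_seeds):
                ds = self._noise_dataset(seed, beta=0.0)
                full = MixedModelSpec(response="y", predictors=("x1", "x2"))
                sel = stepwise_backward_aic(ds, full)
                empty += len(sel.spec.predictors) == 0
        assert empty > n_seeds / 2

    def test_strong_predictor_retained(self):
        kept = 0
        n_seeds = 25
        for seed in range(n_seeds):
            ds = self._noise_dataset(500 + seed, beta=1.0)
            full = MixedModelSpec(response="y", predictors=("x1", "x2"))
            sel = stepwise_backward_aic(ds, full)
            kept += "x1" in sel.spec.predictors
        assert kept >= 0.95 * n_seeds


class TestKruskal:
    def test_identical_samples(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p = kruskal_within_species([1.0, 1.0, 1.0], [1.0, 1.0])
        assert p >= 0.99

    def test_disjoint_supports_minimal_p(self):
        """n=5+5 with disjoint supports attains the minimal two-group
        Kruskal-Wallis p for that n (chi-square approximation of H_max)."""
        from scipy.stats import chi2, rankdata

        stem = [1.0, 2.0, 3.0, 4.0, 5.0]
        twig = [10.0, 11.0, 12.0, 13.0, 14.0]
        h, p = kruskal_within_species(stem, twig)
        # exact enumeration oracle: H is maximal when ranks are fully separated
        ranks = rankdata(stem + twig)
        n = len(ranks)
        h_max = (12.0 / (n * (n + 1))
                 * (5 * (np.mean(ranks[:5]) ** 2)
                    + 5 * (np.mean(ranks[5:]) ** 2))
                 - 3 * (n + 1))
        assert h == pytest.approx(h_max)
        assert p == pytest.approx(chi2.sf(h_max, df=1))

    def test_rank_invariance_under_monotone_transform(self):
        stem = [1.0, 5.0, 2.5, 7.0]
        twig = [3.0, 4.0, 6.0]
        h1, _ = kruskal_within_species(stem, twig)
        h2, _ = kruskal_within_species(np.exp(stem), np.exp(twig))
        assert h1 == pytest.approx(h2)
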