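"""Mixed-model association machinery: encodings, REML null fit, scan, Me."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nciikit import (
    MixedModelScan,
    effective_snp_count,
    encode_model,
    fit_null_lmm,
    gwas_pipeline,
    scan,
)
from nciikit.assoc import LMMNullFit, reml_loglik
from nciikit.simulate import pick_segregating_qtl, simulate_phenotypes

from conftest import make_matrix


def ols_pvalues(y, G):
    """Simple-linear-regression oracle, one variant at a time."""
    out = []
    for j in range(G.shape[1]):
        res = stats.linregress(G[:, j], y)
        out.append(res.pvalue)
    return np.array(out)


class TestEncodeModel:
    def test_additive_is_identity(self, rng):
        codes = rng.integers(0, 3, size=(5, 8))
        np.testing.assert_array_equal(encode_model(codes, "additive"), codes)

    def test_dominant_recodes_het_as_alt_homozygote(self):
        col = np.array([0, 1, 2, 1])
        np.testing.assert_array_equal(encode_model(col, "dominant"), [0, 2, 2, 2])

    def test_recessive_recodes_het_as_ref_homozygote(self):
        col = np.array([0, 1, 2, 1])
        np.testing.assert_array_equal(encode_model(col, "recessive"), [0, 0, 2, 0])

    def test_missing_preserved(self):
        col = np.array([0.0, 1.0, np.nan, 2.0])
        out = encode_model(col, "dominant")
        assert np.isnan(out[2]) and out[1] == 2

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown model"):
            encode_model(np.zeros(3), "codominant")


class TestNullFit:
    def test_identity_kinship_matches_ols_total_variance(self, rng):
        """With K = I only the total variance is identified; it must equal
        the OLS residual variance."""
        n = 80
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ np.array([1.0, 2.0]) + rng.normal(0, 1.5, n)
        fit = fit_null_lmm(y, X, np.eye(n))
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        s2_ols = resid @ resid / (n - 2)
        assert fit.sigma_g2 + fit.sigma_e2 == pytest.approx(s2_ols, rel=1e-4)

    def test_optimum_beats_random_points(self, rng):
        n = 60
        A = rng.normal(size=(n, n))
        K = A @ A.T / n
        X = np.ones((n, 1))
        L = np.linalg.cholesky(K + 1e-8 * np.eye(n))
        y = 2.0 + L @ rng.normal(0, 1, n) + rng.normal(0, 1, n)
        fit = fit_null_lmm(y, X, K)
        for _ in range(50):
            sg, se = rng.uniform(0.05, 5.0, 2)
            assert fit.reml_loglik >= reml_loglik(fit, y, X, sg, se) - 1e-6

    def test_recovers_variance_components_on_average(self, rng):
        """sigma_g2=2, sigma_e2=1, n=300: mean estimates within 30% over 20
        replicates."""
        n = 300
        A = rng.normal(size=(n, 2 * n))
        K = A @ A.T / (2 * n)
        L = np.linalg.cholesky(K + 1e-10 * np.eye(n))
        X = np.ones((n, 1))
        gs, es = [], []
        for _ in range(20):
            y = L @ rng.normal(0, np.sqrt(2.0), n) + rng.normal(0, 1.0, n)
            fit = fit_null_lmm(y, X, K)
            gs.append(fit.sigma_g2)
            es.append(fit.sigma_e2)
        assert abs(np.mean(gs) - 2.0) / 2.0 < 0.3
        assert abs(np.mean(es) - 1.0) / 1.0 < 0.3

    def test_constant_phenotype_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_null_lmm(np.ones(10), np.ones((10, 1)), np.eye(10))

    def test_non_psd_kinship_rejected(self, rng):
        K = np.diag([1.0] * 9 + [-1.0])
        with pytest.raises(ValueError, match="positive semi-definite"):
            fit_null_lmm(rng.normal(size=10), np.ones((10, 1)), K)


class TestScan:
    def test_identity_kinship_matches_ols(self, rng):
        n, M = 100, 120
        G = rng.binomial(2, 0.3, size=(n, M)).astype(float)
        y = rng.normal(size=n)
        res = scan(y, np.ones((n, 1)), np.eye(n), G)
        np.testing.assert_allclose(res["p"], ols_pvalues(y, G), atol=1e-8)

    def test_sigma_g_zero_equals_weighted_ols(self, rng):
        """With sigma_g2 pinned to 0 the GLS collapses to OLS exactly."""
        n, M = 50, 30
        G = rng.binomial(2, 0.4, size=(n, M)).astype(float)
        y = rng.normal(size=n)
        K = np.eye(n)
        lam, U = np.linalg.eigh(K)
        null = LMMNullFit(0.0, 1.3, np.inf, 0.0, lam, U)
        res = scan(y, np.ones((n, 1)), K, G, nullfit=null)
        np.testing.assert_allclose(res["p"], ols_pvalues(y, G), atol=1e-10)

    def test_duplicated_variant_identical_statistics(self, rng):
        n = 60
        g = rng.binomial(2, 0.5, size=n).astype(float)
        G = np.column_stack([g, rng.binomial(2, 0.5, size=n), g])
        y = g + rng.normal(size=n)
        res = scan(y, np.ones((n, 1)), np.eye(n), G)
        assert res.loc[0, "p"] == res.loc[2, "p"]
        assert res.loc[0, "beta"] == res.loc[2, "beta"]

    def test_invariant_to_constant_shift(self, rng):
        n = 50
        G = rng.binomial(2, 0.4, size=(n, 20)).astype(float)
        y = rng.normal(size=n)
        K = np.eye(n)
        r1 = scan(y, np.ones((n, 1)), K, G)
        r2 = scan(y + 37.5, np.ones((n, 1)), K, G)
        np.testing.assert_allclose(r1["stat"], r2["stat"], atol=1e-8)

    def test_monomorphic_variant_reported_with_reason(self, rng):
        n = 40
        G = rng.binomial(2, 0.4, size=(n, 3)).astype(float)
        G[:, 1] = 2.0
        y = rng.normal(size=n)
        res = scan(y, np.ones((n, 1)), np.eye(n), G)
        assert np.isnan(res.loc[1, "p"])
        assert res.loc[1, "reason"] == "zero-variance-or-collinear"
        assert res.loc[0, "reason"] == ""

    def test_exact_mode_agrees_on_small_instance(self, rng):
        n = 40
        A = rng.normal(size=(n, n))
        K = A @ A.T / n
        G = rng.binomial(2, 0.4, size=(n, 10)).astype(float)
        L = np.linalg.cholesky(K + 1e-8 * np.eye(n))
        y = 0.8 * G[:, 0] + L @ rng.normal(0, 0.5, n) + rng.normal(0, 0.5, n)
        X = np.ones((n, 1))
        approx = scan(y, X, K, G, fit_null_lmm(y, X, K))
        exact = scan(y, X, K, G, exact=True)
        # the EMMAX approximation tracks the exact per-variant REML closely
        lp1 = -np.log10(approx["p"])
        lp2 = -np.log10(exact["p"])
        assert np.corrcoef(lp1, lp2)[0, 1] > 0.99


class TestEffectiveSnpCount:
    def test_all_copies_collapse_to_one(self, rng):
        col = rng.binomial(2, 0.5, size=50).astype(float)
        G = np.tile(col[:, None], (1, 30))
        me, thr = effective_snp_count(G, window_size=30)
        assert me == pytest.approx(1.0)
        assert thr == pytest.approx(0.05)

    def test_independent_variants_me_close_to_m(self, rng):
        G = rng.binomial(2, 0.5, size=(4000, 100)).astype(float)
        me, _ = effective_snp_count(G, window_size=100)
        assert me / 100 == pytest.approx(1.0, abs=0.1)

    def test_me_bounded_by_m(self, rng):
        G = rng.binomial(2, 0.3, size=(30, 200)).astype(float)
        me, _ = effective_snp_count(G, window_size=50)
        assert me <= 200

    def test_single_variant_window_contributes_one(self, rng):
        G = rng.binomial(2, 0.5, size=(20, 1)).astype(float)
        me, _ = effective_snp_count(G, window_size=1000)
        assert me == pytest.approx(1.0)

    def test_threshold_grows_with_ld(self, rng):
        """More LD -> fewer effective tests -> weakly larger threshold."""
        col = rng.binomial(2, 0.5, size=(60, 1)).astype(float)
        corr = np.tile(col, (1, 40))
        flip = rng.random((60, 40)) < 0.1
        corr[flip] = rng.binomial(2, 0.5, size=int(flip.sum()))
        indep = rng.binomial(2, 0.5, size=(60, 40)).astype(float)
        _, thr_ld = effective_snp_count(corr, window_size=40)
        _, thr_indep = effective_snp_count(indep, window_size=40)
        assert thr_ld >= thr_indep


class TestPipeline:
    def test_planted_additive_qtl_top_hit_in_gca_scan(self):
        from nciikit import NCIIDesign, SimConfig, derive_f1_genotypes, simulate_parents

        cfg = SimConfig(n_males=48, n_females=4, n_subpops=2, n_snps=300,
                        residual_sd=0.6, seed=42)
        parents, labels = simulate_parents(cfg)
        males = parents.take_samples(parents.sample_ids[: cfg.n_males])
        females = parents.take_samples(parents.sample_ids[cfg.n_males:])
        design = NCIIDesign.full_factorial(males.sample_ids, females.sample_ids, 3)
        f1 = derive_f1_genotypes(males, females, design)
        q = pick_segregating_qtl(males, females, require_female_segregation=False)
        pheno, _ = simulate_phenotypes(
            parents, f1, design, cfg, subpop_labels=labels,
            qtl_additive=np.array([q]), qtl_dominance=np.array([], dtype=int),
            additive_effects=np.array([2.0]),
        )
        res = gwas_pipeline(
            parents, f1, pheno, design, [("parent-gca", "additive")], "trait1",
            n_pcs=5, me_window=150,
        )[("parent-gca", "additive")]
        top = res.results.loc[res.results["p"].idxmin()]
        assert top["pos"] == parents.variants["pos"].iloc[q]
        assert res.me <= res.m
        assert res.threshold == pytest.approx(0.05 / res.me)

    def test_f1_target_on_parent_genotypes_switch(self, small_dataset):
        """sca_on_parents scans each hybrid's value on its male parent's
        genotype row; results exist for every retained variant."""
        ds = small_dataset
        res = gwas_pipeline(
            ds.parents, ds.f1, ds.phenotypes, ds.design,
            [("f1-sca", "additive")], "trait1", n_pcs=3, sca_on_parents=True,
        )[("f1-sca", "additive")]
        assert len(res.results) == res.m
        assert res.results["p"].notna().all()

    def test_estimator_interface(self, small_dataset):
        est = MixedModelScan(encoding="additive", n_pcs=3, me_window=100)
        males = small_dataset.males
        y = pd.Series(
            np.random.default_rng(0).normal(size=males.n_samples) + males.dosages()[:, 0],
            index=males.sample_ids,
        )
        est.fit(males, y)
        assert est.results_.shape[0] == males.n_variants
        assert set(["chrom", "pos", "encoding", "beta", "se", "stat", "p", "maf"]).issubset(
            est.results_.columns
        )
        assert est.get_params()["n_pcs"] == 3
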