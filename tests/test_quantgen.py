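"""NCII ANOVA, variance components, GCA/SCA, heterosis, correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nciikit import (
    NCIIAnova,
    UnbalancedDesignError,
    anova_ncii,
    cell_mean_table,
    compute_gca_sca,
    correlation_tests,
    heritability_from_components,
    heterotic_advantage,
    trait_matrix,
    variance_components_from_ms,
)

from conftest import anova_ss_oracle, balanced_pheno_frame


class TestNCIIAnova:
    def test_toy_matches_bruteforce_ss(self, toy_2x2x2):
        fit = NCIIAnova().fit(toy_2x2x2)
        oracle = anova_ss_oracle(toy_2x2x2)
        for src in ("replications", "males", "females", "males_x_females", "error"):
            assert fit.anova_.loc[src, "ss"] == pytest.approx(oracle[src], abs=1e-9)
        assert fit.anova_["df"].tolist() == [1, 1, 1, 1, 3]

    def test_all_equal_observations(self):
        df = balanced_pheno_frame([[[5, 5], [5, 5]], [[5, 5], [5, 5]]])
        fit = NCIIAnova().fit(df)
        np.testing.assert_allclose(fit.anova_["ss"], 0.0, atol=1e-12)
        assert fit.anova_["F"].isna().all()

    def test_ss_additivity_on_balanced_data(self, rng):
        vals = rng.normal(50, 5, size=(6, 3, 3))
        df = balanced_pheno_frame(vals.tolist())
        fit = NCIIAnova().fit(df)
        ss_total = float(np.sum((vals - vals.mean()) ** 2))
        assert fit.anova_["ss"].sum() == pytest.approx(ss_total, rel=1e-10)

    def test_random_balanced_matches_oracle(self, rng):
        vals = rng.normal(0, 1, size=(4, 3, 2))
        df = balanced_pheno_frame(vals.tolist())
        fit = NCIIAnova().fit(df)
        oracle = anova_ss_oracle(df)
        for src in ("replications", "males", "females", "males_x_females", "error"):
            assert fit.anova_.loc[src, "ss"] == pytest.approx(oracle[src], abs=1e-9)

    def test_unbalanced_input_directed_to_cell_mean_mode(self, toy_2x2x2):
        df = toy_2x2x2.iloc[:-1]  # drop one observation
        with pytest.raises(UnbalancedDesignError, match="compute_gca_sca"):
            NCIIAnova().fit(df)

    def test_f_denominators(self, rng):
        """Males/females are tested over the interaction MS, the interaction
        over the error MS."""
        vals = rng.normal(0, 1, size=(5, 4, 3))
        fit = NCIIAnova().fit(balanced_pheno_frame(vals.tolist()))
        a = fit.anova_
        assert a.loc["males", "F"] == pytest.approx(
            a.loc["males", "ms"] / a.loc["males_x_females", "ms"]
        )
        assert a.loc["females", "F"] == pytest.approx(
            a.loc["females", "ms"] / a.loc["males_x_females", "ms"]
        )
        assert a.loc["males_x_females", "F"] == pytest.approx(
            a.loc["males_x_females", "ms"] / a.loc["error", "ms"]
        )


class TestVarianceComponents:
    def test_equal_mean_squares_give_zero_genetic_variance(self):
        vc = variance_components_from_ms(3.0, 3.0, 3.0, 3.0, r=3, m=4, f=10)
        assert vc.var_male == vc.var_female == vc.var_sca == 0.0
        assert vc.h2 == 0.0 and vc.H2 == 0.0

    def test_negative_estimate_flagged_and_optionally_truncated(self):
        raw = variance_components_from_ms(1.0, 1.0, 2.0, 1.0, r=3, m=4, f=10)
        assert raw.negative_flag and raw.var_male < 0
        trunc = variance_components_from_ms(1.0, 1.0, 2.0, 1.0, r=3, m=4, f=10, truncate=True)
        assert trunc.var_male == 0.0 and trunc.negative_flag

    def test_h2_never_exceeds_H2_for_nonnegative_components(self, rng):
        for _ in range(20):
            vf, vm, vs, ve = rng.uniform(0, 5, 4)
            vc = heritability_from_components(vf, vm, vs, ve)
            assert 0.0 <= vc.h2 <= vc.H2 <= 1.0

    def test_estimates_unbiased_on_synthetic_components(self, rng):
        """Method-of-moments recovery: the estimator is linear in the mean
        squares and hence unbiased; the mean over 200 balanced replicates
        must sit within 3 MC standard errors of each generating component
        (3 rather than 2 because four components are checked jointly under
        one fixed seed)."""
        f, m, r = 20, 4, 3
        true = {"male": 1.0, "female": 0.5, "sca": 0.8, "error": 1.2}
        est = {k: [] for k in true}
        for _ in range(200):
            gm = rng.normal(0, np.sqrt(true["male"]), f)
            gf = rng.normal(0, np.sqrt(true["female"]), m)
            sca = rng.normal(0, np.sqrt(true["sca"]), (f, m))
            obs = (
                gm[:, None, None]
                + gf[None, :, None]
                + sca[:, :, None]
                + rng.normal(0, np.sqrt(true["error"]), (f, m, r))
            )
            fit = NCIIAnova().fit(balanced_pheno_frame(obs.tolist()))
            vc = fit.variance_components_
            est["male"].append(vc.var_male)
            est["female"].append(vc.var_female)
            est["sca"].append(vc.var_sca)
            est["error"].append(vc.var_error)
        for k in true:
            arr = np.array(est[k])
            se = arr.std(ddof=1) / np.sqrt(len(arr))
            assert abs(arr.mean() - true[k]) < 3 * se + 1e-9, k


class TestCombiningAbility:
    def test_additive_table(self):
        ca = compute_gca_sca(pd.DataFrame([[10.0, 12.0], [14.0, 16.0]]))
        assert ca.grand_mean_ == 13.0
        assert ca.gca_male_.tolist() == [-2.0, 2.0]
        assert ca.gca_female_.tolist() == [-1.0, 1.0]
        np.testing.assert_allclose(ca.sca_.to_numpy(), 0.0, atol=1e-12)

    def test_pure_interaction_table(self):
        ca = compute_gca_sca(pd.DataFrame([[10.0, 14.0], [14.0, 10.0]]))
        np.testing.assert_allclose(ca.gca_male_, 0.0, atol=1e-12)
        np.testing.assert_allclose(ca.gca_female_, 0.0, atol=1e-12)
        np.testing.assert_allclose(
            ca.sca_.to_numpy(), [[-2.0, 2.0], [2.0, -2.0]], atol=1e-12
        )

    def test_reconstruction_identity_random_4x96(self, rng):
        cell = pd.DataFrame(rng.normal(100, 10, size=(96, 4)))
        ca = compute_gca_sca(cell)
        pd.testing.assert_frame_equal(ca.predict(), cell)
        assert ca.gca_male_.sum() == pytest.approx(0.0, abs=1e-8)
        assert ca.gca_female_.sum() == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(ca.sca_.sum(axis=0), 0.0, atol=1e-8)
        np.testing.assert_allclose(ca.sca_.sum(axis=1), 0.0, atol=1e-8)

    def test_missing_cells_flagged_incomplete(self):
        cell = pd.DataFrame([[10.0, np.nan], [14.0, 10.0]])
        ca = compute_gca_sca(cell)
        assert not ca.complete_

    def test_fully_missing_row_rejected(self):
        cell = pd.DataFrame([[np.nan, np.nan], [14.0, 10.0]])
        with pytest.raises(ValueError, match="fully missing"):
            compute_gca_sca(cell)

    def test_noise_free_decomposition_matches_truth(self):
        """GCA/SCA of the noise-free synthetic genetic values equals the
        generator's recorded truth exactly."""
        from nciikit import SimConfig, simulate_ncii_dataset

        ds = simulate_ncii_dataset(
            SimConfig(n_males=12, n_females=3, n_subpops=2, n_snps=100, seed=17)
        )
        gv = ds.truth.genetic_values
        cell = pd.DataFrame(
            index=ds.design.male_ids, columns=ds.design.female_ids, dtype=float
        )
        for (m, f), h in ds.design.crosses.items():
            cell.loc[m, f] = gv[h]
        ca = compute_gca_sca(cell)
        pd.testing.assert_series_equal(ca.gca_male_, ds.truth.true_gca_males)
        pd.testing.assert_frame_equal(ca.sca_, ds.truth.true_sca)


class TestHeterosis:
    def test_formula_examples(self, small_dataset):
        ds = small_dataset
        tab = heterotic_advantage(ds.phenotypes, ds.design, "trait1")
        means = trait_matrix(ds.phenotypes, "mean")["trait1"]
        row = tab.iloc[0]
        expect = 100.0 * (means[row["hybrid"]] - means[row["male"]]) / means[row["male"]]
        assert row["advantage_pct"] == pytest.approx(expect)
        # element-wise recomputation across all hybrids
        for _, r in tab.iterrows():
            e = 100.0 * (r["hybrid_value"] - r["male_value"]) / r["male_value"]
            assert r["advantage_pct"] == pytest.approx(e)

    def test_plus_fifty_and_zero_percent(self):
        import pandas as pd

        from nciikit import NCIIDesign, PhenotypeTable

        design = NCIIDesign.full_factorial(["m1", "m2"], ["f1"], 1)
        rows = [
            ("m1", 20.0), ("m2", 20.0), ("m1xf1", 30.0), ("m2xf1", 20.0),
        ]
        pheno = PhenotypeTable(
            pd.DataFrame(
                [{"id": i, "trait": "t", "rep": "r1", "value": v} for i, v in rows]
            )
        )
        tab = heterotic_advantage(pheno, design, "t").set_index("hybrid")
        assert tab.loc["m1xf1", "advantage_pct"] == pytest.approx(50.0)
        assert tab.loc["m2xf1", "advantage_pct"] == pytest.approx(0.0)

    def test_zero_male_mean_flagged_undefined(self):
        import pandas as pd

        from nciikit import NCIIDesign, PhenotypeTable

        design = NCIIDesign.full_factorial(["m1"], ["f1"], 1)
        pheno = PhenotypeTable(
            pd.DataFrame(
                [
                    {"id": "m1", "trait": "t", "rep": "r1", "value": 0.0},
                    {"id": "m1xf1", "trait": "t", "rep": "r1", "value": 5.0},
                ]
            )
        )
        tab = heterotic_advantage(pheno, design, "t")
        assert tab["undefined"].iloc[0]
        assert np.isnan(tab["advantage_pct"].iloc[0])


class TestCorrelations:
    def test_perfect_linear_relation(self, rng):
        x = rng.normal(size=30)
        X = pd.DataFrame({"x": x, "y": 2 * x + 1})
        r, p, n = correlation_tests(X)
        assert r.loc["x", "y"] == pytest.approx(1.0)
        assert p.loc["x", "y"] == pytest.approx(0.0, abs=1e-12)

    def test_p_matches_analytic_t(self, rng):
        x = rng.normal(size=25)
        y = x + rng.normal(size=25)
        r, p, n = correlation_tests(pd.DataFrame({"x": x}), pd.DataFrame({"y": y}))
        rr = r.loc["x", "y"]
        t = rr * np.sqrt((25 - 2) / (1 - rr**2))
        assert p.loc["x", "y"] == pytest.approx(2 * stats.t.sf(abs(t), 23))
        # and agrees with the standard two-sided test
        assert p.loc["x", "y"] == pytest.approx(stats.pearsonr(x, y).pvalue, rel=1e-10)

    def test_zero_variance_column_gives_missing(self, rng):
        X = pd.DataFrame({"x": rng.normal(size=10), "c": 1.0})
        r, p, _ = correlation_tests(X)
        assert np.isnan(r.loc["x", "c"]) and np.isnan(p.loc["x", "c"])

    def test_pairwise_complete_handling(self, rng):
        x = rng.normal(size=20)
        y = x.copy()
        y[:5] = np.nan
        r, p, n = correlation_tests(pd.DataFrame({"x": x}), pd.DataFrame({"y": y}))
        assert n.loc["x", "y"] == 15
        assert r.loc["x", "y"] == pytest.approx(1.0)

    def test_null_correlations_small(self, rng):
        x = rng.normal(size=1000)
        y = rng.normal(size=1000)
        r, _, _ = correlation_tests(pd.DataFrame({"x": x}), pd.DataFrame({"y": y}))
        assert abs(r.loc["x", "y"]) < 0.1


def test_anova_pipeline_from_design(small_dataset):
    """anova_ncii wires the phenotype/design plumbing into the estimator."""
    fit = anova_ncii(small_dataset.phenotypes, small_dataset.design, "trait1")
    assert fit.r_ == 3 and fit.m_ == 4 and fit.f_ == 24
    cell = cell_mean_table(small_dataset.phenotypes, small_dataset.design, "trait1")
    assert cell.shape == (24, 4)
    assert cell.notna().all().all()
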