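"""Reproducible simulation experiments over the full analysis pipeline.

Each function builds its own synthetic NCII data from a base seed, runs the
relevant slice of the pipeline and returns summary numbers.  They back both
the validation suite and the reproduction script: heritability recovery at
the emulated trial scale (96 males x 4 testers x 3 replications),
mixed-model calibration against ordinary least squares and under the null,
planted-QTL detection under the three genotype encodings, and the
parent-versus-F1 LD contrast.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .assoc import fit_null_lmm, genomic_inflation, gwas_pipeline, scan
from .genodata import NCIIDesign
from .quantgen import anova_ncii
from .simulate import (
    SimConfig,
    derive_f1_genotypes,
    pick_segregating_qtl,
    simulate_ncii_dataset,
    simulate_parents,
    simulate_phenotypes,
)
from .structure import kinship_ibs, ld_decay


def _child_seeds(base_seed: int, n: int) -> np.ndarray:
    """Independent 31-bit seeds derived from one base seed."""
    return np.random.SeedSequence(base_seed).generate_state(n) % (2**31)


def _build_trial(cfg: SimConfig):
    parents, labels = simulate_parents(cfg)
    males = parents.take_samples(parents.sample_ids[: cfg.n_males])
    females = parents.take_samples(parents.sample_ids[cfg.n_males:])
    design = NCIIDesign.full_factorial(males.sample_ids, females.sample_ids, cfg.n_reps)
    f1 = derive_f1_genotypes(males, females, design)
    return parents, males, females, design, f1, labels


def h2_recovery(
    base_seed: int,
    n_replicates: int = 50,
    n_snps: int = 400,
    **cfg_overrides,
) -> dict:
    """Estimated vs realized narrow-sense heritability at trial scale.

    Simulates full 96 x 4 x 3 datasets under the default architecture
    (which targets h2 near 0.6), estimates h2 by NCII ANOVA and compares
    the replicate mean with the mean realized h2 recorded by the generator.
    """
    est, realized = [], []
    for s in _child_seeds(base_seed, n_replicates):
        cfg = SimConfig(seed=int(s), n_snps=n_snps, **cfg_overrides)
        ds = simulate_ncii_dataset(cfg)
        fit = anova_ncii(ds.phenotypes, ds.design, "trait1")
        est.append(fit.variance_components_.h2)
        realized.append(ds.truth.realized_h2)
    return {
        "mean_estimated_h2": float(np.mean(est)),
        "mean_realized_h2": float(np.mean(realized)),
        "abs_bias": float(abs(np.mean(est) - np.mean(realized))),
        "n_replicates": n_replicates,
    }


def pure_additive_sca_bias(
    base_seed: int, n_replicates: int = 50, n_snps: int = 300
) -> dict:
    """Estimated SCA variance under a purely additive architecture.

    With every dominance effect zero the interaction component has
    expectation zero; reports the replicate mean, its Monte-Carlo standard
    error and the standardized mean.
    """
    vals = []
    for s in _child_seeds(base_seed, n_replicates):
        cfg = SimConfig(
            seed=int(s), n_snps=n_snps, n_qtl_dominance=1, dominance_effect_sd=0.0
        )
        ds = simulate_ncii_dataset(cfg)
        fit = anova_ncii(ds.phenotypes, ds.design, "trait1")
        vals.append(fit.variance_components_.var_sca)
    vals = np.asarray(vals)
    se = float(vals.std(ddof=1) / np.sqrt(len(vals)))
    return {
        "mean_var_sca": float(vals.mean()),
        "mc_se": se,
        "standardized_mean": float(vals.mean() / se),
        "n_replicates": n_replicates,
    }


def lmm_vs_ols(base_seed: int, n: int = 200, m: int = 500) -> dict:
    """Identity-kinship scan against per-variant simple regression.

    With K = I and an intercept-only design the mixed model is ordinary
    least squares; reports the largest absolute p-value discrepancy.
    """
    rng = np.random.default_rng(base_seed)
    G = rng.binomial(2, rng.uniform(0.1, 0.5, m), size=(n, m)).astype(float)
    y = rng.normal(size=n)
    res = scan(y, np.ones((n, 1)), np.eye(n), G)
    ols = np.array([stats.linregress(G[:, j], y).pvalue for j in range(m)])
    return {
        "max_abs_p_diff": float(np.max(np.abs(res["p"].to_numpy() - ols))),
        "n": n,
        "m": m,
    }


def null_pvalue_uniformity(base_seed: int, n: int = 200, m: int = 500) -> dict:
    """KS uniformity of scan p-values under a permuted-phenotype null."""
    rng = np.random.default_rng(base_seed)
    G = rng.binomial(2, rng.uniform(0.1, 0.5, m), size=(n, m)).astype(float)
    y = G[:, 0] * 0.5 + rng.normal(size=n)
    y = rng.permutation(y)  # break any genotype-phenotype link
    res = scan(y, np.ones((n, 1)), np.eye(n), G)
    ks = stats.kstest(res["p"].dropna(), "uniform")
    return {"ks_pvalue": float(ks.pvalue), "n": n, "m": m}


def lambda_gc_null(
    base_seed: int, n_samples: int = 300, m: int = 2000
) -> dict:
    """Genomic inflation of the Q+K model on a structured polygenic null.

    Simulates a structured panel, draws y from N(0, sigma_g2*K + sigma_e2*I)
    with K the IBS kinship of the panel (no individual causal variant), and
    scans all variants; a calibrated model keeps the median test statistic
    at its null value (lambda_GC near 1).
    """
    cfg = SimConfig(
        n_males=n_samples - 4, n_females=4, n_subpops=3, n_snps=m, seed=int(base_seed)
    )
    parents, _ = simulate_parents(cfg)
    K = kinship_ibs(parents).to_numpy()
    rng = np.random.default_rng(base_seed + 1)
    lam, U = np.linalg.eigh(K)
    lam = np.clip(lam, 0.0, None)
    sigma_g2, sigma_e2 = 1.0, 1.0
    y = U @ (np.sqrt(sigma_g2 * lam) * rng.normal(size=n_samples)) + rng.normal(
        0, np.sqrt(sigma_e2), n_samples
    )
    from .structure import GenotypePCA

    d = parents.dosages()
    pcs = GenotypePCA(n_components=5).fit(d).scores_
    X = np.column_stack([np.ones(n_samples), pcs])
    null = fit_null_lmm(y, X, K)
    res = scan(y, X, K, d, null)
    return {
        "lambda_gc": genomic_inflation(res["p"].dropna().to_numpy()),
        "n": n_samples,
        "m": m,
    }


def dominance_qtl_detection(
    base_seed: int,
    n_replicates: int = 20,
    n_snps: int = 600,
    d_effect: float = 3.0,
) -> dict:
    """Planted pure-dominance QTL: detection rates in the F1-SCA scans.

    One QTL with a = 0 and large d, placed at a variant segregating in both
    parent pools (a dominance locus fixed among the testers leaves no SCA
    signal).  Reports how often the QTL clears the Me-Bonferroni threshold
    under the dominant and the additive encodings.
    """
    hit_dom = hit_add = 0
    for s in _child_seeds(base_seed, n_replicates):
        cfg = SimConfig(seed=int(s), n_snps=n_snps, residual_sd=0.5, block_sd=0.3)
        parents, males, females, design, f1, labels = _build_trial(cfg)
        q = pick_segregating_qtl(males, females)
        pheno, _ = simulate_phenotypes(
            parents, f1, design, cfg, subpop_labels=labels,
            qtl_additive=np.array([], dtype=int),
            qtl_dominance=np.array([q]),
            dominance_effects=np.array([d_effect]),
        )
        out = gwas_pipeline(
            parents, f1, pheno, design,
            [("f1-sca", "dominant"), ("f1-sca", "additive")],
            "trait1", me_window=200,
        )
        pos_q = parents.variants["pos"].iloc[q]
        for enc, counter in (("dominant", "dom"), ("additive", "add")):
            r = out[("f1-sca", enc)]
            sel = r.results["pos"] == pos_q
            p_q = r.results.loc[sel, "p"].min() if sel.any() else 1.0
            if p_q < r.threshold:
                if enc == "dominant":
                    hit_dom += 1
                else:
                    hit_add += 1
    return {
        "rate_dominant": hit_dom / n_replicates,
        "rate_additive": hit_add / n_replicates,
        "n_replicates": n_replicates,
    }


def additive_qtl_top_hit(
    base_seed: int,
    n_replicates: int = 5,
    n_snps: int = 600,
    a_effect: float = 2.0,
) -> dict:
    """Planted large additive QTL: top-hit rate in the parent-GCA scan."""
    hits = 0
    for s in _child_seeds(base_seed, n_replicates):
        cfg = SimConfig(seed=int(s), n_snps=n_snps, residual_sd=0.7)
        parents, males, females, design, f1, labels = _build_trial(cfg)
        q = pick_segregating_qtl(males, females, require_female_segregation=False)
        pheno, _ = simulate_phenotypes(
            parents, f1, design, cfg, subpop_labels=labels,
            qtl_additive=np.array([q]),
            qtl_dominance=np.array([], dtype=int),
            additive_effects=np.array([a_effect]),
        )
        res = gwas_pipeline(
            parents, f1, pheno, design, [("parent-gca", "additive")], "trait1",
            me_window=200,
        )[("parent-gca", "additive")]
        top = res.results.loc[res.results["p"].idxmin()]
        hits += int(top["pos"] == parents.variants["pos"].iloc[q])
    return {"top_hit_rate": hits / n_replicates, "n_replicates": n_replicates}


def ld_parent_vs_f1(base_seed: int, n_snps: int = 300) -> dict:
    """LD decay distance in parents versus their F1s, matched simulation.

    With a few female testers the F1 panel has far fewer independent
    haplotypes than the parent panel, inflating long-range r^2; the F1
    decay distance should be at least the parental one.
    """
    cfg = SimConfig(
        n_males=60, n_females=4, n_subpops=2, fst=0.3, n_snps=n_snps,
        ld_block_size=10, ld_swap_prob=0.05, snp_spacing_bp=2000, seed=int(base_seed),
    )
    parents, males, females, design, f1, _ = _build_trial(cfg)
    kw = dict(max_dist_bp=200_000, bin_width_bp=10_000, r2_threshold=0.2)
    curve_par = ld_decay(males, **kw)
    curve_f1 = ld_decay(f1, **kw)
    maxd = float(kw["max_dist_bp"])
    far = curve_par.bins["dist_lo"] >= 50_000  # beyond the haplotype-block span
    return {
        "parents_decay_bp": min(curve_par.decay_distance, maxd),
        "f1_decay_bp": min(curve_f1.decay_distance, maxd),
        "f1_at_least_parents": bool(
            curve_f1.decay_distance >= curve_par.decay_distance
        ),
        "parents_far_mean_r2": float(np.nanmean(curve_par.bins.loc[far, "mean_r2"])),
        "f1_far_mean_r2": float(np.nanmean(curve_f1.bins.loc[far, "mean_r2"])),
    }
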