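"""Synthetic NCII mating-design datasets with known ground truth.

The generator emulates a hybrid-rice NCII experiment: a diverse panel of
fully inbred male lines drawn from a few diverged subpopulations, a handful
of inbred female tester lines, the complete male x female set of F1 hybrids,
and replicated phenotypes with additive and dominance genetic architecture.

Population structure follows the Balding-Nichols model: each variant has an
ancestral allele frequency p drawn from ``maf_range`` and each subpopulation
an own frequency drawn from Beta(p(1-F)/F, (1-p)(1-F)/F) with divergence F
(``fst``).  Parents are fully homozygous (codes 0/2 only), so every F1
genotype is determined: heterozygous where the parents differ, otherwise
the shared homozygote.

The genetic value of an individual is sum_k a_k x_k + sum_k d_k [x_k == 1]
over the planted QTLs (x = alt-allele dosage); an observed replicate adds a
shared block effect and a Gaussian plot residual.  The returned
:class:`SimTruth` records the planted effects and the exact GCA/SCA
decomposition of the noise-free F1 genetic values, together with the
realized narrow- and broad-sense heritabilities implied by the simulated
architecture.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genodata import GenotypeMatrix, NCIIDesign, PhenotypeTable, write_vcf
from .quantgen import compute_gca_sca


@dataclass
class SimConfig:
    """Parameters of one synthetic NCII dataset.

    Defaults mirror the emulated experiment: 96 inbred males in 4
    subpopulations crossed to 4 female testers (384 F1s), 3 replications,
    and a genetic architecture whose additive share of the phenotypic
    variance lands near 0.6 — mid-range of the heritabilities such trials
    report (~0.13 to ~0.76 across yield traits).
    """

    n_males: int = 96
    n_females: int = 4
    n_subpops: int = 4
    fst: float = 0.15
    n_snps: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 1  # >1 correlates consecutive variants (haplotype blocks)
    ld_swap_prob: float = 0.1  # per-variant chance of leaving the block allele
    snp_spacing_bp: int = 2000
    n_qtl_additive: int = 20
    n_qtl_dominance: int = 10
    additive_effect_sd: float = 0.5
    dominance_effect_sd: float = 0.5
    mean: float = 100.0  # trait grand mean (baseline)
    n_reps: int = 3
    block_sd: float = 0.5
    residual_sd: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        counts = dict(
            n_males=self.n_males,
            n_females=self.n_females,
            n_subpops=self.n_subpops,
            n_snps=self.n_snps,
            n_reps=self.n_reps,
            ld_block_size=self.ld_block_size,
        )
        for name, v in counts.items():
            if int(v) != v or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v}")
        if not 0 <= self.fst < 1:
            raise ValueError("fst must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.n_subpops > self.n_males:
            raise ValueError("n_subpops cannot exceed n_males")
        for name in ("additive_effect_sd", "dominance_effect_sd", "block_sd", "residual_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_qtl_additive + self.n_qtl_dominance > self.n_snps:
            raise ValueError("QTL counts exceed n_snps")

    def rngs(self) -> dict[str, np.random.Generator]:
        """Named independent RNG streams, all derived from ``seed``."""
        ss = np.random.SeedSequence(self.seed)
        names = ("parents", "qtl", "noise")
        return {n: np.random.default_rng(c) for n, c in zip(names, ss.spawn(len(names)))}


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset (single trait)."""

    qtl_indices: np.ndarray
    additive_effects: np.ndarray  # a_k, aligned with qtl_indices
    dominance_effects: np.ndarray  # d_k, aligned with qtl_indices
    subpop_labels: np.ndarray
    true_gca_males: pd.Series
    true_gca_females: pd.Series
    true_sca: pd.DataFrame
    var_male: float
    var_female: float
    var_sca: float
    var_error: float
    realized_h2: float
    realized_H2: float
    genetic_values: pd.Series = field(repr=False, default=None)

    def to_json(self, path: str) -> None:
        payload = {
            "qtl_indices": self.qtl_indices.tolist(),
            "additive_effects": self.additive_effects.tolist(),
            "dominance_effects": self.dominance_effects.tolist(),
            "subpop_labels": self.subpop_labels.tolist(),
            "true_gca_males": self.true_gca_males.to_dict(),
            "true_gca_females": self.true_gca_females.to_dict(),
            "true_sca": self.true_sca.to_dict(),
            "var_male": self.var_male,
            "var_female": self.var_female,
            "var_sca": self.var_sca,
            "var_error": self.var_error,
            "realized_h2": self.realized_h2,
            "realized_H2": self.realized_H2,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _block_frequencies(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-subpopulation allele frequencies, shape (n_subpops, n_blocks)."""
    n_blocks = -(-cfg.n_snps // cfg.ld_block_size)
    lo, hi = cfg.maf_range
    p_anc = rng.uniform(lo, hi, size=n_blocks)
    if cfg.fst == 0:
        return np.tile(p_anc, (cfg.n_subpops, 1))
    c = (1.0 - cfg.fst) / cfg.fst
    freqs = rng.beta(p_anc * c, (1.0 - p_anc) * c, size=(cfg.n_subpops, n_blocks))
    return np.clip(freqs, 1e-4, 1.0 - 1e-4)


def simulate_parents(cfg: SimConfig) -> tuple[GenotypeMatrix, np.ndarray]:
    """Simulate inbred male and female parents.

    Returns one matrix with the males first (ids M001..) then the females
    (ids F01..), plus a subpopulation label per sample.  Males fill the
    subpopulations in contiguous near-equal blocks; females are assigned
    round-robin.  All genotypes are homozygous (0 or 2).
    """
    rng = cfg.rngs()["parents"]
    freqs = _block_frequencies(cfg, rng)

    male_labels = np.array_split(np.arange(cfg.n_males), cfg.n_subpops)
    labels = np.empty(cfg.n_males + cfg.n_females, dtype=int)
    for k, idx in enumerate(male_labels):
        labels[idx] = k
    labels[cfg.n_males:] = np.arange(cfg.n_females) % cfg.n_subpops

    n = len(labels)
    block_of = np.arange(cfg.n_snps) // cfg.ld_block_size
    p = freqs[labels][:, block_of]  # n x n_snps
    core = rng.random((n, freqs.shape[1])) < freqs[labels]  # block allele per sample
    alleles = core[:, block_of]
    if cfg.ld_block_size > 1 and cfg.ld_swap_prob > 0:
        swap = rng.random((n, cfg.n_snps)) < cfg.ld_swap_prob
        redraw = rng.random((n, cfg.n_snps)) < p
        alleles = np.where(swap, redraw, alleles)
    codes = (2 * alleles).astype(np.int8)

    sample_ids = [f"M{i + 1:03d}" for i in range(cfg.n_males)] + [
        f"F{j + 1:02d}" for j in range(cfg.n_females)
    ]
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": (np.arange(cfg.n_snps) + 1) * cfg.snp_spacing_bp,
            "ref": "A",
            "alt": "T",
        }
    )
    return GenotypeMatrix(sample_ids, variants, codes), labels


def derive_f1_genotypes(
    males: GenotypeMatrix, females: GenotypeMatrix, design: NCIIDesign
) -> GenotypeMatrix:
    """Mendelian F1 genotypes from inbred parents.

    The F1 is heterozygous (1) where the parents carry different homozygotes,
    carries the shared code where they agree, and is missing if either
    parent is missing.  Any heterozygous parent call is an error (the
    parents are inbred lines by assumption).
    """
    for G, who in ((males, "male"), (females, "female")):
        het = np.argwhere(G.codes == 1)
        if het.size:
            s, v = het[0]
            row = G.variants.iloc[v]
            raise ValueError(
                f"{who} parent {G.sample_ids[s]!r} is heterozygous at "
                f"{row['chrom']}:{row['pos']} — parents must be inbred"
            )
    male_ix = {s: i for i, s in enumerate(males.sample_ids)}
    female_ix = {s: i for i, s in enumerate(females.sample_ids)}
    hybrid_ids, rows = [], []
    for (m, f), hyb in design.crosses.items():
        gm = males.codes[male_ix[m]].astype(np.int16)
        gf = females.codes[female_ix[f]].astype(np.int16)
        f1 = ((gm + gf) // 2).astype(np.int8)
        f1[(gm < 0) | (gf < 0)] = -1
        hybrid_ids.append(hyb)
        rows.append(f1)
    return GenotypeMatrix(hybrid_ids, males.variants, np.vstack(rows))


def _genetic_values(
    G: GenotypeMatrix, qtl: np.ndarray, a: np.ndarray, d: np.ndarray
) -> pd.Series:
    x = G.dosages()[:, qtl]
    if np.isnan(x).any():
        raise ValueError("missing genotypes at QTL sites")
    gv = x @ a + (x == 1).astype(float) @ d
    return pd.Series(gv, index=G.sample_ids)


def simulate_phenotypes(
    parents: GenotypeMatrix,
    f1: GenotypeMatrix,
    design: NCIIDesign,
    cfg: SimConfig,
    subpop_labels: np.ndarray | None = None,
    trait: str = "trait1",
    qtl_additive: np.ndarray | None = None,
    qtl_dominance: np.ndarray | None = None,
    additive_effects: np.ndarray | None = None,
    dominance_effects: np.ndarray | None = None,
) -> tuple[PhenotypeTable, SimTruth]:
    """Simulate replicated phenotypes for male parents and F1 hybrids.

    QTL positions are drawn without replacement unless given explicitly;
    effect sizes are N(0, sd) draws unless ``additive_effects`` /
    ``dominance_effects`` (aligned with the explicit index arrays) are
    supplied.  Female testers get no phenotype records (they are
    male-sterile in the emulated trial).  The block effect of each
    replicate is shared by every entry in that replicate (randomized block
    design).
    """
    rng_q = cfg.rngs()["qtl"]
    rng_n = cfg.rngs()["noise"]
    if qtl_additive is None or qtl_dominance is None:
        n_qtl = cfg.n_qtl_additive + cfg.n_qtl_dominance
        drawn = rng_q.choice(parents.n_variants, size=n_qtl, replace=False)
        if qtl_additive is None:
            qtl_additive = drawn[: cfg.n_qtl_additive]
        if qtl_dominance is None:
            qtl_dominance = drawn[cfg.n_qtl_additive:]
    qtl_additive = np.asarray(qtl_additive, dtype=int)
    qtl_dominance = np.asarray(qtl_dominance, dtype=int)
    qtl = np.unique(np.concatenate([qtl_additive, qtl_dominance]))
    a = np.zeros(qtl.size)
    d = np.zeros(qtl.size)
    pos_of = {v: i for i, v in enumerate(qtl)}
    if additive_effects is None:
        additive_effects = rng_q.normal(0.0, cfg.additive_effect_sd, qtl_additive.size)
    if dominance_effects is None:
        dominance_effects = rng_q.normal(0.0, cfg.dominance_effect_sd, qtl_dominance.size)
    a[[pos_of[v] for v in qtl_additive]] = np.asarray(additive_effects, dtype=float)
    d[[pos_of[v] for v in qtl_dominance]] = np.asarray(dominance_effects, dtype=float)

    gv_parents = _genetic_values(parents, qtl, a, d)
    gv_f1 = _genetic_values(f1, qtl, a, d)

    # exact decomposition of the noise-free F1 genetic values
    cell = pd.DataFrame(
        np.nan, index=design.male_ids, columns=design.female_ids, dtype=float
    )
    for (m, f), hyb in design.crosses.items():
        cell.loc[m, f] = gv_f1[hyb]
    ca = compute_gca_sca(cell)
    fm, m_ = design.n_males, design.n_females
    var_male = float(np.sum(ca.gca_male_**2) / (fm - 1)) if fm > 1 else 0.0
    var_female = float(np.sum(ca.gca_female_**2) / (m_ - 1)) if m_ > 1 else 0.0
    var_sca = (
        float(np.sum(ca.sca_.to_numpy() ** 2) / ((fm - 1) * (m_ - 1)))
        if fm > 1 and m_ > 1
        else 0.0
    )
    var_error = cfg.residual_sd**2
    var_p = var_male + var_female + var_sca + var_error
    h2 = (var_male + var_female) / var_p if var_p > 0 else np.nan
    H2 = (var_male + var_female + var_sca) / var_p if var_p > 0 else np.nan

    records = []
    gv_all = pd.concat([gv_parents[design.male_ids], gv_f1])
    for rep in design.rep_labels:
        block = rng_n.normal(0.0, cfg.block_sd)
        noise = rng_n.normal(0.0, cfg.residual_sd, gv_all.size)
        vals = cfg.mean + gv_all.to_numpy() + block + noise
        records.append(
            pd.DataFrame(
                {"id": gv_all.index, "trait": trait, "rep": rep, "value": vals}
            )
        )
    pheno = PhenotypeTable(pd.concat(records, ignore_index=True))

    labels = (
        np.asarray(subpop_labels)
        if subpop_labels is not None
        else np.zeros(parents.n_samples, dtype=int)
    )
    truth = SimTruth(
        qtl_indices=qtl,
        additive_effects=a,
        dominance_effects=d,
        subpop_labels=labels,
        true_gca_males=ca.gca_male_,
        true_gca_females=ca.gca_female_,
        true_sca=ca.sca_,
        var_male=var_male,
        var_female=var_female,
        var_sca=var_sca,
        var_error=var_error,
        realized_h2=h2,
        realized_H2=H2,
        genetic_values=gv_all,
    )
    return pheno, truth


def pick_segregating_qtl(
    males: GenotypeMatrix,
    females: GenotypeMatrix,
    target_freq: float = 0.5,
    require_female_segregation: bool = True,
) -> int:
    """Index of the variant whose male-side allele frequency is nearest
    ``target_freq``, optionally restricted to variants where the female
    testers also segregate.

    A dominance QTL only shows up in SCA when the female pool segregates:
    with all testers fixed, heterozygosity in the F1 is a function of the
    male alone and the dominance deviation is absorbed into the male GCA
    margin.
    """
    p = np.nanmean(males.dosages(), axis=0) / 2.0
    ok = np.ones(males.n_variants, dtype=bool)
    if require_female_segregation:
        f = females.codes
        ok = (f == 0).any(axis=0) & (f == 2).any(axis=0)
        if not ok.any():
            raise ValueError("no variant segregates among the female testers")
    cand = np.flatnonzero(ok)
    return int(cand[np.argmin(np.abs(p[cand] - target_freq))])


@dataclass
class SimulatedDataset:
    config: SimConfig
    parents: GenotypeMatrix
    males: GenotypeMatrix
    females: GenotypeMatrix
    f1: GenotypeMatrix
    design: NCIIDesign
    phenotypes: PhenotypeTable
    truth: SimTruth
    subpop_labels: np.ndarray


def simulate_ncii_dataset(cfg: SimConfig, **pheno_kwargs) -> SimulatedDataset:
    """Full pipeline: parents -> design -> F1 -> phenotypes + truth."""
    parents, labels = simulate_parents(cfg)
    male_ids = parents.sample_ids[: cfg.n_males]
    female_ids = parents.sample_ids[cfg.n_males:]
    males = parents.take_samples(male_ids)
    females = parents.take_samples(female_ids)
    design = NCIIDesign.full_factorial(male_ids, female_ids, cfg.n_reps)
    f1 = derive_f1_genotypes(males, females, design)
    pheno, truth = simulate_phenotypes(
        parents, f1, design, cfg, subpop_labels=labels, **pheno_kwargs
    )
    return SimulatedDataset(cfg, parents, males, females, f1, design, pheno, truth, labels)


def write_dataset(ds: SimulatedDataset, outdir: str) -> None:
    """Write a simulated dataset as plain-text files (VCF, TSV, JSON)."""
    import os

    os.makedirs(outdir, exist_ok=True)
    write_vcf(ds.parents, os.path.join(outdir, "parents.vcf"))
    write_vcf(ds.f1, os.path.join(outdir, "f1.vcf"))
    ds.parents.to_tsv(os.path.join(outdir, "parents.tsv"))
    ds.f1.to_tsv(os.path.join(outdir, "f1.tsv"))
    ds.phenotypes.to_tsv(os.path.join(outdir, "phenotypes.tsv"))
    ds.design.to_frame().to_csv(os.path.join(outdir, "design.tsv"), sep="\t", index=False)
    ds.truth.to_json(os.path.join(outdir, "truth.json"))
    with open(os.path.join(outdir, "config.json"), "w") as fh:
        cfg = asdict(ds.config)
        cfg["maf_range"] = list(cfg["maf_range"])
        json.dump(cfg, fh, indent=1)
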