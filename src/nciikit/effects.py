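"""Per-locus effect characterization after an association scan.

Covers the dominance index d/a (with |d/a| > 1 flagging overdominance), the
variance in a trait explained by one locus or a set of loci, and the
accumulation of favourable alleles in the extreme tails of a GCA or SCA
ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genodata import GenotypeMatrix


@dataclass
class DominanceEffect:
    """Genotype-class means and the derived additive/dominance effects.

    ``a`` is half the difference between the homozygote class means.  Two
    d conventions are reported: ``d_population`` measures the heterozygote
    mean against the overall population mean (frequency-dependent; the
    headline value), ``d_midpoint`` against the homozygote midpoint (the
    classical dominance deviation).  ``d_over_a`` uses the population
    convention; |d/a| > 1 flags overdominance.
    """

    mean_ref: float
    mean_het: float
    mean_alt: float
    n_ref: int
    n_het: int
    n_alt: int
    a: float
    d_population: float
    d_midpoint: float
    d_over_a: float
    d_over_a_midpoint: float
    overdominant: bool
    reason: str = ""


def dominance_index(pheno: np.ndarray, genotype: np.ndarray) -> DominanceEffect:
    """Dominance index d/a of one locus.

    ``genotype`` holds raw dosage codes (0/1/2; negative or NaN = missing).
    All three genotype classes must be non-empty for d to be defined.
    a = 0 leaves the ratio undefined (NaN, with a reason).
    """
    y = np.asarray(pheno, dtype=float).ravel()
    g = np.asarray(genotype, dtype=float).ravel()
    ok = ~np.isnan(y) & ~np.isnan(g) & (g >= 0)
    y, g = y[ok], g[ok]
    means, counts = [], []
    for c in (0, 1, 2):
        sel = g == c
        counts.append(int(sel.sum()))
        means.append(float(y[sel].mean()) if sel.any() else np.nan)
    reason = ""
    if 0 in counts:
        reason = "empty genotype class"
    a = (means[2] - means[0]) / 2.0 if counts[0] and counts[2] else np.nan
    d_pop = means[1] - float(y.mean()) if counts[1] else np.nan
    d_mid = (
        means[1] - (means[0] + means[2]) / 2.0
        if counts[1] and counts[0] and counts[2]
        else np.nan
    )
    if a == 0:
        reason = reason or "zero additive effect"
        ratio = ratio_mid = np.nan
    else:
        ratio = d_pop / a
        ratio_mid = d_mid / a
    return DominanceEffect(
        mean_ref=means[0],
        mean_het=means[1],
        mean_alt=means[2],
        n_ref=counts[0],
        n_het=counts[1],
        n_alt=counts[2],
        a=a,
        d_population=d_pop,
        d_midpoint=d_mid,
        d_over_a=ratio,
        d_over_a_midpoint=ratio_mid,
        overdominant=bool(np.abs(ratio) > 1) if np.isfinite(ratio) else False,
        reason=reason,
    )


@dataclass
class LocusEffect:
    variant_ids: list
    r2_single: dict
    r2_joint: float


def variance_explained(
    pheno: np.ndarray,
    genotypes: np.ndarray,
    variant_ids: list | None = None,
    encoding: str = "dosage",
) -> LocusEffect:
    """Trait variance explained by one locus or jointly by a set.

    A single locus reports the squared Pearson correlation between dosage
    and phenotype.  A set reports the R^2 of the joint least-squares fit —
    on the dosage columns by default (so a one-member set reproduces the
    single-locus r^2 exactly), or on genotype-class indicator columns with
    ``encoding="indicator"``.
    """
    y = np.asarray(pheno, dtype=float).ravel()
    G = np.asarray(genotypes, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    n, k = G.shape
    if variant_ids is None:
        variant_ids = list(range(k))
    ok = ~np.isnan(y) & ~np.isnan(G).any(axis=1) & (G >= 0).all(axis=1)
    y, G = y[ok], G[ok]
    n = y.size
    if np.std(y) == 0:
        raise ValueError("phenotype is constant")
    r2_single = {}
    for j, vid in enumerate(variant_ids):
        col = G[:, j]
        if np.std(col) == 0:
            raise ValueError(f"genotype column {vid!r} is constant")
        r2_single[vid] = float(np.corrcoef(col, y)[0, 1] ** 2)
    if encoding == "indicator":
        cols = []
        for j in range(k):
            for c in (1, 2):
                ind = (G[:, j] == c).astype(float)
                if ind.std() > 0:
                    cols.append(ind)
        Xd = np.column_stack(cols) if cols else np.empty((n, 0))
    elif encoding == "dosage":
        Xd = G
    else:
        raise ValueError("encoding must be 'dosage' or 'indicator'")
    if n < Xd.shape[1] + 2:
        raise ValueError("too few observations for the joint fit")
    Xfull = np.column_stack([np.ones(n), Xd])
    beta, *_ = np.linalg.lstsq(Xfull, y, rcond=None)
    resid = y - Xfull @ beta
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2_joint = 1.0 - float(np.sum(resid**2)) / ss_tot
    return LocusEffect(list(variant_ids), r2_single, r2_joint)


def allele_accumulation(
    scores: pd.Series,
    G: GenotypeMatrix,
    loci: list[int],
    top_n: int,
    bottom_n: int,
    favourable: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Genotype frequencies of chosen loci in the score extremes.

    ``scores`` maps sample id to a GCA/SCA value; ids are ranked descending
    (ties broken by id for determinism) and the top/bottom groups compared.
    ``favourable`` names the favourable allele per locus ("alt" or "ref",
    default "alt"); the table reports genotype-class frequencies (within
    non-missing calls) and the mean favourable-allele count per group, plus
    the top-minus-bottom difference.
    """
    scores = scores.dropna()
    if top_n + bottom_n > scores.size:
        raise ValueError("top_n + bottom_n exceeds the number of scored ids")
    order = scores.to_frame("score")
    order["_id"] = order.index.astype(str)
    order = order.sort_values(["score", "_id"], ascending=[False, True])
    groups = {
        "top": list(order.index[:top_n]),
        "bottom": list(order.index[-bottom_n:]),
    }
    favourable = favourable or {}
    rows = []
    sample_ix = {s: i for i, s in enumerate(G.sample_ids)}
    for locus in loci:
        if not 0 <= locus < G.n_variants:
            raise KeyError(f"locus index {locus} absent from genotype matrix")
        fav = favourable.get(locus, "alt")
        var = G.variants.iloc[locus]
        for gname, ids in groups.items():
            try:
                codes = np.array([G.codes[sample_ix[s], locus] for s in ids])
            except KeyError as exc:
                raise KeyError(f"sample {exc.args[0]!r} absent from genotypes")
            nonmiss = codes[codes >= 0]
            ntot = nonmiss.size
            counts = {c: int(np.sum(nonmiss == c)) for c in (0, 1, 2)}
            fav_dosage = (
                float(np.mean(nonmiss)) if fav == "alt" else float(np.mean(2 - nonmiss))
            ) if ntot else np.nan
            rows.append(
                {
                    "locus": locus,
                    "chrom": var["chrom"],
                    "pos": var["pos"],
                    "group": gname,
                    "n": ntot,
                    "n_ref": counts[0],
                    "n_het": counts[1],
                    "n_alt": counts[2],
                    "freq_ref": counts[0] / ntot if ntot else np.nan,
                    "freq_het": counts[1] / ntot if ntot else np.nan,
                    "freq_alt": counts[2] / ntot if ntot else np.nan,
                    "favourable": fav,
                    "mean_favourable_count": fav_dosage,
                }
            )
    tab = pd.DataFrame(rows)
    piv = tab.pivot(index="locus", columns="group", values="mean_favourable_count")
    diff = (piv["top"] - piv["bottom"]).rename("favourable_count_diff")
    return tab.merge(diff, left_on="locus", right_index=True)
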