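"""Population structure and linkage-disequilibrium summaries.

These provide the GWAS covariates: identity-by-state kinship (the fraction
of shared SNP alleles between two samples) and principal components of the
centered genotype matrix, plus a binned LD-decay curve of pairwise r^2
against physical distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .genodata import GenotypeMatrix


def kinship_ibs(G: GenotypeMatrix) -> pd.DataFrame:
    """Identity-by-state kinship: mean allele-sharing fraction per site.

    For dosages g_s, g_t in {0,1,2} the per-site sharing is
    (2 - |g_s - g_t|)/2, averaged over variants non-missing in both
    samples.  A pair with no shared non-missing variant gets NaN.
    """
    if G.n_samples < 2:
        raise ValueError("kinship needs >=2 samples")
    codes = G.codes
    # one-hot planes; sharing = sum of same-class matches + half-matches
    planes = [(codes == c).astype(float) for c in (0, 1, 2)]
    nonmiss = (codes >= 0).astype(float)
    shared = sum(p @ p.T for p in planes)
    half = planes[0] @ planes[1].T + planes[1] @ planes[2].T
    shared = shared + 0.5 * (half + half.T)
    denom = nonmiss @ nonmiss.T
    with np.errstate(invalid="ignore", divide="ignore"):
        K = np.where(denom > 0, shared / denom, np.nan)
    return pd.DataFrame(K, index=G.sample_ids, columns=G.sample_ids)


class GenotypePCA(BaseEstimator, TransformerMixin):
    """Principal components of a genotype matrix via plain SVD.

    Columns (variants) are mean-centered but not variance-scaled.  Scores
    are left singular vectors times singular values.  Each component is
    oriented so that its largest-|loading| entry is positive, making signs
    reproducible across linear-algebra backends.

    Attributes: ``components_`` (n_components x n_variants), ``scores_``
    (fitted-sample scores), ``explained_variance_ratio_``, ``mean_``.
    """

    def __init__(self, n_components: int = 5):
        self.n_components = n_components

    def fit(self, X: np.ndarray, y=None) -> "GenotypePCA":
        X = np.asarray(X, dtype=float)
        if np.isnan(X).any():
            raise ValueError(
                "missing genotypes present; subset to complete variants first"
            )
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        k = min(self.n_components, s.size)
        # orient: largest-|loading| entry of each component positive
        for i in range(k):
            j = int(np.argmax(np.abs(Vt[i])))
            if Vt[i, j] < 0:
                Vt[i] *= -1
                U[:, i] *= -1
        self.components_ = Vt[:k]
        self.singular_values_ = s[:k]
        self.scores_ = U[:, :k] * s[:k]
        total = float(np.sum(s**2))
        self.explained_variance_ratio_ = (
            s[:k] ** 2 / total if total > 0 else np.full(k, np.nan)
        )
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) @ self.components_.T


def pca_genotypes(G: GenotypeMatrix, n_components: int = 5) -> GenotypePCA:
    """Fit :class:`GenotypePCA` on the complete-call dosage matrix of ``G``."""
    d = G.dosages()
    complete = ~np.isnan(d).any(axis=0)
    return GenotypePCA(n_components=n_components).fit(d[:, complete])


@dataclass
class LDDecayCurve:
    """Mean pairwise r^2 per physical-distance bin.

    ``decay_distance`` is the midpoint of the first bin whose mean r^2
    falls below the threshold, or ``inf`` when no bin does within the
    window examined.
    """

    bins: pd.DataFrame  # columns: dist_lo, dist_hi, mean_r2, n_pairs
    r2_threshold: float
    decay_distance: float


def ld_decay(
    G: GenotypeMatrix,
    max_dist_bp: int = 1_000_000,
    bin_width_bp: int = 10_000,
    r2_threshold: float = 0.2,
) -> LDDecayCurve:
    """LD decay from squared Pearson correlation of genotype dosages.

    All within-chromosome variant pairs up to ``max_dist_bp`` apart enter;
    pairs involving a monomorphic variant are skipped.  This is the
    unphased-dosage r^2 (identical to haplotype r^2 for fully homozygous
    samples).  Missing calls are mean-imputed per variant.
    """
    n_bins = -(-max_dist_bp // bin_width_bp)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for chrom, sub in G.variants.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        d = G.dosages()[:, idx]
        mu = np.nanmean(d, axis=0)
        nanmask = np.isnan(d)
        if nanmask.any():
            d = np.where(nanmask, np.broadcast_to(mu, d.shape), d)
        sd = d.std(axis=0)
        poly = sd > 0
        if poly.sum() < 2:
            continue
        d = d[:, poly]
        pos = sub["pos"].to_numpy()[poly]
        r = np.corrcoef(d, rowvar=False)
        m = len(pos)
        iu, ju = np.triu_indices(m, k=1)
        dist = pos[ju] - pos[iu]
        ok = dist <= max_dist_bp
        b = (dist[ok] - 1) // bin_width_bp
        np.add.at(sums, b, r[iu[ok], ju[ok]] ** 2)
        np.add.at(counts, b, 1)
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    lo = np.arange(n_bins) * bin_width_bp
    hi = lo + bin_width_bp
    bins = pd.DataFrame(
        {"dist_lo": lo, "dist_hi": hi, "mean_r2": mean_r2, "n_pairs": counts}
    )
    decay = math.inf
    for _, row in bins.dropna(subset=["mean_r2"]).iterrows():
        if row["mean_r2"] < r2_threshold:
            decay = float((row["dist_lo"] + row["dist_hi"]) / 2)
            break
    return LDDecayCurve(bins=bins, r2_threshold=r2_threshold, decay_distance=decay)
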