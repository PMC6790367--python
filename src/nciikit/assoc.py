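"""Q+K linear mixed-model association scans.

The model for a trait y (parental trait, parental GCA, hybrid trait or
hybrid SCA) is

    y = X b + u + e,   u ~ N(0, sigma_g^2 K),   e ~ N(0, sigma_e^2 I)

with X an intercept plus the top principal components (the Q covariates)
and K the identity-by-state kinship.  The variance components are estimated
once by REML on the null model through a single eigendecomposition of K and
a one-dimensional search over the ratio delta = sigma_e^2/sigma_g^2; every
variant is then tested by generalized least squares with the covariance
held fixed — the EMMAX approximation.  An exact mode refitting the variance
components per variant is available for small-instance cross-checks.

Genotype encodings: *additive* leaves the 0/1/2 dosage untouched;
*dominant* recodes heterozygotes as alt homozygotes (1 -> 2, the alt allele
acts dominantly); *recessive* recodes them as ref homozygotes (1 -> 0).
The nonadditive encodings are what give a scan of SCA power, since SCA
reflects nonadditive gene action that an additive dosage cannot capture.

Multiple testing uses a Bonferroni correction at nominal level alpha with
the total SNP count M replaced by the effective number of independent SNPs
Me, computed from eigenvalues of windowed variant correlation matrices
(Li-Ji-family rule).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .genodata import GenotypeMatrix, NCIIDesign, PhenotypeTable, filter_variants
from .quantgen import cell_mean_table, compute_gca_sca, trait_matrix
from .structure import GenotypePCA, kinship_ibs

logger = logging.getLogger(__name__)

ENCODINGS = ("additive", "dominant", "recessive")


def encode_model(codes: np.ndarray, model: str) -> np.ndarray:
    """Re-encode genotype codes for a dominance model.

    additive: identity.  dominant: het -> 2 (alt acts dominant).
    recessive: het -> 0 (alt acts recessive).  Missing codes (<0 or NaN)
    are preserved.
    """
    if model not in ENCODINGS:
        raise ValueError(f"unknown model {model!r}; choose from {ENCODINGS}")
    out = np.array(codes, copy=True)
    if model == "additive":
        return out
    het = out == 1
    out[het] = 2 if model == "dominant" else 0
    return out


@dataclass
class LMMNullFit:
    """REML fit of the variance components under the null model."""

    sigma_g2: float
    sigma_e2: float
    delta: float  # sigma_e2 / sigma_g2
    reml_loglik: float
    eigenvalues: np.ndarray = field(repr=False)
    rotation: np.ndarray = field(repr=False)  # eigenvectors of K, columns


def _reml_loglik_parts(logdelta: float, lam: np.ndarray, yr: np.ndarray, Xr: np.ndarray):
    """Profiled REML log-likelihood at delta = exp(logdelta).

    lam/yr/Xr are the K-eigenvalues and the spectrally rotated y and X.
    Returns (loglik, sigma_g2_hat, beta_hat).
    """
    delta = math.exp(logdelta)
    n, p = Xr.shape
    w = 1.0 / (lam + delta)
    Xw = Xr * w[:, None]
    XtWX = Xr.T @ Xw
    XtWy = Xw.T @ yr
    beta = np.linalg.solve(XtWX, XtWy)
    resid = yr - Xr @ beta
    rss = float(np.sum(w * resid**2))
    sigma_g2 = rss / (n - p)
    sign, logdet_xwx = np.linalg.slogdet(XtWX)
    _, logdet_xx = np.linalg.slogdet(Xr.T @ Xr)
    ll = 0.5 * (
        (n - p) * (math.log((n - p) / (2 * math.pi)) - 1 - math.log(rss))
        - float(np.sum(np.log(lam + delta)))
        + logdet_xx
        - logdet_xwx
    )
    return ll, sigma_g2, beta


def fit_null_lmm(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray,
    grid: tuple[float, float, int] = (-10.0, 10.0, 100),
    tol: float = 1e-6,
) -> LMMNullFit:
    """REML variance components via eigendecomposition of K.

    The restricted likelihood is profiled down to the ratio
    delta = sigma_e^2/sigma_g^2 and maximised over log(delta) on a grid
    refined by golden-section search.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    K = np.asarray(K, dtype=float)
    n = y.size
    if np.ptp(y) == 0:
        raise ValueError("phenotype is constant")
    p = np.linalg.matrix_rank(X)
    if n < p + 2:
        raise ValueError("need n >= rank(X) + 2 observations")
    if not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("K must be symmetric")
    lam, U = np.linalg.eigh(K)
    if lam.min() < -1e-6 * max(1.0, lam.max()):
        raise ValueError("K is not positive semi-definite")
    lam = np.clip(lam, 0.0, None)
    yr = U.T @ y
    Xr = U.T @ X

    lo, hi, npts = grid
    gridpts = np.linspace(lo, hi, int(npts))
    vals = np.array([_reml_loglik_parts(g, lam, yr, Xr)[0] for g in gridpts])
    i = int(np.argmax(vals))
    best = float(gridpts[i])
    # refine only when the grid optimum is strictly interior; a flat
    # likelihood (e.g. K = I, where only the total variance is identified)
    # admits no bracket and the grid point is already optimal
    if 0 < i < len(gridpts) - 1 and vals[i] > vals[i - 1] and vals[i] > vals[i + 1]:
        try:
            res = optimize.minimize_scalar(
                lambda g: -_reml_loglik_parts(g, lam, yr, Xr)[0],
                bracket=(gridpts[i - 1], gridpts[i], gridpts[i + 1]),
                method="golden",
                options={"xtol": tol},
            )
            if -res.fun >= vals[i]:
                best = float(res.x)
        except ValueError:
            pass
    ll, sigma_g2, _ = _reml_loglik_parts(best, lam, yr, Xr)
    delta = math.exp(best)
    return LMMNullFit(
        sigma_g2=sigma_g2,
        sigma_e2=sigma_g2 * delta,
        delta=delta,
        reml_loglik=ll,
        eigenvalues=lam,
        rotation=U,
    )


def reml_loglik(nullfit_or_K, y, X, sigma_g2: float, sigma_e2: float) -> float:
    """Restricted log-likelihood at arbitrary (sigma_g2, sigma_e2).

    Used to verify optimality of the fitted point.  Accepts either an
    :class:`LMMNullFit` (reusing its rotation) or a kinship matrix.
    """
    if isinstance(nullfit_or_K, LMMNullFit):
        lam, U = nullfit_or_K.eigenvalues, nullfit_or_K.rotation
    else:
        lam, U = np.linalg.eigh(np.asarray(nullfit_or_K, dtype=float))
        lam = np.clip(lam, 0.0, None)
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    yr, Xr = U.T @ y, U.T @ X
    v = sigma_g2 * lam + sigma_e2
    if np.any(v <= 0):
        return -math.inf
    w = 1.0 / v
    XtWX = Xr.T @ (Xr * w[:, None])
    beta = np.linalg.solve(XtWX, (Xr * w[:, None]).T @ yr)
    resid = yr - Xr @ beta
    _, logdet_xwx = np.linalg.slogdet(XtWX)
    _, logdet_xx = np.linalg.slogdet(Xr.T @ Xr)
    return 0.5 * (
        -(n - p) * math.log(2 * math.pi)
        - float(np.sum(np.log(v)))
        - float(np.sum(w * resid**2))
        + logdet_xx
        - logdet_xwx
    )


def scan(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray,
    G_encoded: np.ndarray,
    nullfit: LMMNullFit | None = None,
    exact: bool = False,
) -> pd.DataFrame:
    """Per-variant generalized least squares with Sigma fixed from the null.

    Returns a DataFrame with beta, se, stat (t), p and a ``reason`` column
    for skipped variants (zero variance after encoding, or collinear with
    the covariates).  ``exact=True`` refits the variance components per
    variant instead of reusing the null fit.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    G_encoded = np.asarray(G_encoded, dtype=float)
    n, M = G_encoded.shape
    if y.size != n or X.shape[0] != n:
        raise ValueError("dimension mismatch between y, X and genotypes")
    # mean-impute missing encoded genotypes
    if np.isnan(G_encoded).any():
        mu = np.nanmean(G_encoded, axis=0)
        ix = np.where(np.isnan(G_encoded))
        G_encoded = G_encoded.copy()
        G_encoded[ix] = np.take(mu, ix[1])
    G_encoded[G_encoded < 0] = np.nan  # stray sentinel guard
    if np.isnan(G_encoded).any():
        mu = np.nanmean(G_encoded, axis=0)
        ix = np.where(np.isnan(G_encoded))
        G_encoded[ix] = np.take(mu, ix[1])

    if exact:
        return _scan_exact(y, X, K, G_encoded)
    if nullfit is None:
        nullfit = fit_null_lmm(y, X, K)
    lam, U = nullfit.eigenvalues, nullfit.rotation
    v = nullfit.sigma_g2 * lam + nullfit.sigma_e2
    sw = 1.0 / np.sqrt(v)
    yt = sw * (U.T @ y)
    Xt = sw[:, None] * (U.T @ X)
    Gt = sw[:, None] * (U.T @ G_encoded)
    rank_x = np.linalg.matrix_rank(Xt)
    Q, _ = np.linalg.qr(Xt)
    y_perp = yt - Q @ (Q.T @ yt)
    G_perp = Gt - Q @ (Q.T @ Gt)
    gg = np.sum(G_perp**2, axis=0)
    gy = G_perp.T @ y_perp
    df = n - rank_x - 1
    yy = float(y_perp @ y_perp)

    tol = 1e-10 * max(1.0, float(np.max(gg, initial=0.0)))
    ok = gg > tol
    beta = np.full(M, np.nan)
    se = np.full(M, np.nan)
    tstat = np.full(M, np.nan)
    pval = np.full(M, np.nan)
    beta[ok] = gy[ok] / gg[ok]
    rss = np.maximum(yy - beta[ok] ** 2 * gg[ok], 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se[ok] = np.sqrt(rss / df / gg[ok])
        tstat[ok] = beta[ok] / se[ok]
    pval[ok] = 2.0 * stats.t.sf(np.abs(tstat[ok]), df)
    pval[ok] = np.clip(pval[ok], np.finfo(float).tiny, 1.0)
    reason = np.where(ok, "", "zero-variance-or-collinear")
    n_skipped = int((~ok).sum())
    if n_skipped:
        logger.info("scan: skipped %d degenerate variants", n_skipped)
    return pd.DataFrame(
        {"beta": beta, "se": se, "stat": tstat, "p": pval, "reason": reason}
    )


def _scan_exact(y, X, K, G) -> pd.DataFrame:
    """Per-variant REML refit (slow; cross-validation of the approximation)."""
    rows = []
    n = y.size
    for j in range(G.shape[1]):
        g = G[:, j]
        Xj = np.column_stack([X, g])
        if np.linalg.matrix_rank(Xj) <= np.linalg.matrix_rank(X):
            rows.append((np.nan, np.nan, np.nan, np.nan, "zero-variance-or-collinear"))
            continue
        fit = fit_null_lmm(y, Xj, K)
        lam, U = fit.eigenvalues, fit.rotation
        w = 1.0 / (fit.sigma_g2 * lam + fit.sigma_e2)
        Xr = U.T @ Xj
        yr = U.T @ y
        XtWX = Xr.T @ (Xr * w[:, None])
        beta_all = np.linalg.solve(XtWX, (Xr * w[:, None]).T @ yr)
        cov = np.linalg.inv(XtWX)
        b = float(beta_all[-1])
        s = float(np.sqrt(cov[-1, -1]))
        df = n - np.linalg.matrix_rank(X) - 1
        t = b / s
        p = 2.0 * float(stats.t.sf(abs(t), df))
        rows.append((b, s, t, max(p, np.finfo(float).tiny), ""))
    return pd.DataFrame(rows, columns=["beta", "se", "stat", "p", "reason"])


def effective_snp_count(
    G: GenotypeMatrix | np.ndarray,
    window_size: int = 1000,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Effective number of independent SNPs and the derived threshold.

    Within each non-overlapping window of ``window_size`` variants the
    eigenvalues lambda of the variant correlation matrix are converted to
    an effective count via f(lambda) = 1[lambda >= 1] + (lambda - floor
    (lambda)) and summed; window counts add up to Me and the genome-wide
    threshold is alpha / Me.  Monomorphic variants carry no test and
    contribute nothing; a window with a single polymorphic variant
    contributes 1.
    """
    d = G.dosages() if isinstance(G, GenotypeMatrix) else np.asarray(G, dtype=float)
    if d.shape[1] < 1:
        raise ValueError("need at least one variant")
    if np.isnan(d).any():
        mu = np.nanmean(d, axis=0)
        ix = np.where(np.isnan(d))
        d = d.copy()
        d[ix] = np.take(mu, ix[1])
    me = 0.0
    for start in range(0, d.shape[1], window_size):
        block = d[:, start : start + window_size]
        poly = block.std(axis=0) > 0
        block = block[:, poly]
        m = block.shape[1]
        if m == 0:
            continue
        if m == 1:
            me += 1.0
            continue
        corr = np.corrcoef(block, rowvar=False)
        lam = np.clip(np.linalg.eigvalsh(corr), 0.0, None)
        # snap near-integer eigenvalues so floor() is numerically stable
        nearint = np.round(lam)
        lam = np.where(np.abs(lam - nearint) < 1e-8, nearint, lam)
        me += float(np.sum((lam >= 1).astype(float) + lam - np.floor(lam)))
    me = max(me, 1.0)
    return me, alpha / me


class MixedModelScan(BaseEstimator):
    """EMMAX-style Q+K mixed-model scan as an sklearn estimator.

    Parameters
    ----------
    encoding : {"additive", "dominant", "recessive"}
    n_pcs : int
        Number of genotype principal components used as fixed covariates.
    me_window : int
        Window (in variants) for the effective-test-count computation.
    alpha : float
        Nominal genome-wide level for the Me-Bonferroni threshold.
    exact : bool
        Refit variance components per variant (slow; for cross-checks).

    After ``fit(G, y)``: ``results_`` (per-variant table with chrom, pos,
    encoding, beta, se, stat, p, maf), ``m_``, ``me_``, ``threshold_``,
    ``nullfit_``, ``kinship_``, ``pca_``.
    """

    def __init__(
        self,
        encoding: str = "additive",
        n_pcs: int = 5,
        me_window: int = 1000,
        alpha: float = 0.05,
        exact: bool = False,
    ):
        self.encoding = encoding
        self.n_pcs = n_pcs
        self.me_window = me_window
        self.alpha = alpha
        self.exact = exact

    def fit(
        self,
        G: GenotypeMatrix,
        y: np.ndarray | pd.Series,
        K: pd.DataFrame | np.ndarray | None = None,
        covariates: np.ndarray | None = None,
    ) -> "MixedModelScan":
        if isinstance(y, pd.Series):
            y = y.reindex(G.sample_ids).to_numpy(float)
        y = np.asarray(y, dtype=float).ravel()
        if y.size != G.n_samples:
            raise ValueError("phenotype length does not match sample count")
        keep = ~np.isnan(y)
        if not keep.all():
            G = G.take_samples([s for s, k in zip(G.sample_ids, keep) if k])
            y = y[keep]

        if K is None:
            K = kinship_ibs(G)
        Kmat = K.to_numpy(float) if isinstance(K, pd.DataFrame) else np.asarray(K, float)

        d = G.dosages()
        if covariates is None and self.n_pcs > 0:
            complete = ~np.isnan(d).any(axis=0)
            self.pca_ = GenotypePCA(n_components=self.n_pcs).fit(d[:, complete])
            covariates = self.pca_.scores_
        X = np.ones((G.n_samples, 1))
        if covariates is not None and covariates.size:
            X = np.column_stack([X, covariates])

        enc = encode_model(d, self.encoding)
        self.nullfit_ = fit_null_lmm(y, X, Kmat)
        res = scan(y, X, Kmat, enc, self.nullfit_, exact=self.exact)
        res.insert(0, "chrom", G.variants["chrom"].to_numpy())
        res.insert(1, "pos", G.variants["pos"].to_numpy())
        res.insert(2, "encoding", self.encoding)
        res["maf"] = G.maf()
        self.m_ = G.n_variants
        self.me_, self.threshold_ = effective_snp_count(
            G, window_size=self.me_window, alpha=self.alpha
        )
        self.results_ = res
        self.kinship_ = Kmat
        return self


# -- scan targets ---------------------------------------------------------

TARGETS = ("parent-trait", "parent-gca", "f1-trait", "f1-sca")


@dataclass
class AssocResult:
    """One association scan: per-variant table plus scan-level metadata."""

    target: str
    encoding: str
    trait: str
    results: pd.DataFrame
    m: int
    me: float
    threshold: float
    nullfit: LMMNullFit


def _target_phenotype(
    target: str,
    pheno: PhenotypeTable,
    design: NCIIDesign,
    trait: str,
) -> tuple[pd.Series, str]:
    """Build the scanned trait vector for a pipeline target.

    Returns (series indexed by sample id, which-genotypes flag).  GCA scans
    use the male parents only: with a handful of female testers the female
    GCA has too few levels to scan, so it is absorbed into the decomposition
    and the male GCA is the new trait of each male parent.  SCA scans give
    each hybrid the SCA of its cross as its trait value.
    """
    if target == "parent-trait":
        means = trait_matrix(pheno, "mean")[trait]
        return means.reindex(design.male_ids), "parents"
    if target == "parent-gca":
        ca = compute_gca_sca(cell_mean_table(pheno, design, trait))
        return ca.gca_male_.reindex(design.male_ids), "parents"
    if target == "f1-trait":
        means = trait_matrix(pheno, "mean")[trait]
        return means.reindex(design.hybrid_ids()), "f1"
    if target == "f1-sca":
        ca = compute_gca_sca(cell_mean_table(pheno, design, trait))
        sca = {
            h: ca.sca_.loc[m, f] for (m, f), h in design.crosses.items()
        }
        return pd.Series(sca).reindex(design.hybrid_ids()), "f1"
    raise ValueError(f"unknown target {target!r}; choose from {TARGETS}")


def gwas_pipeline(
    G_parents: GenotypeMatrix,
    G_f1: GenotypeMatrix,
    pheno: PhenotypeTable,
    design: NCIIDesign,
    targets: list[tuple[str, str]],
    trait: str,
    maf_min: float = 0.05,
    missing_max: float = 0.15,
    n_pcs: int = 5,
    me_window: int = 1000,
    alpha: float = 0.05,
    sca_on_parents: bool = False,
) -> dict[tuple[str, str], AssocResult]:
    """Run Q+K scans for a set of (target, encoding) pairs.

    Parent-side scans (traits and GCA) use the male-parent genotypes;
    F1-side scans (traits and SCA) use the derived hybrid genotypes.
    ``sca_on_parents=True`` switches F1 targets onto the male-parent
    genotypes instead (each hybrid keeps its own trait value but carries
    its male parent's genotype row) — for designs where hybrid genotypes
    are unavailable; note the dominance encodings are then inert, since
    inbred parents carry no heterozygotes.
    """
    males = G_parents.take_samples(design.male_ids)
    filtered = {
        "parents": filter_variants(males, maf_min, missing_max),
        "f1": filter_variants(G_f1, maf_min, missing_max),
    }
    out: dict[tuple[str, str], AssocResult] = {}
    for target, encoding in targets:
        yser, which = _target_phenotype(target, pheno, design, trait)
        if which == "f1" and sca_on_parents:
            fp = filtered["parents"]
            parents_of = design.parents_of()
            row_of = {s: i for i, s in enumerate(fp.sample_ids)}
            hybrids = design.hybrid_ids()
            rows = np.array([row_of[parents_of[h][0]] for h in hybrids])
            G = GenotypeMatrix(hybrids, fp.variants, fp.codes[rows])
        else:
            G = filtered[which]
        est = MixedModelScan(
            encoding=encoding, n_pcs=n_pcs, me_window=me_window, alpha=alpha
        ).fit(G, yser)
        out[(target, encoding)] = AssocResult(
            target=target,
            encoding=encoding,
            trait=trait,
            results=est.results_,
            m=est.m_,
            me=est.me_,
            threshold=est.threshold_,
            nullfit=est.nullfit_,
        )
    return out


def genomic_inflation(pvalues: np.ndarray) -> float:
    """Genomic-control lambda: median association chi2 over its null median."""
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.isf(0.5, df=1))
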