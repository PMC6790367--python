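"""NCII combining-ability statistics.

A North Carolina design II crosses every one of f male lines with every one
of m female (tester) lines; the mf hybrids are grown in r replicated blocks.
The hybrid phenotype decomposes as

    Y_ij = Y + G_i + G_j + S_ij

where G_i and G_j are the general combining abilities (GCA) of the male and
female parents — their mean hybrid performance expressed as a deviation from
the grand mean — and S_ij is the specific combining ability (SCA) of the
cross, the residual interaction.  GCA variance reflects additive gene
action, SCA variance nonadditive gene action.

The two-factor ANOVA with a replications stratum yields mean squares whose
expectations under the random-effects model are

    E[MS_males]   = sigma_e^2 + r*sigma_sca^2 + r*m*sigma_male^2
    E[MS_females] = sigma_e^2 + r*sigma_sca^2 + r*f*sigma_female^2
    E[MS_mxf]     = sigma_e^2 + r*sigma_sca^2
    E[MS_error]   = sigma_e^2

solved by method of moments.  Narrow-sense heritability is
h^2 = (sigma_male^2 + sigma_female^2) / sigma_P^2 and broad-sense
H^2 = sigma_G^2 / sigma_P^2 with sigma_G^2 the sum of the three genetic
components and sigma_P^2 = sigma_G^2 + sigma_e^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .genodata import NCIIDesign, PhenotypeTable, trait_matrix

ANOVA_SOURCES = ["replications", "males", "females", "males_x_females", "error"]


class UnbalancedDesignError(ValueError):
    """Raised when the EMS pathway is requested on unbalanced data.

    Variance components via expected mean squares require a complete design
    with equal replication.  For unbalanced data use the cell-mean GCA/SCA
    decomposition (:func:`compute_gca_sca`) only.
    """


@dataclass
class VarianceComponents:
    """Method-of-moments variance components for one trait.

    All components are in squared trait units; h2/H2 are unitless.
    ``negative_flag`` marks estimates that came out negative (reported raw
    unless truncation was requested).
    """

    var_female: float  # additive variance among female parents
    var_male: float  # additive variance among male parents
    var_sca: float  # nonadditive male x female interaction variance
    var_error: float  # environmental (within-plot) variance
    var_genetic: float
    var_phenotypic: float
    h2: float  # narrow-sense heritability
    H2: float  # broad-sense heritability
    divisor_male: float
    divisor_female: float
    negative_flag: bool = False

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "var_female": self.var_female,
                "var_male": self.var_male,
                "var_sca": self.var_sca,
                "var_error": self.var_error,
                "var_genetic": self.var_genetic,
                "var_phenotypic": self.var_phenotypic,
                "h2": self.h2,
                "H2": self.H2,
            }
        )


class NCIIAnova(BaseEstimator):
    """Balanced two-factor ANOVA (with replications stratum) for an NCII trial.

    Parameters
    ----------
    truncate_negative : bool, default False
        Truncate negative method-of-moments variance components at zero.

    Attributes
    ----------
    anova_ : pandas.DataFrame
        Sources x (df, ss, ms, F, p).  F for males and females uses the
        interaction mean square as denominator; F for the interaction and
        the replications stratum uses the error mean square.
    r_, m_, f_ : int
        Replications, number of females, number of males.
    variance_components_ : VarianceComponents
    """

    def __init__(self, truncate_negative: bool = False):
        self.truncate_negative = truncate_negative

    def fit(self, X: pd.DataFrame, y=None) -> "NCIIAnova":
        """Fit from a tidy frame with columns male, female, rep, value."""
        df = X.dropna(subset=["value"])
        males = sorted(pd.unique(df["male"]))
        females = sorted(pd.unique(df["female"]))
        reps = sorted(pd.unique(df["rep"]))
        f, m, r = len(males), len(females), len(reps)
        if f < 2 or m < 2 or r < 2:
            raise ValueError("need >=2 males, >=2 females and >=2 replications")
        counts = df.groupby(["male", "female", "rep"], sort=False).size()
        if len(counts) != f * m * r or (counts != 1).any():
            raise UnbalancedDesignError(
                "design is unbalanced (incomplete cells or unequal replication); "
                "expected-mean-square components are undefined — use the "
                "cell-mean GCA/SCA decomposition (compute_gca_sca) instead"
            )

        y_all = df["value"].to_numpy(float)
        grand = y_all.mean()
        ss_total = float(np.sum((y_all - grand) ** 2))
        mean_male = df.groupby("male")["value"].mean()
        mean_female = df.groupby("female")["value"].mean()
        mean_rep = df.groupby("rep")["value"].mean()
        mean_cell = df.groupby(["male", "female"])["value"].mean()

        ss_males = r * m * float(np.sum((mean_male - grand) ** 2))
        ss_females = r * f * float(np.sum((mean_female - grand) ** 2))
        ss_reps = m * f * float(np.sum((mean_rep - grand) ** 2))
        # interaction: cell mean minus both margins plus grand mean
        cell = mean_cell.unstack()
        inter = (
            cell.to_numpy()
            - mean_male.reindex(cell.index).to_numpy()[:, None]
            - mean_female.reindex(cell.columns).to_numpy()[None, :]
            + grand
        )
        ss_mxf = r * float(np.sum(inter**2))
        ss_error = ss_total - ss_males - ss_females - ss_mxf - ss_reps
        ss_error = max(ss_error, 0.0)

        df_rep = r - 1
        df_males = f - 1
        df_females = m - 1
        df_mxf = (m - 1) * (f - 1)
        df_error = (r - 1) * (m * f - 1)

        ss = dict(
            replications=ss_reps,
            males=ss_males,
            females=ss_females,
            males_x_females=ss_mxf,
            error=ss_error,
        )
        dfs = dict(
            replications=df_rep,
            males=df_males,
            females=df_females,
            males_x_females=df_mxf,
            error=df_error,
        )
        ms = {k: ss[k] / dfs[k] for k in ss}

        def f_test(num: str, den: str) -> tuple[float, float]:
            if ms[den] <= 0:
                return (np.nan, np.nan)
            fstat = ms[num] / ms[den]
            p = float(stats.f.sf(fstat, dfs[num], dfs[den]))
            return (fstat, p)

        fstats = {
            "replications": f_test("replications", "error"),
            "males": f_test("males", "males_x_females"),
            "females": f_test("females", "males_x_females"),
            "males_x_females": f_test("males_x_females", "error"),
            "error": (np.nan, np.nan),
        }
        self.anova_ = pd.DataFrame(
            {
                "df": [dfs[s] for s in ANOVA_SOURCES],
                "ss": [ss[s] for s in ANOVA_SOURCES],
                "ms": [ms[s] for s in ANOVA_SOURCES],
                "F": [fstats[s][0] for s in ANOVA_SOURCES],
                "p": [fstats[s][1] for s in ANOVA_SOURCES],
            },
            index=ANOVA_SOURCES,
        )
        self.r_, self.m_, self.f_ = r, m, f
        self.grand_mean_ = grand
        self.variance_components_ = variance_components_from_ms(
            ms_males=ms["males"],
            ms_females=ms["females"],
            ms_interaction=ms["males_x_females"],
            ms_error=ms["error"],
            r=r,
            m=m,
            f=f,
            truncate=self.truncate_negative,
        )
        return self


def anova_ncii(
    pheno: PhenotypeTable,
    design: NCIIDesign,
    trait: str,
    truncate_negative: bool = False,
) -> NCIIAnova:
    """Run the NCII two-factor ANOVA for one trait of the hybrid population."""
    parents = design.parents_of()
    df = pheno.data[pheno.data["trait"] == trait].copy()
    df = df[df["id"].isin(parents)]
    if df.empty:
        raise ValueError(f"no hybrid records for trait {trait!r}")
    df["male"] = [parents[h][0] for h in df["id"]]
    df["female"] = [parents[h][1] for h in df["id"]]
    return NCIIAnova(truncate_negative=truncate_negative).fit(
        df[["male", "female", "rep", "value"]]
    )


def variance_components_from_ms(
    ms_males: float,
    ms_females: float,
    ms_interaction: float,
    ms_error: float,
    r: int,
    m: int,
    f: int,
    truncate: bool = False,
) -> VarianceComponents:
    """Solve the NCII expected mean squares for the variance components.

    ``m`` is the number of female parents, ``f`` the number of males.  Each
    parent group's component is divided by r x (size of the opposite group):
    the male component by r*m, the female component by r*f (a male's mean
    averages over all m female testers and vice versa).
    """
    if any(v is None or not np.isfinite(v) for v in (r, m, f)):
        raise ValueError("r, m and f are required")
    var_male = (ms_males - ms_interaction) / (r * m)
    var_female = (ms_females - ms_interaction) / (r * f)
    var_sca = (ms_interaction - ms_error) / r
    var_error = ms_error
    negative = min(var_male, var_female, var_sca, var_error) < 0
    if truncate:
        var_male, var_female, var_sca, var_error = (
            max(v, 0.0) for v in (var_male, var_female, var_sca, var_error)
        )
    return _finish_components(
        var_female, var_male, var_sca, var_error, r * m, r * f, negative
    )


def heritability_from_components(
    var_female: float, var_male: float, var_sca: float, var_error: float
) -> VarianceComponents:
    """Assemble genetic/phenotypic variance and h2/H2 from the four components."""
    return _finish_components(
        var_female,
        var_male,
        var_sca,
        var_error,
        np.nan,
        np.nan,
        min(var_female, var_male, var_sca, var_error) < 0,
    )


def _finish_components(
    var_female, var_male, var_sca, var_error, div_m, div_f, negative
) -> VarianceComponents:
    var_genetic = var_female + var_male + var_sca
    var_phenotypic = var_genetic + var_error
    if var_phenotypic > 0:
        h2 = (var_female + var_male) / var_phenotypic
        H2 = var_genetic / var_phenotypic
    else:
        h2 = H2 = np.nan
    return VarianceComponents(
        var_female=var_female,
        var_male=var_male,
        var_sca=var_sca,
        var_error=var_error,
        var_genetic=var_genetic,
        var_phenotypic=var_phenotypic,
        h2=h2,
        H2=H2,
        divisor_male=div_m,
        divisor_female=div_f,
        negative_flag=bool(negative),
    )


def variance_components(anova: NCIIAnova) -> VarianceComponents:
    """Variance components of a fitted :class:`NCIIAnova` (thin accessor)."""
    return anova.variance_components_


class CombiningAbility(BaseEstimator):
    """GCA/SCA decomposition of a male x female table of cell means.

    Fitted attributes: ``grand_mean_``, ``gca_male_`` and ``gca_female_``
    (Series of deviations from the grand mean, each summing to zero on
    complete tables), and ``sca_`` (DataFrame of interaction deviations whose
    rows and columns each sum to zero).  ``complete_`` is False when the
    table had missing cells, in which case margins use available cells and
    the zero-sum identities hold only approximately.
    """

    def fit(self, X: pd.DataFrame, y=None) -> "CombiningAbility":
        cell = pd.DataFrame(X).astype(float)
        if cell.isna().all(axis=1).any() or cell.isna().all(axis=0).any():
            raise ValueError("cell-mean table has a fully missing row or column")
        self.complete_ = bool(cell.notna().all().all())
        grand = float(np.nanmean(cell.to_numpy()))
        row = cell.mean(axis=1, skipna=True)
        col = cell.mean(axis=0, skipna=True)
        self.grand_mean_ = grand
        self.gca_male_ = row - grand
        self.gca_female_ = col - grand
        # S_ij = Y_ij - Y_i - Y_j + Y, the interaction left after removing
        # both parental margins; reconstructs Y_ij = Y + G_i + G_j + S_ij
        self.sca_ = cell.sub(row, axis=0).sub(col, axis=1) + grand
        self.cell_means_ = cell
        return self

    def predict(self) -> pd.DataFrame:
        """Reconstruct the cell-mean table from the decomposition."""
        return (
            self.sca_.add(self.gca_male_, axis=0).add(self.gca_female_, axis=1)
            + self.grand_mean_
        )


def compute_gca_sca(cell_means: pd.DataFrame) -> CombiningAbility:
    """Decompose a male x female cell-mean table into grand mean, GCA and SCA."""
    return CombiningAbility().fit(cell_means)


def cell_mean_table(
    pheno: PhenotypeTable, design: NCIIDesign, trait: str
) -> pd.DataFrame:
    """Male x female table of hybrid trait means (replicates averaged)."""
    parents = design.parents_of()
    df = pheno.data[pheno.data["trait"] == trait]
    df = df[df["id"].isin(parents)].copy()
    df["male"] = [parents[h][0] for h in df["id"]]
    df["female"] = [parents[h][1] for h in df["id"]]
    tab = df.pivot_table(index="male", columns="female", values="value", aggfunc="mean")
    return tab.reindex(index=design.male_ids, columns=design.female_ids)


@dataclass
class HeterosisRecord:
    hybrid: str
    male: str
    male_value: float
    hybrid_value: float
    advantage_pct: float
    undefined: bool = False


def heterotic_advantage(
    pheno: PhenotypeTable, design: NCIIDesign, trait: str
) -> pd.DataFrame:
    """Heterotic advantage of each hybrid over its male parent, in percent.

    HA = 100 * (hybrid - male parent) / male parent, on replicate-mean
    values.  The female testers are male-sterile so mid-parent heterosis is
    unavailable; the male parent is the reference.  A zero male-parent mean
    leaves HA undefined (flagged); a missing male value gives missing HA.
    """
    means = trait_matrix(pheno, level="mean")
    if trait not in means.columns:
        raise ValueError(f"trait {trait!r} absent from phenotype table")
    vals = means[trait]
    rows = []
    for (male, female), hybrid in design.crosses.items():
        hyb = vals.get(hybrid, np.nan)
        mal = vals.get(male, np.nan)
        undefined = bool(mal == 0)
        if np.isnan(mal) or np.isnan(hyb) or undefined:
            ha = np.nan
        else:
            ha = 100.0 * (hyb - mal) / mal
        rows.append(
            HeterosisRecord(hybrid, male, mal, hyb, ha, undefined=undefined)
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def correlation_tests(
    X: pd.DataFrame, Y: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pearson correlations with two-sided t-test p-values.

    Correlates every column of ``X`` with every column of ``Y`` (or of ``X``
    itself) on pairwise-complete observations.  p comes from
    t = r*sqrt((n-2)/(1-r^2)) on n-2 df, two-sided.  Columns with zero
    variance (or <3 complete pairs) give NaN.

    Returns (r, p, n) DataFrames indexed by X columns x Y columns.
    """
    X = pd.DataFrame(X)
    Y = X if Y is None else pd.DataFrame(Y)
    if Y is not X:
        Y = Y.reindex(X.index)
    r = pd.DataFrame(index=X.columns, columns=Y.columns, dtype=float)
    p = r.copy()
    n = r.copy()
    for cx in X.columns:
        for cy in Y.columns:
            x = X[cx].to_numpy(float)
            y = Y[cy].to_numpy(float)
            ok = ~np.isnan(x) & ~np.isnan(y)
            nn = int(ok.sum())
            n.loc[cx, cy] = nn
            if nn < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                continue
            rr = float(np.corrcoef(x[ok], y[ok])[0, 1])
            r.loc[cx, cy] = rr
            if abs(rr) >= 1.0:
                p.loc[cx, cy] = 0.0
            else:
                t = rr * np.sqrt((nn - 2) / (1.0 - rr * rr))
                p.loc[cx, cy] = 2.0 * float(stats.t.sf(abs(t), nn - 2))
    return r, p, n


def significance_stars(p: float) -> str:
    """Significance stars at the 0.01 / 0.001 / 0.0001 levels."""
    if np.isnan(p):
        return ""
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    return ""
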