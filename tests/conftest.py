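import numpy as np
import pandas as pd
import pytest

from nciikit import GenotypeMatrix, NCIIDesign, SimConfig, simulate_ncii_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """One modest NCII dataset reused by read-only tests."""
    cfg = SimConfig(n_males=24, n_females=4, n_subpops=2, n_snps=200, seed=11)
    return simulate_ncii_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_matrix(codes, positions=None, chrom="1", sample_ids=None):
    """Small GenotypeMatrix from a raw code array (helper, not a fixture)."""
    codes = np.asarray(codes, dtype=np.int8)
    n, m = codes.shape
    if positions is None:
        positions = (np.arange(m) + 1) * 1000
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    variants = pd.DataFrame(
        {"chrom": chrom, "pos": positions, "ref": "A", "alt": "T"}
    )
    return GenotypeMatrix(sample_ids, variants, codes)


def balanced_pheno_frame(values):
    """Tidy (male, female, rep, value) frame from values[i][j][k]."""
    rows = []
    for i, mi in enumerate(values):
        for j, cell in enumerate(mi):
            for k, v in enumerate(cell):
                rows.append(
                    {"male": f"m{i}", "female": f"f{j}", "rep": f"r{k}", "value": v}
                )
    return pd.DataFrame(rows)


def anova_ss_oracle(df):
    """Brute-force NCII sums of squares from marginal means.

    Independent of the implementation: every SS is an explicit sum of
    squared deviations of the relevant marginal means.
    """
    grand = df["value"].mean()
    males = sorted(df["male"].unique())
    females = sorted(df["female"].unique())
    reps = sorted(df["rep"].unique())
    f, m, r = len(males), len(females), len(reps)
    ss_tot = sum((v - grand) ** 2 for v in df["value"])
    ss_males = sum(
        r * m * (df[df["male"] == a]["value"].mean() - grand) ** 2 for a in males
    )
    ss_females = sum(
        r * f * (df[df["female"] == b]["value"].mean() - grand) ** 2 for b in females
    )
    ss_reps = sum(
        m * f * (df[df["rep"] == k]["value"].mean() - grand) ** 2 for k in reps
    )
    ss_mxf = 0.0
    for a in males:
        for b in females:
            cell = df[(df["male"] == a) & (df["female"] == b)]["value"].mean()
            ma = df[df["male"] == a]["value"].mean()
            mb = df[df["female"] == b]["value"].mean()
            ss_mxf += r * (cell - ma - mb + grand) ** 2
    ss_err = ss_tot - ss_males - ss_females - ss_mxf - ss_reps
    return {
        "replications": ss_reps,
        "males": ss_males,
        "females": ss_females,
        "males_x_females": ss_mxf,
        "error": ss_err,
        "total": ss_tot,
    }


@pytest.fixture
def toy_2x2x2():
    """The 2 males x 2 females x 2 reps toy with known cell values."""
    return balanced_pheno_frame(
        [[[10, 12], [14, 16]], [[20, 22], [24, 26]]]
    )


def full_design(n_males, n_females, n_reps=3):
    males = [f"m{i}" for i in range(n_males)]
    females = [f"f{j}" for j in range(n_females)]
    return NCIIDesign.full_factorial(males, females, n_reps)
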