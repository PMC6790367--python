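"""Genotype/phenotype containers, I/O and filtering.

The central containers are :class:`GenotypeMatrix` (samples x biallelic SNPs,
alt-allele dosage codes 0/1/2 with a dedicated missing sentinel),
:class:`NCIIDesign` (the male x female factorial cross map) and
:class:`PhenotypeTable` (long-format trait records).  Variant identity is
always (chromosome, 1-based position, ref, alt).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

#: sentinel for a missing genotype call; never conflated with the 0 dosage
MISSING = -1

VARIANT_COLUMNS = ("chrom", "pos", "ref", "alt")


@dataclass
class GenotypeMatrix:
    """Samples x biallelic SNPs coded as alt-allele counts.

    Parameters
    ----------
    sample_ids : list of str
        Unique sample identifiers, one per row of ``codes``.
    variants : pandas.DataFrame
        One row per variant with columns ``chrom``, ``pos`` (1-based),
        ``ref``, ``alt``.  Positions must be strictly increasing within a
        chromosome.
    codes : ndarray of int8, shape (n_samples, n_variants)
        Alt-allele dosage in {0, 1, 2} or :data:`MISSING`.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")
        self.variants = self.variants.reset_index(drop=True)
        missing_cols = set(VARIANT_COLUMNS) - set(self.variants.columns)
        if missing_cols:
            raise ValueError(f"variant table lacks columns {sorted(missing_cols)}")
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        bad = ~np.isin(self.codes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"invalid genotype codes: {np.unique(self.codes[bad])}")
        for chrom, sub in self.variants.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )

    # -- basic properties -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def dosages(self) -> np.ndarray:
        """Codes as float with missing calls mapped to NaN."""
        d = self.codes.astype(float)
        d[self.codes == MISSING] = np.nan
        return d

    def maf(self) -> np.ndarray:
        """Per-variant minor-allele frequency on non-missing calls.

        Invariant to which allele is labelled ref: min(p, 1-p).
        Variants with no non-missing call get NaN.
        """
        nonmiss = (self.codes != MISSING).sum(axis=0)
        alt = np.where(self.codes == MISSING, 0, self.codes).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(nonmiss > 0, alt / (2.0 * np.maximum(nonmiss, 1)), np.nan)
        return np.minimum(p, 1.0 - p)

    def missing_rate(self) -> np.ndarray:
        return np.mean(self.codes == MISSING, axis=0)

    # -- subsetting -------------------------------------------------------
    def take_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.sample_ids,
            self.variants.iloc[index],
            self.codes[:, index],
        )

    def take_samples(self, ids: list[str]) -> "GenotypeMatrix":
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            rows = [lookup[s] for s in ids]
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not in matrix") from exc
        return GenotypeMatrix(list(ids), self.variants, self.codes[rows])

    # -- I/O ----------------------------------------------------------------
    def to_tsv(self, path: str) -> None:
        """Write as TSV: rows=samples, columns=variant ids, 'NA' for missing."""
        cols = [
            f"{c}:{p}:{r}:{a}"
            for c, p, r, a in self.variants[list(VARIANT_COLUMNS)].itertuples(index=False)
        ]
        df = pd.DataFrame(self.dosages(), index=self.sample_ids, columns=cols)
        df.index.name = "sample"
        df.to_csv(path, sep="\t", na_rep="NA", float_format="%.0f")

    @classmethod
    def from_tsv(cls, path: str) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values="NA")
        parts = [c.split(":") for c in df.columns]
        variants = pd.DataFrame(parts, columns=list(VARIANT_COLUMNS))
        variants["pos"] = variants["pos"].astype(int)
        codes = df.to_numpy(dtype=float)
        codes[np.isnan(codes)] = MISSING
        return cls(list(df.index.astype(str)), variants, codes.astype(np.int8))


_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(G: GenotypeMatrix, path: str) -> None:
    """Write a minimal VCF 4.2 file (biallelic SNPs, GT-only FORMAT)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=nciikit\n")
        for chrom in pd.unique(G.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.sample_ids)
            + "\n"
        )
        for j, (chrom, pos, ref, alt) in enumerate(
            G.variants[list(VARIANT_COLUMNS)].itertuples(index=False)
        ):
            gts = "\t".join(_GT_STRING[c] for c in G.codes[:, j])
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path: str) -> GenotypeMatrix:
    """Parse a VCF with GT fields into a :class:`GenotypeMatrix`.

    Diploid GT is converted to an alt-allele count; phasing is ignored.
    Multi-allelic and non-SNP records are skipped and the count logged.
    """
    try:
        vcf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.header.samples)
    rows: list[tuple] = []
    codes: list[np.ndarray] = []
    n_skipped = 0
    for lineno, rec in enumerate(vcf, start=1):
        alts = rec.alts or ()
        if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
            n_skipped += 1
            continue
        col = np.empty(len(samples), dtype=np.int8)
        try:
            for i, s in enumerate(samples):
                gt = rec.samples[s].get("GT", (None,))
                if gt is None or any(a is None for a in gt):
                    col[i] = MISSING
                else:
                    col[i] = sum(gt)
        except (KeyError, TypeError) as exc:
            raise ValueError(f"malformed record #{lineno} at {rec.chrom}:{rec.pos}: {exc}")
        rows.append((rec.chrom, rec.pos, rec.ref, alts[0]))
        codes.append(col)
    if n_skipped:
        logger.info("read_vcf: skipped %d multi-allelic/non-SNP records", n_skipped)
    variants = pd.DataFrame(rows, columns=list(VARIANT_COLUMNS))
    arr = (
        np.column_stack(codes) if codes else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples, variants, arr)


def filter_variants(
    G: GenotypeMatrix, maf_min: float = 0.05, missing_max: float = 0.15
) -> GenotypeMatrix:
    """Keep variants with MAF >= ``maf_min`` and missing fraction < ``missing_max``.

    MAF is computed on non-missing calls.  The missing-rate comparison is
    strict ("<"), the MAF comparison inclusive (">="); variants where every
    call is missing are always removed (and counted in the log).
    """
    if not 0 <= maf_min <= 0.5:
        raise ValueError("maf_min must be in [0, 0.5]")
    if not 0 <= missing_max <= 1:
        raise ValueError("missing_max must be in [0, 1]")
    maf = G.maf()
    miss = G.missing_rate()
    all_missing = np.isnan(maf)
    keep = ~all_missing & (maf >= maf_min) & (miss < missing_max)
    if all_missing.any():
        logger.info("filter_variants: removed %d all-missing variants", all_missing.sum())
    logger.info(
        "filter_variants: kept %d of %d variants", int(keep.sum()), G.n_variants
    )
    return G.take_variants(np.flatnonzero(keep))


@dataclass
class NCIIDesign:
    """A North Carolina II factorial mating design.

    Every male line is crossed to every female line (unless explicitly
    marked incomplete); each cross yields one hybrid grown in ``rep_labels``
    replicated blocks.
    """

    male_ids: list[str]
    female_ids: list[str]
    crosses: dict[tuple[str, str], str]
    rep_labels: list[str] = field(default_factory=lambda: ["rep1", "rep2", "rep3"])
    complete: bool = True

    def __post_init__(self) -> None:
        hybrids = list(self.crosses.values())
        if len(set(hybrids)) != len(hybrids):
            raise ValueError("hybrid ids must be unique")
        if self.complete:
            expected = {(m, f) for m in self.male_ids for f in self.female_ids}
            if set(self.crosses) != expected:
                raise ValueError(
                    "cross map is not the full male x female factorial; "
                    "pass complete=False for an incomplete design"
                )

    @classmethod
    def full_factorial(
        cls,
        male_ids: list[str],
        female_ids: list[str],
        n_reps: int = 3,
        hybrid_fmt: str = "{male}x{female}",
    ) -> "NCIIDesign":
        crosses = {
            (m, f): hybrid_fmt.format(male=m, female=f)
            for m in male_ids
            for f in female_ids
        }
        reps = [f"rep{i + 1}" for i in range(n_reps)]
        return cls(list(male_ids), list(female_ids), crosses, reps)

    @property
    def n_males(self) -> int:
        return len(self.male_ids)

    @property
    def n_females(self) -> int:
        return len(self.female_ids)

    @property
    def n_reps(self) -> int:
        return len(self.rep_labels)

    def hybrid_ids(self) -> list[str]:
        return [self.crosses[(m, f)] for m in self.male_ids for f in self.female_ids]

    def parents_of(self) -> dict[str, tuple[str, str]]:
        """Map hybrid id -> (male id, female id)."""
        return {h: mf for mf, h in self.crosses.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"male": m, "female": f, "hybrid": h} for (m, f), h in self.crosses.items()
        ]
        return pd.DataFrame(rows)


@dataclass
class PhenotypeTable:
    """Long-format phenotype records: one row per (id, trait, replicate)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"id", "trait", "rep", "value"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"phenotype table needs columns {sorted(required)}")
        self.data = self.data.reset_index(drop=True)
        dup = self.data.duplicated(subset=["id", "trait", "rep"])
        if dup.any():
            first = self.data.loc[dup.idxmax(), ["id", "trait", "rep"]].tolist()
            raise ValueError(f"duplicated (id, trait, rep) record: {first}")
        vals = self.data["value"]
        if np.isinf(vals.to_numpy(dtype=float, na_value=np.nan)).any():
            raise ValueError("phenotype values must be finite or missing")

    @property
    def traits(self) -> list[str]:
        return list(pd.unique(self.data["trait"]))

    def to_tsv(self, path: str) -> None:
        self.data.to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_tsv(cls, path: str) -> "PhenotypeTable":
        return cls(pd.read_csv(path, sep="\t", na_values="NA"))


def trait_matrix(pheno: PhenotypeTable, level: str = "mean") -> pd.DataFrame:
    """Pivot a phenotype table to id x trait.

    ``level="mean"`` averages non-missing replicates; ``level="per-replicate"``
    keeps one row per (id, rep) with a MultiIndex.
    """
    df = pheno.data
    if level == "mean":
        return df.pivot_table(
            index="id", columns="trait", values="value", aggfunc="mean"
        )
    if level == "per-replicate":
        return df.pivot_table(
            index=["id", "rep"], columns="trait", values="value", aggfunc="first"
        )
    raise ValueError(f"unknown level {level!r}; use 'mean' or 'per-replicate'")
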