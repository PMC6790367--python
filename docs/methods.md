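# Methods

This note records the statistical models implemented in `nciikit`, the
conventions chosen where more than one was defensible, and what the
simulation-based validation does and does not establish.

## The NCII model and its ANOVA

A North Carolina design II crosses each of *f* male lines with each of *m*
female lines; the *mf* hybrids (plus the male parents) are grown in *r*
randomized complete blocks.  Treating male, female and interaction effects
as random, the hybrid observation is

y_ijk = μ + ρ_k + g_i + g_j + s_ij + ε_ijk,

with block effects ρ_k, male GCA g_i ~ (0, σ²_m), female GCA g_j ~ (0,
σ²_f), SCA s_ij ~ (0, σ²_mf) and plot residual ε ~ (0, σ²_e).  The balanced
two-factor ANOVA with a replications stratum has expected mean squares

- E[MS_males] = σ²_e + r σ²_mf + r·m σ²_m
- E[MS_females] = σ²_e + r σ²_mf + r·f σ²_f
- E[MS_m×f] = σ²_e + r σ²_mf
- E[MS_error] = σ²_e

solved by method of moments.  Each parent group's component is divided by
r × (size of the opposite group) — the male component by r·m because a
male's mean averages over all m testers, and symmetrically for females.
F-tests follow the random-effects convention: males and females over the
interaction mean square, the interaction (and the replications stratum)
over the error mean square.

Heritabilities are h² = (σ²_m + σ²_f)/σ²_P (narrow sense, additive share)
and H² = (σ²_m + σ²_f + σ²_mf)/σ²_P (broad sense), with σ²_P the sum of all
four components.  Method-of-moments estimates can come out negative in
finite samples; they are reported as computed with a `negative_flag`, and a
truncate-at-zero mode is available.  Reporting raw estimates keeps the
unbiasedness and "centered on zero under pure additivity" properties
testable; truncation would bias both.

The EMS pathway requires a complete, equally replicated design.
Unbalanced input raises `UnbalancedDesignError` and directs the caller to
the cell-mean GCA/SCA decomposition, which needs no variance components.
REML components for unbalanced designs are deliberately out of scope.

## GCA/SCA decomposition

On the male × female table of cell means, G_i = Y_i − Y, G_j = Y_j − Y and
S_ij = Y_ij − Y_i − Y_j + Y.  The "+Y" sign is forced by the decomposition
model Y_ij = Y + G_i + G_j + S_ij itself: it is what makes the
reconstruction exact and all margins of S vanish on complete tables.  With
missing cells the margins use available cells, reconstruction still holds
cell-wise, but the zero-sum identities become approximate; `complete_`
flags this.

Heterotic advantage is 100·(hybrid − male parent)/male parent on
replicate-mean values.  The female testers in the emulated system are
male-sterile, so their own trait values — and hence mid-parent heterosis —
do not exist; the male parent is the only available reference.

## Q+K mixed-model association

The scan model is y = Xb + u + e with u ~ N(0, σ²_g K), e ~ N(0, σ²_e I);
X is an intercept plus the top five principal components of the centered
dosage matrix (structure correction), and K is identity-by-state kinship:
the average per-site allele-sharing fraction (2 − |g_s − g_t|)/2 over sites
non-missing in both samples.

Variance components are estimated once, on the null model, by REML: a
single eigendecomposition of K reduces the restricted likelihood to a
one-dimensional function of δ = σ²_e/σ²_g, profiled over a 100-point grid
on log δ ∈ [−10, 10] and refined by golden-section search (tolerance
1e-6).  When the likelihood is flat in δ — K = I, where only the total
variance is identified — the grid point is used directly; any flat point is
optimal and the per-variant tests are unaffected.  Each variant is then
tested by generalized least squares with Σ = σ²_g K + σ²_e I held fixed
(the EMMAX approximation); an `exact=True` mode refits the components per
variant for small-instance cross-validation, and the two agree closely in
practice.  The per-variant test is a t statistic on n − rank(X) − 1
degrees of freedom; the reference program's exact df convention is not
documented, and at the panel sizes involved the choice is immaterial.
Missing genotypes are mean-imputed per variant for testing (never for
storage); variants left with zero variance after encoding, or collinear
with the covariates, are reported missing with a reason rather than
silently dropped.

Genotype encodings: additive uses the 0/1/2 dosage; dominant recodes
heterozygotes to 2 (alt acts dominant); recessive recodes them to 0.  GCA
scans treat each male parent's GCA as a trait of that parent and use
parental genotypes; the female GCA, with only a handful of testers, has
too few levels to scan and is simply absorbed by the decomposition.  SCA
scans give each hybrid the SCA of its cross and use the derived F1
genotypes.  Scanning F1 targets on F1 genotypes (rather than on the male
parent's genotypes) is a deliberate choice: heterozygosity is a property
of the hybrid, and the dominance encodings only make sense on genotypes
that can be heterozygous.

### Multiple testing

The genome-wide threshold is α/Me with α = 0.05 and Me the effective
number of independent SNPs: within non-overlapping windows (default 1000
variants) the eigenvalues λ of the variant correlation matrix are mapped
through f(λ) = 1[λ ≥ 1] + (λ − ⌊λ⌋) and summed; window sums add up to Me.
Duplicated variants collapse to one effective test; mutually independent
variants give Me ≈ M.  Monomorphic variants carry no test and contribute
nothing; near-integer eigenvalues are snapped before the floor to keep the
rule numerically stable.  Published thresholds from specific SNP panels
are functions of those panels' LD and are not recomputable without them;
the validation suite therefore checks the behaviour of the rule (bounds,
collapse, independence limit, monotonicity in LD), not any particular
published number.

## Per-locus effects

The additive effect at a locus is a = (mean(alt-hom) − mean(ref-hom))/2
(half the homozygote difference, the classical convention).  Two dominance
deviations are reported: d_population = mean(het) − overall mean, and
d_midpoint = mean(het) − homozygote midpoint.  The population-mean form is
frequency-dependent and nonstandard but is the headline d/a here because
it is the convention of the analyses this package reproduces; the
classical midpoint form is always reported alongside.  |d/a| > 1 flags
overdominance.  Under ref/alt relabelling a flips sign, the midpoint d is
unchanged, and |d/a| is invariant.

Variance explained is the squared Pearson correlation between dosage and
phenotype for one locus.  For a locus set the default joint fit regresses
on the dosage columns, so a one-member set reproduces the single-locus r²
exactly and the joint R² is never below any member's r²; an
`encoding="indicator"` option fits genotype-class indicators instead,
which additionally captures nonadditive class effects but breaks the exact
one-member identity.

Allele accumulation ranks ids by a GCA/SCA score (ties broken by id for
determinism), tabulates genotype-class frequencies of chosen loci in the
top-n and bottom-n groups, and reports the mean favourable-allele count
difference.  The favourable allele defaults to alt and can be set per
locus (e.g. from scan effect signs).

## Synthetic data generator

The generator emulates the structure of a hybrid-rice NCII trial: inbred
male parents drawn from a few diverged subpopulations, four inbred female
testers, the complete F1 set, three replications.

- **Structure**: Balding–Nichols — ancestral frequency p ~ U(maf_range),
  subpopulation frequency ~ Beta(p(1−F)/F, (1−p)(1−F)/F) with F = fst
  (default 0.15, enough for clean PCA separation without fixing alleles).
  Males fill subpopulations in contiguous near-equal blocks; testers are
  assigned round-robin.  Parents are fully homozygous — rice lines are
  inbred — which makes F1 derivation deterministic: heterozygous where the
  parents differ, the shared homozygote otherwise, missing if either
  parent is missing.
- **Architecture**: genetic value = Σ a_k x_k + Σ d_k·1[x_k = 1] over
  planted QTLs.  Dominance as an indicator on heterozygosity is the
  minimal model consistent with a d/a analysis; how nonadditive gene
  action is generated is genuinely open, and this is the simplest choice
  that produces SCA variance.  Defaults (20 additive QTLs with effect sd
  0.5, 10 dominance QTLs with sd 0.5, residual sd 0.9, block sd 0.5) put
  the realized narrow-sense heritability near 0.6 — mid-range of the
  0.13–0.76 spanned by yield traits in such trials — with a nonzero SCA
  share.
- **Observations**: value = 100 + genetic value + block effect (one draw
  per replicate, shared across entries — randomized block design) +
  Gaussian plot residual.  Phenotypes are generated for male parents and
  hybrids only; the sterile testers have no measurable yield traits.
- **Ground truth**: the exact GCA/SCA decomposition of the noise-free F1
  genetic values, plus realized variance components defined on the EMS
  scale (Σ G_i²/(f−1) etc., so that the ANOVA estimators target them
  exactly) and the implied realized h²/H².
- **Optional LD**: `ld_block_size > 1` makes consecutive variants share a
  haplotype-block allele (copied with probability 1 − ld_swap_prob),
  giving distance-limited LD for decay analyses.  This is block
  correlation, not a recombination model; recombination, epistasis, G×E
  and sterility loci are out of scope.
- **Reproducibility**: one seed; independent named RNG streams (parents /
  QTL / noise) derived via `SeedSequence.spawn`, so identical
  configurations are bit-identical.

A caveat discovered during validation and worth recording: a
pure-dominance QTL produces **no SCA signal** at loci where all female
testers are fixed, because heterozygosity in the F1 then depends on the
male alone and the dominance deviation is absorbed into the male GCA
margin.  `pick_segregating_qtl` exists to plant detectable SCA loci; real
tester panels are small, so this ascertainment effect is a genuine feature
of NCII-based SCA mapping, not an artifact.

## What the validation shows — and does not

The experiments in `nciikit.experiments` (run by the test suite and
`scripts/acceptance.py`) establish, on synthetic data at trial scale
(96 × 4 × 3, hundreds to thousands of SNPs):

- exact arithmetic of the variance-component equations against tabulated
  worked examples;
- algebraic identities of the decomposition to machine precision;
- equivalence of the mixed-model scan with OLS when K = I, uniform null
  p-values, and genomic inflation λ_GC ∈ [0.9, 1.1] on a structured
  polygenic null (n = 300, M = 2000);
- near-unbiased recovery of h² (replicate-mean bias well under 0.05 at 50
  replicates) and an SCA component centered on zero under pure additivity;
- planted-QTL behaviour reproducing the key qualitative contrast: a
  pure-dominance locus is found by the F1-SCA scan under the dominant
  encoding but not the additive one, while a large additive locus tops the
  parent-GCA scan;
- longer-range LD in F1s than in their parents, driven by the small
  tester panel.

These are statements about data generated by the model above.  Real
genotypes have ascertainment bias, LD that varies along the genome,
admixture rather than discrete subpopulations, and trait architectures
with epistasis and G×E, none of which the generator emulates; passing
these tests shows the machinery is correct and calibrated, not that any
particular real-data result would replicate.  Published real-data
quantities (specific association counts and thresholds, variance shares of
named loci, absolute LD-decay distances, specific correlation
coefficients) depend on unreleased genotype/phenotype matrices and are
covered only qualitatively here.

Problem sizes in the suite and the reproduction script (500–2000 SNPs,
20–50 replicates) were chosen as the smallest at which the Monte-Carlo
standard errors are comfortably below the tolerances being checked.
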