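# Methods

This note documents the models implemented in `lipidwgs`, the
assumptions behind them, the synthetic data they are validated on, and
the numerical and design choices that were genuinely open.

## Phenotype harmonization

Lipids are carried in mg/dl throughout; no mmol/l dialect is supported.
LDL-C is derived by the Friedewald equation when triglycerides are
below 400 mg/dl and otherwise taken from a directly measured column;
an explicit `ldl_source` column records which route produced each
value, since study cohorts do not flag this uniformly. The statin
adjustment (TC/0.8, LDL-C/0.7) estimates the pre-treatment level from
the average proportional statin effect and is applied before any
percentile computation, so extreme-tail definitions refer to adjusted
trait levels. A provenance flag (`adjusted = 1`) makes the preparation
non-idempotent by construction: re-running it on prepared data raises
instead of dividing twice.

## Genotype and variant QC

Genotype-level hard filters (defaults: GQ < 20, DP < 10 or > 200,
homozygous allele balance < 0.90, heterozygous minor-read fraction
< 0.20) set individual calls to missing; variant-level filters then
drop sites with > 5% missingness or exact-test Hardy-Weinberg
p < 10⁻⁹ within any cohort. The heterozygous balance rule is applied
to the minor of the two supporting read fractions, which is symmetric
in REF/ALT and reproduces the usual "alt fraction in [0.2, 0.8]"
behavior. The HWE test conditions on allele counts and uses the
standard log-space recurrence over heterozygote configurations
(mid-p off); no installed library provides this primitive, so it is
implemented here and validated against a rational-arithmetic
enumeration oracle. Quality-by-depth, inbreeding-coefficient and
low-complexity filters require raw alignment context and are consumed
as precomputed site flags, not computed.

## Single-variant association

Per-variant effects are ordinary least squares with the covariate set
age, age², sex, cohort (plus self-reported ethnicity only where a
cohort is multi-ethnic; otherwise the ethnicity indicator is collinear
with the cohort indicator and is omitted). Residualizing trait and
dosage against the shared covariates once and regressing residuals
per variant is algebraically identical to the joint fit
(Frisch–Waugh), which the tests verify against statsmodels. Missing
dosages are mean-imputed for the regression only. Wald p-values are
used; under OLS they coincide with the score test. The synthetic
samples are unrelated by construction, so a fixed-effect model
replaces the mixed-model (kinship) machinery used on real cohorts —
the one deliberate model substitution in the package, made so the null
is exactly calibratable. Meta-analysis is fixed-effect inverse
variance with Cochran's Q heterogeneity; conditional scans add the top
variant as a covariate and stop at p > 10⁻⁴, with a ±1 Mb default
locus window (the width is not pinned down by the source analyses and
is configurable).

## Rare-variant aggregation

Five grouping schemes produce `VariantGroup`s with MAF < 1% members:

- **coding**: per-gene LoF plus disruptive-missense labels on canonical
  transcripts, consumed as annotations;
- **window**: 3 kb windows stepping 1.5 kb, anchored at chromosome
  position 0 so window keys are reproducible, restricted to variants
  on enhancer/promoter/DHS annotation and outside every annotated exon
  (1 bp of exon overlap excludes); an overhanging final window is
  allowed;
- **proximity**: promoter elements within ±5 kb and enhancer elements
  within ±20 kb of the gene's TSS (outermost TSS for multi-TSS genes),
  DHS overlap required; flanks are unsigned, so the rule is
  strand-symmetric;
- **link** and **abc**: rare variants inside elements linked to the
  gene by either linking engine; an element linked to two genes
  contributes to both groups.

The per-group combined MAF is the sum of member MAFs — an upper bound
on the carrier fraction, chosen because it is the scale on which
per-gene aggregate frequencies are usually quoted; the observed
carrier count is reported alongside. Group counts on synthetic data
are not comparable to genome-scale counts; only the Bonferroni rule
(0.05 / actual group count) is reproduced.

## SKAT and Fisher combination

The null model is a least-squares fit of the trait on the covariates
(rank checked; collinear columns named in the error). For a weighted
dosage block A = GW, the statistic is Q = ‖A′r‖²/σ̂² with null
distribution Σλᵢχ²₁, λ the eigenvalues of (PA)′(PA) where P projects
off the covariate space. Weights default to the Beta(1,25) density at
each variant's MAF — the canonical SKAT choice; the original analyses
do not state their weights, so these are exposed in the interface.
P-values use Liu's three-moment matching; an exact evaluator by
numerical inversion of the characteristic function (Imhof's formula)
is available for small groups and serves as the oracle in tests. Liu
agrees with Imhof within 10% relative down to p ≈ 10⁻³ and degrades
slowly below that, which the tests encode explicitly. A single-variant
group reduces exactly to the two-sided score test. Callset p-values
are combined with Fisher's method; the three emulated callsets carry
disjoint samples, so the independence assumption holds. Combining k
copies of the same p is monotone decreasing in k only for small p
(copies of p = 0.5 combine to 0.655); the tests state the property in
that corrected form.

## Enhancer–gene linking

**Correlation classifier.** Features are the Pearson correlations of
five mark signals (H3K27ac, H3K9ac, H3K4me1, H3K4me2, DNase) with a
gene's expression across cell types, computed pairwise-complete with a
3-pair minimum; zero-variance features are missing and imputed as 0
(the null correlation) for the classifier. Strata are (cell type,
chromatin state, 200-bp TSS offset) within ±1 Mb; the training set for
a stratum pools one positive (observed) and one matched negative
(gene-to-expression assignment permuted by a fixed-seed derangement)
per state instance within ±5 kb of the offset. Models are
scikit-learn ridge logistic regressions with C = 1; the original
implementation's regularization parameter maps onto this penalty only
approximately, and coefficient-level equality is not claimed. Strata
with fewer than 10 examples per class fall back to the nearest offset
with enough data. Links are retained at posterior odds
p/(1−p) ≥ 2.5 — boundary inclusive, so retention flips exactly at
p = 5/7 — and only the primary enhancer state 7_Enh is exported by
default.

**ABC model.** Candidate elements are DNase peaks expanded 500 bp each
side and merged. Activity is √((DNase+1)(H3K27ac+1)) — the geometric
mean with unit pseudocounts, the canonical ABC form, since the source
describes activity only as "a function of the normalized read count".
Contact defaults to the power law C(d) = (d+1)^−γ with γ = 1 standing
in for an average Hi-C contact profile; a per-element contact vector
is also accepted. Scores are normalized within 5 Mb of each gene, so
per-gene scores sum to one and are invariant to positive rescaling of
activity or contact. The export cutoff defaults to 0.02 and is
configurable; the experimentally tuned value used on real data is
unpublished.

## Polygenic scores and extremes

Three score families are built from summary statistics after removing
strand-ambiguous (A/T, C/G) variants: greedy r²-pruned lead variants
at p < 5×10⁻⁸; clump-then-threshold over a (p, r²) grid with
unrescaled discovery weights; and an LD-shrinkage family. The
shrinkage family replaces the published Gibbs-sampling reweighting
with its closed-form infinitesimal solution
β̃ = (D + (M/(Nh²))I)⁻¹β̂ within LD windows, extended to causal
fractions ρ < 1 by point-normal thresholding (retain the top ρ·M
variants by |z|, use M_eff = ρM in the shrinkage constant). This keeps
the same interface — causal-fraction grid in, reweighted model out —
at a fraction of the cost; it is a documented simplification, and the
p-threshold nesting property replaces properties specific to the
sampler. Model selection maximizes linear-regression R² on a training
cohort disjoint from the evaluation cohort. Scoring matches variants
by position, flips unambiguously swapped alleles, drops ambiguous
ones, and mean-imputes missing dosages.

Extremes are the ancestry-specific 5th/95th percentiles with the
linear-interpolation quantile convention; "extreme high" is strictly
above the cutoff, so exact ties stay unlabeled and, with distinct
values, ⌊qn⌋ samples flag per side. Monogenic classification requires
a pathogenic/likely-pathogenic assertion with no benign assertion, or
a LoF consequence, below the per-gene frequency bound; recessive
carriers are homozygotes or unphased putative compound heterozygotes
(two distinct qualifying het variants). Classification is monotone:
adding a qualifying variant never unflags a carrier. Association fits
are per ancestry, with logistic (extreme vs not) and linear
(continuous LDL-C) models on carrier + score flag + age + age² + sex;
ancestries with zero carriers report counts with missing ORs rather
than diverging. The attributable fraction uses Miettinen's case-based
form, PAF = 100·(exposed fraction among cases)·(OR−1)/OR, which
reproduces all eight published per-stratum PAF values from their
printed counts and odds ratios — the property that selected this
formula among the PAF variants.

## Synthetic cohort: what it emulates, and what it does not

Defaults are the conditions the validation experiments state: two main
ancestries (4,000 + 2,000 samples), residual noise SD 15 mg/dl, a
dominant LDL-raising gene at 30 mg/dl with ~0.3% carriers, a sparse
additive polygenic background, 9% statin use, ~53% female, age
51 ± 15. Genotypes are Binomial(2, f) per ancestry (HWE, unrelated),
with per-ancestry logit-jittered frequencies from a configurable
rare/low-frequency/common spectrum; three callsets partition the
samples in fixed ancestry-dependent proportions, mirroring a
three-callset joint-calling design. TC is assembled as
LDL + HDL + TG/5 so Friedewald is exact off statin; statin users'
observed TC and LDL are scaled by 0.8/0.7 so the adjustment inverts
the observation model. Simulated GQ/DP/AD are clean by construction
(deep coverage, allele-consistent read support), so the QC defaults
pass them; QC behavior is tested on purpose-built corrupted blocks.

The regulatory landscape places gene TSSs on a lightly jittered
regular grid and plants true links from a configurable fraction of
enhancer bins to their nearest gene at mark/expression correlation
ρ_true (default 0.9) across 56 cell types. Two constructions are
deliberate testbed choices rather than realism: expression profiles
are exactly decorrelated across genes (Gram–Schmidt), so every
non-target pair is a genuine null — real co-expression would make
"the" target formally unidentifiable; and the TSS grid keeps every
planted link within a well-populated offset stratum, so the
classifier's training windows contain true examples at the offsets
where truth exists. Consequently, passing link-recovery tests shows
the engine correctly ranks and thresholds identifiable links; it does
not show that real co-regulated gene clusters can be disambiguated,
and on real data the classifier will (correctly) link elements to
co-expressed genes. The generator also does not model LD structure
beyond optional block correlation, demographic history, relatedness,
or family structure.

## Validation experiment sizes

The standing experiments run at: 1,000 null groups of 8 rare variants
on 1,500 samples for SKAT type-I error; a 10,000-variant
permuted-phenotype scan on 1,000 samples for λ; one 6,000-sample
cohort for 30 mg/dl carrier-effect recovery, with the planted carriers
spread over three dominant genes at 1.5% carrier frequency each so the
estimator's standard error (≈1 mg/dl) sits well inside the ±3 mg/dl
recovery band while every per-gene allele frequency respects the 1%
dominant bound; 100 null replicates of 2,000 samples for logistic CI
coverage; and the default landscape (600 bins, 12 genes, 56 cell
types) for link recovery. The bundled demo pipeline uses 2,400 samples
and 250 variants on a 120 kb chromosome and completes in seconds;
all sizes are package choices that keep the suite quick on one CPU.

## Known limitations

Fixed-effect models assume unrelated samples and would be
anticonservative under cryptic relatedness; Liu p-values are
approximate in the far tail (use the Imhof evaluator for small
groups when tails matter); the shrinkage score family is not the
published sampler and will differ for strongly non-infinitesimal
architectures; strand-ambiguous variants are dropped rather than
frequency-resolved; and the PAF formula, while consistent with all
published values, treats the adjusted OR as exchangeable with the
relative risk in its derivation, as is conventional for rare outcomes.
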