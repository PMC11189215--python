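# Methods

`teqtl` implements an integrative scan for genetic regulators of
transposable-element (TE) expression: given a cohort's SNV genotypes, gene
expression, and TE expression aggregated at the subfamily level, it finds
SNV–gene–TE *trios* — variants that act as cis-eQTLs for a gene and
trans-eQTLs for a TE subfamily whose expression tracks that gene — tiers
them by linkage disequilibrium (LD) structure, quantifies how much of each
SNV's trans effect is mediated by its candidate gene, and characterizes hit
sets with gene-set and trait-category enrichment. Because the interesting
statistical behavior is the pipeline's, not any one dataset's, the package
ships a synthetic-cohort generator whose planted effects make power,
false-positive, and calibration properties directly measurable.

## Genotype model and QC

Genotypes are additive ALT-allele dosages in {0,1,2} with no missing
entries (sites with missingness are rejected at load; an optional
mean-imputation flag exists but is off by default). Variant QC retains
biallelic sites with minor allele frequency ≥ 1% and an exact
Hardy–Weinberg equilibrium p ≥ 1e-6. The HWE test is the Wigginton-style
exact test: conditional on allele counts, it sums the probabilities of all
heterozygote configurations no more likely than the one observed. An exact
test matters here because the 1e-6 cutoff lives deep in the tail where
chi-square approximations misbehave; the implementation is verified against
full enumeration for every configuration up to n = 50.

LD pruning uses the standard sliding-window greedy rule (window 50
variants, step 10, r² threshold 0.1): within a window, while any pair
exceeds the threshold, the lower-MAF member is removed (ties drop the later
position). The victim-selection convention is ours — common pruning tools
do not document theirs precisely — and is frozen by a reference-loop test.
Genotype principal components are computed from the pruned,
column-standardized dosage matrix (zero-variance columns dropped with a
warning); each component is oriented so its largest-magnitude loading is
positive, making score signs reproducible. A net TE copy-number covariate
sums structural-variant dosages over L1/Alu insertions minus L1/Alu
deletions.

## Expression preparation

TE locus counts are first stratified by genomic context against the gene
models — exonic (overlaps any exon by ≥ 1 bp), intronic (in a gene body but
no exon), nearby intergenic (within 5 kb of a gene boundary,
edge-to-edge), distal intergenic (beyond 5 kb) — with precedence
exonic > intronic > nearby > distal, then summed per subfamily (optionally
per stratum; stratified totals partition the unstratified totals exactly).

Low-expression filtering keeps a feature iff its counts-per-million exceed
a cutoff (strictly) in at least ⌈0.9·n⌉ samples; the cutoff is derived as
the CPM corresponding to 10 reads in the median-size library. The
variance-stabilizing transform is log2(count/size_factor + 1) with
median-of-ratios size factors rescaled to geometric mean 1 — a deliberate,
provenance-recorded substitute for heavier model-based transforms, adequate
because every downstream test is rank- or residual-based. Known covariates
(lab, sex, population, genotype PCs 1–2, net TE copy number, and the viral
expression feature, which is consumed as a covariate and excluded from the
scan) are removed by per-feature least squares, preserving feature means.
Optional hidden factors are the top principal components of the
feature-standardized residuals — a PCA stand-in for dedicated hidden-factor
models, appropriate for the rank-one batch structure the generator plants.
Finally each feature is mapped to exact normal scores by the rank-based
inverse normal transform with the Blom offset, Φ⁻¹((r − 3/8)/(n + 1/4)),
ties sharing average ranks. After this step every feature row is a
permutation of one fixed score multiset, which makes downstream scans
distribution-exact targets for property tests.

## Association scans and significance

Because covariates are regressed out beforehand, each association test is
bivariate OLS of inverse-normal expression on dosage with a two-sided t
test at n − 2 df (scans are vectorized as correlation algebra; a scalar
reference implementation is cross-checked against statsmodels). Cis pairs
are SNV–gene combinations within 1 Mb of the gene's nearest boundary; the
trans scan covers every SNV × subfamily pair.

Trans significance uses the stricter of two thresholds at α = 0.05:

* the largest p with Benjamini–Hochberg FDR < α, and
* the largest p with permutation-averaged empirical FDR < α, where 20
  permutations scramble the expression matrix's sample labels (one shared
  permutation per round, preserving feature–feature correlation) and
  eFDR(pᵢ) = (mean null count ≤ pᵢ across permutations)/(real count ≤ pᵢ),
  capped at 1.

The empirical threshold is taken as the largest *observed real* p passing,
not a grid value. p-values are floored at machine tiny, never 0. A targeted
scan re-tests a named pair list only (the replication-cohort design), with
BH adjusted over the targeted family alone.

## Trio integration, clumping, tiers

SNVs significant in both scans (FDR < 0.05 strictly, trans calls also
gated by the stricter-of-two p threshold) seed candidate trios; each unique
(gene, subfamily) pair is tested by linear regression on the
inverse-normal values (direction-symmetric for the bivariate case) and BH
adjusted across candidate pairs. Trios require all three FDRs < 0.05.
Trans-significant SNVs with no cis gene are reported as orphans, never
dropped. Trio SNVs are clumped greedily by their best trans p (500 kb
window, r² > 0.1); genes linked to a clump's index SNV are tier 1, genes
linked only to non-index members tier 2.

## Mediation

For each trio the SNV→TE effect decomposes by OLS into
total = direct + indirect with indirect = a·b (a: gene ~ SNV slope;
b, direct: TE ~ gene + SNV coefficients); the identity holds to machine
precision and is asserted everywhere. Significance of the indirect effect
uses a residual-permutation test: the mediator is split into its fitted
SNV component and residuals, the residuals are permuted, and the null
statistic is |a·b_null| with a held at its observed value — an exact-style
permutation test of the partial gene→TE slope. We deliberately do *not*
permute the whole mediator vector: that scheme breaks the SNV→gene path
too, and for trios with a strong a path (which integrated trios have by
construction) it deflates the null products so badly that most trios reach
significance even when the gene→TE path is absent. The residual scheme is
verified uniform under both the complete null and the a ≠ 0, b = 0 null.
p-values use the add-one convention over 10,000 permutations by default
(configurable); BH FDR is computed over all trios in a run. Flags:
*significant* (FDR < 0.05), *consistent* (indirect and total share sign),
*partial* (consistent and proportion mediated strictly inside (0,1) — a
numeric operationalization of a term the literature uses loosely).

## Differential expression and enrichment

Genotype-stratified differential expression fits, per feature, OLS of
log2-normalized counts on the 0/1/2 genotype plus covariates; the group
coefficient is the log2 fold change and coefficient/SE the Wald-type
statistic that ranks a combined gene + TE-subfamily list. This OLS proxy
is what the enrichment layer needs — a well-calibrated ranking — and is
null-calibrated by test rather than matching any count-model's variance
structure.

Gene-set enrichment is the weighted Kolmogorov–Smirnov running sum
(weight 1 by default; weight 0 reduces exactly to classic KS): members add
|stat|^w normalized over member stats, non-members subtract 1/(N−hits);
the ES is the signed maximum deviation, oracle-tested against a naive walk
on 1,000 random instances. The null permutes feature labels (random
same-size sets) because sample-level permutation is impossible for a
precomputed ranked list; NES = ES / mean(|null ES| of matching sign), and
p = (1 + matching-sign exceedances)/(n_perm + 1) — the denominator counts
all permutations so the attainable floor is 1/(n_perm+1), which is what
lets a single true positive among ~50 sets clear BH FDR < 0.05 at 1,000
permutations. TE family sets, L1 evolutionary-age sets (L1M old, L1P
intermediate, L1PA young with L1HS assigned young by definition despite its
prefix), and region-stratified sets come from the annotation; pathway sets
load from GMT.

Whole-family log2FC shifts are tested by one-sample Wilcoxon signed rank
(exact for n ≤ 25 without ties, continuity-corrected normal approximation
otherwise — the two agree within 0.01 at the crossover). Fisher's method
(χ² = −2Σln p, df = 2k) combines p-values across analyses; shared gene
sets — significant with the required NES sign in every analysis — are
ranked by their combined p.

## Trait-category (PheWAS-style) enrichment

Hit SNVs are compared with 500 random equal-size SNV sets drawn from the
scan universe (the observed SNVs are not excluded from the universe). Per
category, the random mapping counts define an ecdf; the reported p is the
literal 1 − ecdf(observed), which can be exactly 0, so a conservative
add-one permutation p is stored alongside. ES = observed / median(random);
a category is enriched when ES > 1 and BH FDR < 0.05.

## Synthetic cohorts

The generator's defaults are the study conditions every calibration and
recovery figure refers to: 200 samples in 2 populations (Balding–Nichols
divergence Fst = 0.05, between within-continental and continental scales,
enough for PCA to need to do real work), 2,000 SNVs on 2 chromosomes with
block-copy LD (blocks of 10, copy probability 0.7, giving realistic
adjacent-pair r²), 40 structural variants, 200 genes, 400 TE loci placed
to realize each genomic stratum exactly (verified by classifier
round-trip), 20 subfamilies spanning L1 (all three age strata), Alu, SVA
and other common families, negative-binomial counts (dispersion 0.1,
log-normal library-size factors), lab/sex/viral covariate loadings, and
three planted mediated trios with a = b = 0.6 on the latent log scale.
Mediated effects act through the latent (noise-free) gene value, so the
true indirect effect is exactly a·b on that scale. The generator is fully
reproducible from (config, seed) and `write_cohort` round-trips through
VCF/TSV/GTF/GMT/JSON.

What the generator does not emulate: realistic recombination maps or
coalescent LD, sequence-level reads, gene-length effects, dispersion
trends, cell-type heterogeneity, or the LD structure between SNVs and the
TE loci themselves. Passing tests therefore demonstrate the pipeline's
statistical correctness and calibration under a faithful-but-idealized
cohort, not performance on real population data.

## Numerical and design choices

* Strict inequalities at every FDR gate (a trio at FDR exactly 0.05 is
  excluded); CPM comparison is strict.
* Ties: average ranks in INT; ranking-stat ties broken by feature ID;
  pruning ties drop the later position.
* Degenerate inputs: constant expression → slope 0, p 1; constant dosage,
  constant INT rows, rank-deficient designs, empty backgrounds → errors
  naming the offender.
* One-hot encoding drops the lexicographically first level; the intercept
  is always present.
* Scans, permutations, the generator, GSEA and PheWAS draws all run off
  explicit seeds; fixed seeds give bit-identical output files.
* Test problem sizes: the null-calibration suite runs one full-scale null
  cohort (40,000 trans tests, 20 permutations); recovery uses 50 cis
  replicates and 20 end-to-end replicates at the default conditions with
  mediation permutations scaled to 300 and the enrichment stages off —
  sizes chosen to keep the suite fast while leaving wide margins to the
  pass thresholds. The KS uniformity check is applied to a fully
  independent test subset (one test per LD block, with the subfamily
  rotating so no dosage vector or feature row is shared), since KS assumes
  independent samples and the full scan's LD- and shared-dosage-correlated
  p-values reject spuriously; the marginal p distribution itself is
  verified exactly uniform.

## Known limitations

* The mediation permutation tests the gene→TE path specifically; it does
  not provide a joint test of a·b against the composite null, and no
  generalized-Pareto tail acceleration is implemented for extreme p.
* The empirical-FDR threshold is resolution-limited by the number of
  permutations; with 20 rounds it cannot distinguish FDRs below ~1/20 per
  real discovery.
* NES magnitudes depend on the feature-label permutation null and are not
  comparable with tools using adaptive or sample-permutation nulls; only
  signs and significance patterns are.
* No kinship/mixed-model correction, conditional eQTL mapping, phasing,
  sex-chromosome handling, or colocalization.
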