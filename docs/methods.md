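# Methods

This note describes the statistical procedures `sexhet` implements, the
modelling assumptions behind its synthetic data, and the numerical and design
choices that were genuinely open.

## Problem setting

Many complex traits and diseases differ between the sexes, yet the autosomal
genetics of those differences is largely uncharacterized.  Given sex-stratified
GWAS summary statistics for a panel of quantitative (biometric) traits, the
package identifies *sex-heterogeneous (sex-het) SNPs* — variants whose
estimated effect differs between the female and male strata beyond sampling
error — and then asks what those SNPs do: whether they are enriched in
association signal for unrelated diseases and traits, which genes and gene
sets they implicate, and whether they preferentially overlap regulatory
elements, meQTLs, and expression-predictive (Pr-eQTL) variants.

## Discovery

**Harmonization.**  Female and male tables of one trait are joined on SNP id
and put on a shared effect-allele orientation: swapped alleles negate the
male beta and flip its allele frequency; strand-ambiguous SNPs (A/T, C/G)
are dropped because orientation cannot be resolved from summary data.  MAF is
taken from the female stratum after harmonization, so one consistent
reference stratum defines the frequency used by filters and matching.

**Per-trait heterogeneity.**  For each SNP,

    Z_het = (β_F − β_M) / sqrt(SE_F² + SE_M²),        Q = Z_het²,

with Q referred to a chi-square with 1 df.  For two strata these are the same
test — P_Q equals the two-sided normal p-value of Z_het identically, and the
test suite enforces the identity at 1e-12 relative tolerance.  Trait-specific
sex-het SNPs satisfy P_Q < 5×10⁻⁸ and MAF ≥ 0.1%.  Calibration is monitored
with the genomic inflation factor λ = median(χ²)/0.4549 (χ² computed from
log p to stay finite below 1e-300).

**Effect-scale conversion.**  Cross-trait meta-analysis needs effects and
standard errors, so Z_het is converted with the allele frequency p and total
sample size n:

    β_het = Z_het / sqrt(2p(1−p)(n + Z_het²)),
    SE_het = 1 / sqrt(2p(1−p)(n + Z_het²)),

which preserves β_het/SE_het = Z_het exactly.  The frequency entering the
conversion is the harmonized MAF (symmetric in allele labelling and the same
covariate the matched nulls condition on).  The meta-analysis input is signed:
positive when |β_F| > |β_M| (female-driven), negative otherwise, so traits in
which the same sex drives the difference reinforce each other.

**Multi-trait meta-analysis with sample overlap.**  Signed (β_het, SE_het)
are combined across traits by fixed-effects inverse-variance weighting.
Because cohorts may share samples, a correlated fixed-effects (Lin–Sullivan)
variant is available: with per-trait SEs s and a trait-by-trait null-z
correlation matrix R, Σ_ij = R_ij s_i s_j and

    β_meta = (1'Σ⁻¹β)/(1'Σ⁻¹1),   SE_meta = (1'Σ⁻¹1)^(−1/2).

R is estimated as the Pearson correlation of z-scores over SNPs where both
traits have |z| < 1 (the band keeps genuinely heterogeneous SNPs out), then
**de-truncated**: restricting a bivariate normal to |z| < 1 attenuates a true
correlation of 0.5 to an in-band Pearson r of about 0.15, so the in-band
estimate is mapped back through a numerical inversion of the truncated-
bivariate-normal correlation function (Gauss–Legendre quadrature plus root
finding).  Without this step the correction visibly under-corrects: in a
simulation with 50% shared samples the uncorrected meta has type-I error
≈ 0.11 at α = 0.05, the non-de-truncated correction ≈ 0.08, and the
de-truncated correction restores 0.05.  A singular R (e.g. duplicated
traits) falls back to the pseudo-inverse, which yields the correct
no-double-counting limit.  SNPs missing in some traits are meta-analysed
over the traits available, grouped by missingness pattern.

**Candidate set and clumping.**  Univariate and multivariate significant SNPs
(both at P < 5×10⁻⁸, MAF ≥ 0.001, the MAF filter re-applied to meta results)
are united, each tagged univariate_only / multivariate_only / both and
annotated with its leading trait (minimum per-trait P_Q) and that best P_Q.
Greedy LD clumping on ascending best P_Q retains a SNP iff r² < 0.2 with
every SNP already kept; ties are broken by (chrom, pos, snp_id) for
determinism, SNPs absent from the LD reference are treated as independent
(kept, with a logged count), and clumping is genome-wide with
cross-chromosome r² defined as 0.  The clump window is unlimited within a
chromosome (configurable); only the r² rule is part of the method.

Each catalog SNP is classified *female-driven* (|β_F| > |β_M|) or
*male-driven*, with exact ties assigned male-driven deterministically and
logged, and by mechanism at a per-sex nominal α = 0.05: effect in one sex
only, opposite directions, or same direction with different magnitude.  A
fourth label, `undetermined`, covers the (practically unreachable for
genome-wide-significant Q) case in which neither stratum is nominal.

## Matched permutation null

Sex-het SNPs are an ascertained set — common, strongly trait-associated — so
enrichment must be judged against sex-homogeneous SNPs with the same nuisance
profile.  For each catalog SNP a match is drawn uniformly from the pool of
SNPs that are not sex-het and not in LD (r² > 0.2) with any sex-het SNP,
subject to

* MAF within ±0.001 when the catalog SNP has MAF < 0.01, ±0.02 otherwise
  (a catalog MAF of exactly 0.01 uses the ±0.02 rule), and
* combined-sex marginal effect within ±75 positions of the pool ranked by
  the inverse-variance female+male meta-analysed beta of the SNP's leading
  trait.

Sampling is without replacement within a set; SNPs may recur across sets
(default 1,000), each set drawn from an independent child stream of one
master seed.  If an entry has no eligible match, both tolerances are doubled
up to three times, then the nearest eligible neighbour in scaled
(rank, MAF) distance is taken; every relaxation is flagged on the emitted
set and logged.  At desk scale relaxations concentrate at extreme
marginal-effect ranks where the pool thins out; with genome-scale pools they
are rare.  A MAF diagnostic (medians and KS distances of catalog vs pool vs
null sets) verifies the matching.

Empirical p-values are rank-based and include the observed value in the
denominator: empP = (1 + #{null ≥ observed})/(N + 1) for the enrichment tail,
mirrored for depletion, so the smallest attainable value with 1,000 sets is
1/1001 and the statistic is valid by construction.

## Enrichment statistics

**Association signal.**  Among catalog SNPs present in a disease or trait
GWAS, the observed statistic is the percentage with P < 0.05, compared with
the 5% null expectation analytically (1-df chi-square goodness of fit on
counts, expected count = 0.05 × overlap; Fisher/binomial exact available for
small overlaps) and empirically against the matched nulls.  Female- vs
male-driven subsets are contrasted with a 2×2 chi-square and a fold ratio.

**SNP sets.**  Overlap with meQTLs (caller pre-filters to P < 1×10⁻¹⁴),
Pr-eQTLs (optionally restricted to or excluding brain tissues via the tissue
column), or any SNP id set is reported as the percentage of the catalog in
the target, a SNP counting once regardless of how many CpG probes or eGenes
it maps to; unique item counts and per-SNP ranges are reported alongside,
each with its own empirical p.

**Intervals.**  The percentage of catalog SNPs inside a named annotation
(BED, 0-based half-open; a 1-based SNP position pos is inside [start, end)
iff start < pos ≤ end) is tested in both directions — enrichment and
depletion — since ascertained SNP sets are often significantly depleted from
regulatory categories.

**Conditional Pr-eQTL enrichment.**  To separate sex heterogeneity from
expression-regulatory function, the association-signal enrichment is
recomputed on the catalog's Pr-eQTL subset against null sets drawn only from
sex-homogeneous Pr-eQTLs (eligibility intersected with Pr-eQTL membership).

## Gene annotation and overrepresentation

A SNP inside a gene body takes that gene with class priority
splicing > UTR > exonic > intronic ("splicing" = within 2 bp of an internal
exon boundary; gene models without exon substructure class genic SNPs as
intronic, which does not affect assignment).  An intergenic SNP takes its
nearest gene only within 25 kb, measured to the closer transcript boundary,
strand-ignorant (both the anchor and the cutoff are configurable).  The
cutoff is supported by the flank diagnostic: counting, per distance bin, SNPs
whose nearest flank (gene_A) vs second flank (gene_B) lies in the bin shows
gene_A dominating the 0–25 kb bin severalfold, decaying at larger distances.
The mapped gene list is profiled for loss-of-function intolerance: observed
fractions with pLI > 0.9 and pLI < 0.1 are tested with exact binomial tests
against user-supplied reference proportions (the reference census is an
input, not a download).

ORA compares the mapped list L against each gene set S within a universe U
(default: genes present in both the GMT collection and the gene models;
list genes outside the universe are dropped before testing, as unmapped RNA
genes are in practice): expected = |S∩U|·|L|/|U|, FE = observed/expected,
two-sided Fisher exact p (one-tailed hypergeometric via a flag), BH-FDR
across sets.  Because lists built from trait-associated SNPs are enriched in
many sets for reasons unrelated to sex heterogeneity, a permutation layer
re-runs the ORA on gene lists derived (by the same annotation rule) from the
matched null sets and reports a rank-based empirical p per set — the ge tail
of FE for overrepresented sets, the le tail for underrepresented ones.
Hormone-responsive (androgen/estrogen) gene lists are ordinary GMT inputs to
this same machinery; no bespoke path exists.

## Synthetic data

The generator produces every input at desk scale with known truth.  Effects
live on the z scale; per-stratum standard errors follow the standardized-
trait relation SE = 1/sqrt(2·MAF·(1−MAF)·n), so no genotypes are simulated
and runtime is flat in sample size.  Defaults emulate the study conditions the package
is designed for: consortium-scale strata (170,000 females, 150,000 males), MAF from
0.5·Beta(1,3) floored at 2×10⁻⁴, 1% strand-ambiguous SNPs, 20% of male rows
written on the flipped allele orientation, LD in blocks of 10 consecutive
SNPs with within-block r² = 0.5 realized as exchangeable noise correlation
sqrt(r²), a 5% sex-homogeneous polygenic layer with z ~ N(0, 4²), and a
0.3% planted sex-het layer with |Δβ|/SE drawn from {4, 5, 6}, realized
through mechanisms mixed 66.8% one-sex / 32.6% opposite-direction / 0.6%
magnitude-difference (the proportions observed in the discovered catalog)
and planted only at MAF ≥ 0.01 (catalog SNPs are common variants).  The
planted heterogeneity is shared across traits, mirroring a catalog dominated
by the multivariate analysis.  Disease tables give a configurable fraction
of sex-het SNPs (and optionally of controls, or only of Pr-eQTLs) a signal
of |z| ≈ 3, everything else Uniform(0,1) p.

Annotations: genes of 20 kb with exponentially distributed intergenic gaps
(mean 80 kb — fixed tiling would make the gene_B-within-25 kb diagnostic bin
structurally empty), five 1 kb exons and 500 bp terminal UTRs per gene; pLI
from a two-component Beta mixture (20% constrained); regulatory BED sets at
exact coverages 2–30%; meQTL and Pr-eQTL maps with baseline membership rates
5% and 17% and sex-het excesses 1.2× and 1.28× (a 21.8% vs 17%
sex-het/sex-homogeneous contrast); two planted GMT layers — a
sex-het-specific set boosted (3×) for genes near planted sex-het SNPs, and a
trait-association set boosted for genes near SNPs in the top decile of
|combined-sex marginal beta|, the exact covariate null matching preserves,
so the permutation layer can calibrate it out.

What the generator does **not** emulate: realistic human LD (blocks are
exchangeable and rectangular), allele-frequency–dependent genetic
architecture, population stratification, cross-trait phenotypic correlation
beyond sample overlap, or winner's-curse effects in the input statistics.
Passing tests therefore demonstrate correctness and calibration of the
procedures under the stated model, not robustness to those real-data
complications.

## Numerical choices and problem sizes

* χ² from p in log space; p-values floored at 1e-300 when written.
* Heterogeneity identities (Q = Z², β/SE = Z) hold to 1e-12 relative
  tolerance and are asserted on 10⁵ random inputs.
* De-truncation of banded correlations: 48-node Gauss–Legendre quadrature,
  Brent root finding at 1e-6, estimates clipped to |ρ| ≤ 0.999.
* Deterministic tie-breaks throughout (clumping order, direction ties,
  rank ties by snp_id); one master seed with spawned child streams per
  permutation set.
* Test problem sizes were chosen as the smallest that make the statistical
  assertions stable: discovery recovery at 10⁵ SNPs × 3 traits, the
  matched-null audit at 1,000 sets over a ~200-SNP catalog, the two-layer
  ORA at 60,000 SNPs with ~1,100 catalog SNPs, ~1,050-gene lists and 100
  permutations.

## Known limitations

* The overlap correction assumes a common null correlation across the
  genome; heteroscedastic overlap (e.g. trait pairs sharing samples in one
  cohort only) is averaged.
* Matching is marginal (MAF and effect rank separately), not joint; a
  propensity- or Mahalanobis-style matcher is out of scope.
* With desk-scale pools, a minority of matched-null entries require logged
  tolerance relaxations at extreme effect ranks; genome-scale pools make
  these rare.
* ORA treats gene sets as flat lists; GO-graph propagation and
  parent-term redundancy reduction are out of scope.
* Empirical p-values share null sets across analyses, so they are
  correlated across diseases/annotations; per-analysis calibration is
  unaffected.
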