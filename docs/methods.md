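# Methods

## Design and estimand

The package targets cohorts produced by crossing many outbred paternal
parents to one inbred maternal tester.  Each F1 plant is heterozygous
tester/parent wherever its inherited paternal haplotype differs from the
tester genome, so allelic read ratios at exonic SNPs measure the activity
of the paternal *cis*-regulatory allele relative to the tester allele.  The
estimand of the differential-ASE (DASE) analysis is, per gene and
population, the average difference in log2(paternal/tester) expression
between F1s whose fathers came from highland versus lowland sites — a
population-level contrast of *cis*-regulatory alleles, insulated from
*trans* variation because both alleles share each plant's cellular
environment, and from plant-level confounders by the tester serving as a
within-plant reference.

## SNP filters and their rationale

Allelic counts are consumed in the GATK ASEReadCounter column layout
(1-based positions; `refCount`/`altCount` per SNP per sample).  Three
per-sample filters are applied before any aggregation:

1. **Both alleles observed.**  At a locus truly homozygous in a given F1,
   all reads report one allele; keeping such loci would assign both
   alleles' reads to one side.  Keeping only landrace-allele-only loci
   while discarding reference-only ones (which look homozygous) would bias
   ratios toward the landrace allele, so both directions are excluded.
2. **Total coverage ≥ 10 reads.**  Below this, allele drop-out by sampling
   is common even with balanced expression.
3. **|log2(alt) − log2(ref)| < 2** (strict).  At high coverage, sequencing
   errors create low-frequency non-reference counts that pass filter 1;
   such sites show extreme ratios and would bias gene ratios toward the
   reference allele.

Counts of surviving SNPs are summed within genes (`snp_sum` mode; a read
spanning k SNPs of one gene contributes k times — documented
double-counting) or, when a read-level assignment table exists, each read
counts once per gene per allele (`read_assignment`, exact, the default when
available).  SNPs inside exons of more than one gene are dropped as
ambiguous.  `log2ASE = log2(landrace) − log2(tester)` is **missing** (zero
weight) when either count is zero: a zero count is absence of information
about the ratio, not a ratio of zero.

Gene-level inclusion uses population-by-elevation groups: for ASE a gene
needs ≥ 10 samples with ≥ 32 ASE-informative reads in **every** group (the
contrast must be estimable in all four cells); for total expression, in
**at least one** group.  Samples with fewer than 2 × 10⁶ mapped reads are
removed first.

## Variance modeling

Both analysis paths share one engine.  The total-expression path is
standard voom on TMM-normalized log2-CPM.  The ASE path adapts the same
idea to ratios: the sampling variance of log2ASE is driven by the
ASE-informative total of that gene in that sample, not by expression level
per se.  The procedure is

1. an unweighted per-gene least-squares fit of the design to log2ASE
   (missing cells excluded; genes with < 1 residual df dropped);
2. a lowess trend (span 0.5, 3 robustifying iterations) of
   sqrt(residual SD) against log2 mean normalized total count per gene,
   where totals are scaled per sample by the ASE library size and offset
   by +0.5 before the log;
3. the trend evaluated at each observation's own log2 normalized total,
   linearly interpolated with endpoint clamping; the observation weight is
   the predicted value to the −4th power (a sqrt-SD trend to the fourth
   power is a variance; the weight is its inverse), and exactly 0 for
   missing cells.

The design matrix per site:tissue contains: intercept; block dummies (only
where a tissue spans > 1 field block); sampling-team dummies; a cubic
orthogonal polynomial of the within-field sampling order fit separately per
team (orthogonalized within team with a canonical sign so results are
row-order invariant); one dummy per non-reference population; an
`elev_<population>` highland indicator per population, whose coefficient is
the extractable highland-vs-lowland contrast; and within-population
centered latitude.  Optional cell-composition scores append one column
each.  Rank deficiency is an error naming the aliased columns.

Per-gene weighted least squares yields β̂, unscaled SDs, residual SD s and
df d.  Empirical-Bayes moderation fits a scaled-F prior to the residual
variances by moment matching on e = log s² − ψ(d/2) + log(d/2): the prior
df d₀ solves ψ′(d₀/2) = var(e) − mean(ψ′(d/2)) (Newton inversion of the
trigamma), s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2)).  When the moment
target is non-positive the prior df is infinite and all variances shrink to
s₀².  Posterior variance s²ₚₒₛₜ = (d₀s₀² + d s²)/(d₀ + d); reported
SE = √s²ₚₒₛₜ · stdev.unscaled; moderated t on d₀ + d df.  These formulas
reproduce limma's `squeezeVar` to 1e−6 and the TMM factors reproduce
edgeR's `calcNormFactors` to 1e−8 (both cross-checked in the test suite by
running the R implementations).

## Meta-analysis and the lfsr

Per-population elevation effects and SEs from the three site:tissues form a
genes × 6 effect table, meta-analyzed jointly with a
mixture-of-multivariate-normals prior: a point mass at zero plus shapes
ωU_k for U_k in the canonical set (identity, per-condition singletons,
equal effects, partial sharing with off-diagonals 0.25/0.5/0.75) and
data-driven shapes — rank-1 principal components and the rank-2
reconstruction of the z-scores of genes with |z| > 3.3 in ≥ 1 condition
(a pre-fit proxy for significance, since the lfsr is unavailable before
fitting) — each normalized to unit maximum diagonal.  The scale grid is
geometric with ratio 2 from (min SE/10)² to (4·max|effect|)².  Residual
correlation between conditions is the empirical correlation of z-scores
over genes with |z| < 2 everywhere, shrunk 5% toward the identity — a
documented simplification of the EM residual-correlation estimator.
Extreme-deconvolution refinement of the data-driven shapes is omitted;
PCA shapes alone are used.

Mixture weights maximize the penalized likelihood (Dirichlet pseudo-weight
10 on the null) by EM; because component likelihoods are fixed, each EM
step reduces to two matrix-vector products, and the loop runs to a change
below 1e−8 per gene (up to 2×10⁴ iterations) — near-null scale components
make the likelihood almost flat in some directions, so a tight tolerance
matters.  With per-gene SEs that vary across genes (the realistic case)
the null weight on pure-null data concentrates ≥ 0.95; with artificially
constant SEs the point null and the smallest-scale components are nearly
unidentifiable and weight spreads among them without affecting posteriors.

Posteriors mix the conjugate normal conditionals over components with
per-gene responsibilities.  `lfsr = min(P(b ≤ 0 | data), P(b ≥ 0 | data))`,
the point mass counting toward both sides, so a fully-null posterior has
lfsr = 1.  The per-gene overall lfsr is the minimum over conditions
("significant in ≥ 1 condition"); the alternative (lfsr of the average
effect) is stricter and not used.  Missing conditions are imputed with
effect 0 and SE 10⁶, contributing no information, and are masked to NaN in
all outputs.  Sign probabilities and posterior means agree with 2-D Simpson
quadrature of prior × likelihood to 1e−6 on a toy model.

## IBD classification

Sibling F1 plants share the tester genome and, per chromosome segment, one
of two paternal haplotypes.  For a pair of samples, each chromosome is cut
into 20 bins with equal SNP counts from the full SNP panel; per bin, the
shared-het fraction is |A∩B| / min(|A|,|B|) over the two samples' filtered
heterozygous calls (a SNP passing the ASE filters counts as heterozygous),
undefined if either set is empty.  Fractions pool across chromosomes into
one two-component univariate Gaussian mixture per pair (EM; means
initialized at the 25th/75th percentiles, equal variances and weights;
tolerance 1e−8 on the log-likelihood, ≤ 1000 iterations; numerically
constant input is flagged degenerate with uniform posteriors).  Components
are ordered by mean; the higher-mean component is read as IBD.  Bins with
posterior > 0.9 are IBD, < 0.1 not-IBD, otherwise ambiguous (strict
inequalities; empty bins are ambiguous).  On simulated siblings the
classifier reaches ≥ 95% accuracy once the two fraction components are
separated by about 5 SDs, which requires reasonably dense het coverage per
bin; sparser panels mostly inflate the ambiguous class.

## Cell-composition scores

Score(sample, population) = Σ_g w_g · (x_gs − mean_s′ x_gs′) over the
reference marker genes assayed, with x the log2-CPM matrix of the analyzed
site:tissue and w the marker's reference log2 fold-change.  This is a
relaxed relative of least-squares deconvolution: no constraint that the
reference spans all populations present, and scores are relative, not
proportions.  Reliability is tested by recomputing the total score
variance 200 times with marker identities reassigned uniformly at random
(without replacement) among the expression-filtered genes, weights kept;
the empirical p is (1 + #{null ≥ real})/(n_perm + 1).  The "total
variation" statistic is the variance of the scores themselves (the
alternative — variance explained in expression space — would weight
high-variance genes differently; the score-variance version matches the
projection being validated).  Scores can be injected as design covariates
to absorb composition-driven expression differences.

## Convergence

A gene is convergent when lfsr < 0.05 in both populations and the
population-level posterior means share a (nonzero) sign — "same size in
both populations" is read as same sign, consistent with directional-change
language; both-significant genes with opposite signs are reported
separately as discordant.  Population-level lfsr is the minimum over that
population's conditions and the population-level effect the mean posterior
effect over them.  Overlap significance is P(X ≥ x) for X hypergeometric
(N assayed background genes, K and n significant per population), computed
through the log-space survival function; effect concordance compares the
Pearson correlation of posterior effects over the convergent subset versus
all assayed genes.

## The simulator

`simdata` generates the full data structure the pipeline consumes, with
known truth.  Defaults emulate the motivating study design: 108 F1
families split evenly between two populations (Mexico / SouthAmerica) and
elevation classes; three site:tissues (leaf tip and base at the highland
field with two blocks — one plant per block providing both tissues — and
leaf tip at the lowland field, one block), three sampling teams with
round-robin field order; 10 chromosomes × 5 independently inherited
haplotype segments; 2,000 genes with Poisson(3) exonic SNPs each.

Generative model: per gene, family and paternal haplotype, a cis effect
θ ~ N(δ_g·highland, τ²) in log2 units, with δ_g = δ (default 1.0) for the
designated DASE genes and 0 otherwise and τ = 0.3 baseline haplotype
variation; expected paternal fraction p = 2^θ/(1+2^θ).  Gene totals are
negative-binomial (dispersion 0.05) around library-size-scaled lognormal
relative expression, multiplied by (1+2^θ)/2 so a cis-up allele also
raises total expression; 20% of genes additionally carry a smooth
field-order (time-of-day) trans effect exercising the polynomial
covariates.  The paternal split of a gene's ASE-informative reads (a read
overlaps ≥ 1 SNP with probability 1−0.9^(#SNPs)) is beta-binomial with
intra-class correlation ρ (default 0.01; α = p(1−ρ)/ρ, β = (1−p)(1−ρ)/ρ;
ρ = 0 is binomial), giving the extra-binomial variation the weights must
handle.  SNP counts arise by equal-probability multinomial thinning
(vectorized stick-breaking) of the gene-level allelic reads; a SNP is
informative only if the inherited haplotype carries the alternate allele
(carrier probability 0.5 per haplotype per SNP), otherwise its paternal
reads are indistinguishable from tester reads; sequencing errors flip
individual allele calls at rate 10⁻³.  Default library size is 5×10⁶
(lognormal, σ = 0.2) so the 2×10⁶ QC threshold trims only the low tail, as
in realistic cohorts.

Truth tables expose θ, δ, DASE flags, inherited haplotypes and expected
fractions, and `SimCohort.realized_elevation_effects()` returns the actual
estimand of a finite cohort — the mean θ contrast of the haplotypes the
sampled plants inherited — which is the correct sign oracle: even a gene
with δ = 0 has a small nonzero realized contrast in 40 families, so naive
"δ = 0 ⇒ any call is wrong" scoring would overstate sign errors.

What the simulator does **not** emulate: read-level sequences and
alignment/mapping bias (beyond the scalar error rate), recombination maps
(segments are fixed-length), linkage between genes beyond shared segments,
cell-composition structure in the counts (composition signal is
constructed directly at the expression-matrix level where needed), and any
real genome's coordinates.  Passing tests therefore demonstrate
correctness of the statistical machinery under the stated generative
model, not robustness to alignment artifacts or reference bias in real
reads — the SNP filters address those, but their real-data effectiveness
is validated only indirectly (the per-sample log2ASE median sits near zero
on simulated null data).

## Problem sizes and numerical choices

Validation simulations use cohorts of 24–40 families with 200–2,000 genes
and libraries of 0.25–5 × 10⁶ reads — sizes where every property under
test (filter tallies, effect recovery within 0.15 log2 units, ≥ 95% IBD
accuracy, lfsr sign-error ≤ 7%, permutation-p uniformity over 50 cohorts)
is measurable with comfortable Monte-Carlo margins on a single core.
Randomness flows from one root seed through named `SeedSequence`
substreams per stage, so pipeline outputs are byte-identical across reruns
(verified by manifest hashes).  Degenerate inputs are handled explicitly:
header-only SNP tables parse to empty tables; all-zero-count samples,
zero-exon annotations, and sub-threshold group sizes raise named errors;
constant GMM input and constant score matrices are flagged rather than
fit.

## Known limitations

* `snp_sum` aggregation double-counts reads spanning multiple SNPs of a
  gene; the exact read-level mode needs an assignment table that real
  workflows derive from tagged alignments.
* The residual-correlation estimator and the PCA-only data-driven
  covariances are simplifications; with few strong genes the data-driven
  shapes can overfit chance structure (mitigated by the null-biased
  prior).
* The mixture null weight is not separately identifiable from
  vanishing-scale components when SEs are artificially constant across
  genes; posteriors and lfsr are unaffected.
* IBD truth is undefined for bins straddling a segment boundary where
  inheritance flips; accuracy is assessed over well-defined bins, and real
  recombination breakpoints have the same property.
* One GMM is fit per sample pair (fractions pooled across chromosomes);
  per-chromosome fits would need far more bins per chromosome to be
  stable.
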