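# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the known limitations of `mkm`.

## Count models and the depth offset

All abundance and richness analyses treat reads as Poisson counts with a
log link and a `log(total reads)` offset, so a sample sequenced twice as
deeply is expected to yield twice the counts with no change in the
biological coefficients.  Fixed effects are the design factors: block,
sequencing run, organ where both are present, and (for the combined
richness analysis) kingdom with the run factor nested inside kingdom,
since each amplicon is sequenced on its own runs.

The per-taxon organ-enrichment GLM is fit with statsmodels IRLS
(convergence 1e-10).  Taxa entirely absent from one organ produce a
separated fit; the rate ratio is reported at its boundary (0 or ∞) and
flagged rather than suppressed.  Wald p-values are the default, a
likelihood-ratio alternative is available, and no multiple-testing
correction is applied at this stage.

### The Poisson GLMM

`mkm.glmm` implements the single-random-intercept Poisson GLMM by a
Laplace approximation: for a fixed random-effect variance σ²ᴬ, penalized
IRLS finds the joint mode of (β, u); because the accession factor
partitions the observations, Z′WZ is diagonal and each step is one dense
solve of size p + q.  The profiled Laplace objective is maximized over
log σ²ᴬ by bounded Brent search (xatol 1e-4 on the log scale, PIRLS
deviance tolerance 1e-8, gradient check at the mode).  Brent replaces a
general quasi-Newton optimizer because the profiled objective is
one-dimensional and unimodal in practice.  The fit agrees with lme4's
`glmer` on shared fixtures to ~1e-3 in the variance component and BLUPs
(an Rscript oracle test enforces this).  An optimum pinned at the lower
bound of log σ²ᴬ ∈ [−12, 4] is reported as σ²ᴬ = 0.

Broad-sense heritability of a fitted GLMM is the accession share of the
latent-scale variance, H² = σ²ᴬ / (σ²_fixed + σ²ᴬ + σ²_dist), with
σ²_fixed the variance of the fixed linear predictor (offset excluded)
and σ²_dist = ln(1 + 1/λ̄) the log-link distribution-specific variance at
the geometric-mean rate λ̄ = exp(mean η).  This is the
conditional-minus-marginal R² convention for Poisson mixed models.  Note
that λ̄ includes the offset, because the Poisson noise on the latent
scale depends on the realized rate, not a depth-standardized one.

## Diversity

Richness is the number of taxa with ≥1 read.  Rarefaction draws a
multivariate hypergeometric sample (without replacement) of the target
depth from each sample's realized read pool; samples below the depth are
excluded and logged.  The default depth of 400 reads reflects the lower
sequencing effort of the fungal libraries.  Whittaker's turnover is
β = S/ᾱ − 1, which is 0 for identical and 1 for disjoint communities;
the variant S/ᾱ (range [1, 2]) is deliberately not used so that the
statistic is a [0, 1] dissimilarity.

The "kingdom preference" phenotype is the per-accession difference of
bacterial and fungal richness BLUPs; positive values mark hosts with
relatively more diverse bacterial communities.

## Networks

Correlations are Pearson coefficients of rarefied counts (not relative
abundances, not BLUPs) among the best-sequenced taxa, with two-sided
p-values from the t transform on n − 2 degrees of freedom.  Edges enter
the graph at p < 0.01; signs are kept as attributes but betweenness and
degree are computed on the unweighted, sign-agnostic graph (networkx,
betweenness unnormalized).  Zero-variance taxa have undefined
correlations and become isolated nodes.  The kingdom-vs-degree contrast
is an OLS of degree on a fungi indicator, whose slope equals the
difference in kingdom mean degree.

## Ordination and Procrustes

Accession-level ordination is PCA of the BLUP matrix after centering and
unit-variance scaling; zero-variance columns are dropped with a warning.
PC signs are fixed by making each loading column's largest-magnitude
entry positive.  Taxa whose GLMM fails to converge are zero-imputed only
when rare (≤1% of columns), otherwise excluded, to avoid structured
artifacts.  The Procrustes statistic is the symmetric variant: both score
matrices centered and scaled to unit Frobenius norm, rotation from the
SVD of the cross-product, r = √(1 − m²) with m² = 1 − (Σ singular
values)²; the permutation p-value uses the (exceedances + 1)/(n + 1)
convention, flooring p at 1/(n_perm + 1).

## The host-genotype grid

Nested subsets take the top ⌈f·T⌉ taxa by total reads (ties broken
lexicographically, so subsets are truly nested).  Before sample-level
PCA, counts are scaled to a common reference depth and log1p-transformed
(a `raw-scaled` option exists), each taxon is residualized on block and
run, and columns are standardized.  The clustering statistic is the
factor fit R² = 1 − SS_within/SS_total over the first n_pcs score
columns jointly; its permutation null has mean (k − 1)/(n − 1).
Samples are the exchangeable unit after residualization.  The default
fraction axis {1, 2, 3, 4, 5, 10, 25, 50, 100}% keeps a desk-scale
runtime; a full 1–100% axis is a parameter away.

## Quantitative genetics

Kinship is the standardized GRM K = ZZ′/m over MAF-filtered SNPs
(monomorphic SNPs dropped; tiny negative eigenvalues from roundoff
clipped).  Its column centering pins the off-diagonal mean at
−trace(K)/(n(n−1)); "unrelatedness" therefore shows in the off-diagonal
spread (≈1/√m), not the mean.  REML uses one eigendecomposition of K and
bounded Brent search over h² ∈ (0, 1) on the profiled restricted
likelihood (xatol 1e-8); boundary optima are flagged.  GWAS estimates
variance components once on the null model, rotates phenotype and
genotypes into K's eigenbasis, and tests each SNP by weighted least
squares with a t-test on n − 2 degrees of freedom; genomic-control λ is
the median test χ² over 0.4549.  The permutation threshold whitens the
phenotype with the Cholesky factor of V̂ (so it is exchangeable under
the null), permutes, back-transforms, rescans, and takes the empirical
α-quantile of the per-permutation minimum p; fewer than 20 permutations
are refused because the quantile is unstable.

Windows are half-open 10-kb bins, 0-based: a SNP at 1-based position p
falls in window (p − 1)//w.  Gene scores are the minimum SNP p within
the gene body ± one window on each side.  The enrichment tail holds the
⌈0.01·N⌉ best-scored genes; categories are tested hypergeometrically and
corrected with Storey q-values (π₀ from the λ-grid 0.05…0.95 with a
cubic smoothing spline, clipped to (1/m, 1], q monotonized; π₀ = 1
reproduces Benjamini–Hochberg exactly).  Genotypes are coded haploid
{0, 1} for inbred lines, heterozygous VCF calls set missing by default,
and missing dosages mean-imputed per SNP before kinship and GWAS.

## The synthetic-data generator

`mkm.synth` emulates the study design end to end: 196 accessions × 4
replicates (replicate r in block r, as in a randomized complete block
design), leaf and root samples, two kingdoms with their own sequencing
runs (6 contiguous batches per kingdom) and their own depth
distributions — lognormal, moment-matched to 2524 ± 1594 reads for
bacteria and 562 ± 726 for fungi.  Per taxon, the log-rate is

    η = μ_t + organ_t·[root] + a(accession, t) + b(block, t)
        + c(run, t) + f_s·L_t + ε,

with baseline abundances μ_t ~ N(0, 1.5²) (a lognormal species-abundance
distribution), block/run artifacts of SD 0.2, three latent factors with
loading scale 0.3 inducing the mildly positive cross-taxon correlations
seen in real communities, organ effects of SD 0.5 and a per-observation
residual of SD 0.5 (overdispersion).  Counts are multinomial draws of
each sample's depth over softmax(η), so depth is conserved exactly and
proportions follow the Poisson structure the models assume.

Accession effects are polygenic by default: each taxon draws 10 causal
SNPs from a per-kingdom pool of 25 host loci (pleiotropy, as expected
when a limited set of immunity/root-development genes shapes many taxa),
plus a shared polygenic "evenness axis" (weight 0.5) that pushes common
taxa up and rare taxa down, making community diversity itself heritable.
Each taxon's accession effect is rescaled so its realized share of the
log-scale variance equals the target h² exactly, which makes recovery
targets well-defined; h² = 1 with nonzero artifact variances is rejected
as infeasible.  A TruthRecord stores every latent component (including
the evenness score) so η can be rebuilt exactly in tests.

What the generator does *not* emulate: taxonomic correlation structure
(lineages are arbitrary labels), linkage disequilibrium between SNPs
(markers are independent given cluster frequencies), spatial field
effects, and zero-inflation beyond what the multinomial induces.
Passing tests therefore demonstrate statistical correctness of the
estimators under the assumed generative family, not robustness to every
artifact of real amplicon data.

### A known limit: richness SNP-heritability through the offset model

The richness model's offset asserts richness ∝ reads.  For any finite
taxon pool the true richness–reads relation saturates (measured log-log
slope 0.3–0.6 in the emulation), so the offset injects (1 − b)·log-depth
noise into the accession BLUPs — about 0.2 SD at the accession level
given the fungal depth dispersion.  This swamps the attainable richness
genetic signal: a slope-corrected control recovers the true polygenic
diversity score at r ≈ 0.86, while the offset-model BLUPs recover it at
r ≈ 0.2–0.3.  Consequently the fungal-heritable vs bacterial-null
contrast on richness SNP-h² reorders only in roughly two-thirds of
simulation seeds, and the corresponding acceptance test fails honestly;
the broad-sense (GLMM) contrast is more reliable but inflated for both
kingdoms by overdispersion absorbed into the accession variance.  The
offset convention is kept because it is the method under test.

## Problem sizes

Tests and the acceptance script run the full 196 × 4 accession design
where recovery claims demand it, with 300–800 SNPs, 40–120 taxa per
kingdom, 99–999 permutations and 5–50 simulation seeds per claim; these
sizes were chosen so each suite completes in minutes on one CPU while
keeping every statistical check adequately powered.

## Interface choice

The package is a library: its importable API plus the narrative scripts
in `examples/` are the interface, and outputs are DataFrames and plain
dataclasses rather than files.  A command-line wrapper was considered
and dropped — every realistic use composes several stages with
user-specific decisions in between, which is Python-session work, not
shell work.
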