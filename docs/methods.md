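# Methods

This note documents the models implemented in `droughtomics`, the
numerical and design choices behind them, what the synthetic-data
generator does and does not emulate, and the known limitations.

## Trial model and genetic parameters

Phenotypes are replicated observations of variety × trait ×
environment, where an environment is a year × watering-regime cell
(e.g. WW17 = well-watered 2017). The per-environment analysis is a
randomized-complete-block two-way ANOVA with genotype and replicate
effects; balanced layouts use closed-form sums of squares and
unbalanced ones a sequential least-squares fit (replicate entered
before genotype). The replicate count `r` entering the variance
components is the harmonic mean across genotypes.

From the genotype and error mean squares:
σg² = (MSG − MSE)/r, σe² = MSE, σp² = σg² + σe². A negative σg²
estimate is clamped to zero and flagged rather than propagated. The
coefficients of variation are 100·√MSE/x̄ (ECV), 100·σg/x̄ (GCV) and
100·σp/x̄ (PCV), guaranteeing GCV ≤ PCV; broad-sense heritability is
h² = 100·σg²/σp², and genetic advance under truncation selection is
GA = k·(h²/100)·σp with GAM = 100·GA/x̄. The default selection
intensity k = 1.76 corresponds to keeping the top 10% of a standard
normal; the exact normal-theory value is φ(z₀.₉)/0.1 = 1.755, which
the breeding literature conventionally rounds to 1.76
(`quantgen.selection_intensity` returns the exact value).

σe² is taken to be MSE (not MSE/r); the CV and heritability columns of
a typical variety-trial table are mutually consistent only under this
reading, which is why it is the package's convention. GA deliberately
omits a division by the trait mean — that normalisation belongs to GAM
alone; the chain reproduces published variety-trial rows only under
this form.

The combined analysis treats year as random and genotype and regime as
fixed. Expected-mean-square logic for a single random factor gives the
test denominators: G against G×Y, regime against Y×E, G×E against
G×Y×E, and all year-involving terms against the residual. Lattice
inter-block recovery is not implemented; the genotype + replicate RCBD
approximation is used because plot/block-level incidence is rarely
published. REML variance components and spatial field models are out
of scope.

## Marker statistics

QC filters run in a fixed order — call rate ≥ 0.90, biallelic,
MAF ≥ 0.05, missingness ≤ 0.10, all boundaries inclusive on the keep
side — and the report counts removals per stage, so the counts sum to
(input − output). PIC per biallelic locus is 1 − (p²+q²) − 2p²q² with
frequencies from non-missing calls.

Pairwise r² is the squared Pearson correlation of dosages over samples
with both calls present (pairs with fewer than 5 complete observations
are skipped and counted). D′ requires haplotype frequencies, estimated
by a two-locus EM on unphased diploids: only the double heterozygote is
phase-ambiguous, and the EM iterates its cis/trans split; D is then
normalised by its maximum given the allele frequencies. Confidence
bounds on |D′| for the block definition profile the genotype-table
likelihood over a |D′| grid with allele frequencies fixed at their
marginal estimates, normalise it to a distribution, and take the
central 90% interval — the unphased analogue of the classical
confidence-interval block method. A pair is "strong LD" when the upper
bound ≥ 0.98 and the lower ≥ 0.70, "strong recombination" when the
upper bound < 0.90, and uninformative otherwise; a span is a block when
its outermost pair is strong and ≥ 95% of its informative pairs are
strong, with blocks accepted greedily longest-first without overlap.

LD decay is summarised by fitting the Hill–Weir drift-recombination
expectation of r² (with the sample-size term at 2n chromosomes) to
mean r² in log-spaced distance bins, weighted by √(pairs per bin), with
a free multiplicative scale. The free scale matters: the fixed
theoretical intercept (≈ 0.46) generally sits above or below the
data's short-range plateau, and without it flat curves cannot be
recognised as non-decaying. The decay distance is where the fitted
curve falls to half its fitted value at the shortest observed distance;
if that never happens within the observed range the estimate is
reported right-censored, and a binned half-max fallback (flagged) covers
optimizer failure. The half-of-fitted-intercept rule is one of several
defensible definitions of "decay distance"; estimates are comparable
within this package but not across definitions.

Kinship is the VanRaden centred genomic relationship matrix
G = ZZ′/(2Σp(1−p)) with missing dosages mean-imputed for this
computation only; an IBS variant is available since toolkit default
kinships differ slightly. PCA operates on centred (mean-imputed)
dosages via SVD with a deterministic sign convention (largest-magnitude
loading positive); five components are the default structure
covariates.

## Association models

The GLM regresses the per-variety trait mean for one trait ×
environment on dosage plus an intercept and structure covariates,
dropping samples with a missing call per SNP; the dosage coefficient
gets a two-sided t-test, and marker R² is the nested-model
(SSE_reduced − SSE_full)/SST on the same samples.

The MLM is y = Xβ + s·a + u + e with u ~ N(0, K·σu²). The variance
ratio δ = σe²/σu² is estimated once by REML on the null model through
the spectral decomposition of K (profile likelihood over log δ on a
grid refined by bounded scalar minimisation) and then held fixed for
every marker — the P3D/EMMAX approximation, which matches standard
mixed-model GWAS practice and makes the per-marker test a weighted
least-squares Wald t-test in the rotated space. Missing dosages are
mean-imputed in the MLM so the single rotation stays valid (per-SNP
sample dropping would invalidate it); the GLM keeps per-SNP dropping.
With σu² → 0 the MLM reproduces GLM p-values to numerical precision,
which is tested. The MLM marker "R²" is a likelihood-ratio
(Cox–Snell-style) analogue, 1 − exp(−LR/n), not an exact variance
partition.

Phenotype input to association is the per-environment variety mean; no
BLUEs/BLUPs stage is interposed. Significance uses the fixed P < 10⁻⁴
threshold with strict inequality (BH FDR is available but never the
default). Stable SNPs are significant for the same trait in ≥ 2
environments; pleiotropic SNPs for ≥ 2 traits in any environment; lead
SNPs break ties by smallest p then smallest position. Allele-class
means are compared by Tukey's HSD at family level 0.05, with
compact-letter display obtained from maximal cliques of the
not-significantly-different graph, ordered by class mean; classes with
fewer than two members are reported but untested. Genomic inflation is
λ = median χ²/0.4549.

## Candidate genes, expression, integration

Gene models are 1-based inclusive intervals (GFF3 in, BED-style
half-open exports converted explicitly). A gene is a candidate for a
SNP when the distance to its nearest edge is within the window
(inclusive); distance is SNP-to-edge, not to the TSS, matching how
"x kbp downstream of gene" is normally phrased. Relations are
strand-aware: upstream is 5′ of the TSS. Two window presets exist —
200 kbp and the LD-decay estimate (288 kbp default).

FPKM is count/(length_kb × library-size_millions), libraries defaulting
to column sums. A gene is a DEG when |log2FC| ≥ 1 (the threshold is
applied two-sidedly since both directions are reported) and BH Q < 0.05,
with log2FC computed on mean FPKM with a pseudo-count of 1. The default
test is a pooled two-sample t on log2(FPKM + c) with empirical-Bayes
variance moderation: per-gene variances are shrunk toward a scaled
inverse-chi-square prior fitted by moments on log s², and the residual
degrees of freedom grow by the prior df. At the validation design's
3-vs-3 replication an unmoderated test leaves roughly half of genuine
4-fold changes below the BH threshold, so moderation is the default;
plain Welch and a per-gene negative-binomial GLM (log library-size
offset) remain available. "Q value" is interpreted as BH FDR.

Enrichment is the one-sided hypergeometric tail per category (≥ 2
annotated background genes), BH-corrected across categories.
Integration builds ±144-kbp intervals (288-kbp width) around
significant SNPs, merges overlaps to avoid double counting, and
compares DEG vs non-DEG proportions inside vs outside the merged
intervals by a one-sided Fisher exact test, alongside the up/down DEG
ratios for both sets. "Validated" candidates are candidate genes that
are DEGs in at least one drought-vs-control contrast.

## Synthetic data

The generator reproduces the trial's statistical structure, not its
biology. Subpopulation allele frequencies follow the Balding–Nichols
model (Beta around a Uniform[maf_floor, 1−maf_floor] ancestral
frequency at the configured FST); defaults are 119 samples, 29,310
SNPs over 19 chromosomes (A ≈ 28.4 Mbp, C ≈ 54.3 Mbp each), 7
subpopulations at FST 0.10. Haplotypes come from a latent Gaussian
AR(1) copula: within blocks of `ld_block_len` the latent correlation
between adjacent SNPs is exp(−recomb_rate·d) and blocks are
independent, so r² decays on a controllable scale — a deliberately
simple blockwise model rather than a coalescent simulation, which the
downstream estimators do not need. Thresholding the latent Gaussian
attenuates allelic correlation below the latent one;
`expected_allelic_r2`/`expected_r2_curve` give the exact population
curve, and `popgen.expected_decay_distance` pushes it (plus the
(1−r²)/n sampling floor) through the same fitting pipeline as the
estimator to produce the deterministic recovery target. The default
recomb_rate 3.1e-7/bp and ld_block_len 2.1 Mbp were chosen so the
measured genome-wide decay distance under the default structured
conditions lands near the ~288 kbp scale typical of such panels;
admixture LD from the subpopulation structure is part of that
calibration. Mean PIC at the defaults falls in the 0.24–0.38 band
expected for such marker sets.

Phenotypes are y = μ_env + Σ dosage·effect + u_poly + gxe + rep + ε,
with the polygenic variance solved from the h² target given the
realised QTN variance (clamped at zero when QTNs already exceed the
target), and truth objects (QTN list, per-environment true h², genetic
values) always returned. Expression counts are Gamma–Poisson (negative
binomial) with length- and lognormal-baseline-proportional means,
library sizes ~1M, dispersion 0.05, and planted DEGs drawn
preferentially from genes within 288 kbp of supplied QTNs.

What the generator does not emulate: genotyping-platform ascertainment,
linkage between QTNs and local LD surface (QTNs sit on observed SNPs),
selection/demography, spatial field trends, count overdispersion
heterogeneity across genes, and batch effects. Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
model, not robustness to every artefact of real data.

## Numerical choices and scales

Missing genotypes use the single sentinel −1 throughout. All positions
are 1-based with inclusive windows; BED exports are 0-based half-open.
Seeds propagate through `numpy.random.default_rng`; every generator is
bit-reproducible given its seed. The test-suite and acceptance-script
problem sizes (e.g. 5,000-SNP calibration nulls, 50-simulation
recovery medians, 300-gene expression panels) were chosen as the
smallest sizes at which the binomial/Monte-Carlo error of each check is
comfortably below its acceptance margin.

## Known limitations

- Per-environment association uses variety means, not BLUEs; with
  strong replicate imbalance the two differ.
- P3D/EMMAX underestimates per-marker variance-component uncertainty
  relative to exact per-SNP REML; the difference is negligible at
  h²-scale polygenicity but grows for markers of very large effect.
- The D′ confidence interval is a likelihood-profile approximation on
  unphased data; with < ~40 samples its bounds are wide and most pairs
  become uninformative for block building.
- The LD-decay distance depends on the chosen definition
  (half-of-fitted-intercept); absolute values are not comparable across
  software using other definitions.
- Multi-locus GWAS, haplotype-based association, epistasis, imputation
  and phasing beyond EM pair estimates are out of scope.
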