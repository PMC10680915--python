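# Methods

This note documents the statistical models in `eqtlgrowth`, the design
choices that were genuinely open, the synthetic data the tests run on, and
what passing tests do and do not establish about real segregant data.

## Setting and data model

A biparental haploid cross provides segregants genotyped at biallelic
markers coded −1 (BY parent) / +1 (RM parent). Coding by parent rather
than allele count makes every marker–trait Pearson correlation
sign-symmetric under relabelling of the parents, so allele effects are
reported as correlations throughout. Coordinates are 1-based inclusive
base pairs internally; BED exports are 0-based half-open. Expression is
complete by construction; growth phenotypes carry explicit missing values
and all correlations use pairwise-complete observations (listwise within
condition for REML).

## Preprocessing

Expression is residualized per gene on measurement batch (factor) and
OD600 at RNA extraction (numeric) by OLS. An intercept is always included:
the generative equations omit it, but standardization makes it harmless
and it protects the fit when covariate columns are unbalanced. Growth is
not covariate-corrected (an optional per-condition residualization on
growth in the base medium is provided). Order of operations is fixed:
correct expression, then standardize both matrices column-wise to mean 0,
SD 1 over non-missing entries; constant columns are flagged and zeroed.

## Genetic correlations and FDR

The genetic correlation of gene *j* and condition *i* is the Pearson
correlation of the processed phenotypes across segregants; two-sided p
from the t-transform with n−2 degrees of freedom. FDR uses Storey
q-values: π₀(λ) = #{p > λ}/(m(1−λ)) evaluated on λ ∈ {0, 0.05, …, 0.95},
smoothed by a cubic least-squares polynomial evaluated at λ = 0.95 and
clipped to (0, 1]. This is a close analogue of the df-3 smoothing spline
in the reference q-value implementation; setting π₀ = 1 reproduces
Benjamini–Hochberg exactly, which the tests assert. Families are
per-condition by default (significant-gene counts are reported per
condition); a global family is available because the choice is not
dictated by the problem. The panel-size analysis resamples segregants
without replacement at configurable sizes and reports per-condition
medians over repetitions.

## QTL-effect correlations

For a gene with at least three detected eQTLs, the effect of each peak
marker on expression and on each growth condition is a Pearson r with a
95% CI from the Fisher z-transform (z ± 1.96/√(n−3), mapped back by tanh;
width floored at 10⁻⁶ so that degenerate |r| = 1 effects keep finite
weights rather than dominating the fit). The agreement between the two
effect profiles is a weighted Pearson correlation with weights equal to
the inverse product of the two CI widths; its p-value uses a t statistic
with (number of loci − 2) degrees of freedom, matching the behaviour of
the standard weighted-correlation routine — a compatibility choice, since
the effective sample size is debatable for inverse-variance weights. FDR
here is Benjamini–Hochberg across all tested gene × condition pairs.

## Hotspot effects and hotspot correlations

Hotspot positions are inputs, not discoveries. Effects of the hotspot
peak markers on a trait are assigned by forward stepwise selection: among
unretained markers, retain the one with the largest |r| against the
current residualized trait provided its correlation p < 0.05; record that
r as the marker's effect; regress the marker out; stop when nothing is
significant; unretained effects are exactly 0. Ties in |r| break to the
lowest marker index (determinism). The recorded effect is the correlation
at the retention step, matching the sequential description of the
procedure rather than a final joint refit. The hotspot correlation of a
gene/condition pair is the Pearson correlation of the two effect vectors
with zeros included; all-zero vectors are flagged rather than tested.
Empirical significance of any hotspot-based statistic comes from random
marker sets of the same size, with the add-one estimator
p = (#{null ≥ obs} + 1)/(n_sets + 1), which cannot return 0.

A note on support recovery: with the p < 0.05 stop rule, a set containing
k truly null markers retains at least one of them in roughly 1 − 0.95ᵏ of
scans by construction. Exact recovery of the causal support is therefore
only achievable when every marker in the set carries a real effect, and
that is the regime in which the recovery tests operate.

## Variance components

The fraction of growth variance attributable to a marker set uses the
mixed model y = μ + u + e, u ~ N(0, σ²_g K), e ~ N(0, σ²_e I), with
K = ZZ'/m from the column-standardized genotype submatrix (observed
means/SDs, not assumed 0.5 allele frequencies; duplicated markers only
rescale K; constant markers are dropped with a warning). REML rather than
ML matches the convention of mixed-model heritability software. The
restricted likelihood is profiled to one dimension in the ratio
δ = σ²_e/σ²_g after a single spectral decomposition of the
intercept-projected kernel; the kernel of the centred GRM is handled by
lumping its total η² onto the retained zero-eigenvalue coordinates (the
likelihood depends on equal eigenvalues only through their summed η²).
Bounded scalar optimization over log₁₀δ ∈ [−8, 8] plus endpoint checks
gives the estimate; a dense-matrix grid search serves as the independent
oracle in the tests (|Δh²| < 10⁻³). A GRM numerically equal to the
identity is flagged unidentifiable (only σ²_g + σ²_e is estimable).
Hotspot curves fit GRMs of the top-k hotspots ranked by number of target
genes, k = 2…K, and report the smallest k reaching 50% and 80% of the
all-hotspot fraction.

## Interval statistics

Overlap between two interval sets is counted after padding each side by
5 kb (clipped at chromosome ends, with a warning). The null places
intervals of the observed sizes uniformly at random, genome-wide
(chromosome chosen proportional to the number of valid start positions),
subject to mutual non-overlap, by rejection sampling with a max-attempt
guard; only the gQTL intervals are randomized while hotspots stay fixed.
Placements may optionally be pinned to the original chromosomes; the
default is unconstrained, since the procedure being emulated does not
state a constraint. Peak co-occurrence tiles each chromosome with fixed
bins anchored at position 1 (last bin truncated) and reports the Spearman
correlation of per-bin eQTL and gQTL peak counts for each configured bin
size.

## Colocalization

Eligible pairs are a local eQTL and a gQTL whose padded confidence
intervals overlap and whose single-trait LODs reach the configured
threshold. The scan interval is the smallest span containing both CIs,
padded 5 kb; markers are first pruned greedily left-to-right so
consecutive retained markers have r < 0.95, and the ≥3-marker eligibility
rule applies after pruning. For every ordered marker pair (λ₁, λ₂) a
bivariate Gaussian model with trait means α_t + β_t·g_{λ_t} and
unstructured 2×2 residual covariance is fit in closed form (per-trait OLS
plus the MLE cross-covariance, n-divisor throughout, so likelihoods are
comparable). The diagonal λ₁ = λ₂ is the pleiotropy model. The statistic
is log₁₀L(best pair) − log₁₀L(best diagonal) ≥ 0; profile LODs subtract
the diagonal maximum, so a maximum profile LOD of zero means one shared
QTL explains both traits. Significance comes from a parametric bootstrap
under the fitted pleiotropy model; p ≤ 0.05 rejects pleiotropy in favour
of distinct QTLs. No kinship random effect is included: a one-generation
haploid cross has no family structure, so the bivariate fixed-effect
model is adequate and orders of magnitude faster.

## Effect removal

For pairs significant before removal (5% FDR) whose gene has at least one
local and one trans eQTL, the marker set under study (local eQTL markers,
the gene's trans-eQTL peak markers, or all hotspot peak markers) is
regressed out of both phenotypes jointly (OLS with intercept; collinear
genotype columns deduplicated by pivoted-QR rank detection) and the
correlation recomputed on the residuals. Percent drop is
(|r_before| − |r_after|)/|r_before| × 100, summarized by medians; paired
Wilcoxon signed-rank tests compare |r| before vs after per set, and
size-matched random marker sets estimate the drop expected from linkage
alone. Removal of many markers from few observations is refused rather
than regularized.

## Enrichment, clustering, signatures

Significant correlates of a condition are split by sign and each gene-set
term is tested one-sided (enrichment) by Fisher's exact test against the
tested-gene universe; expected counts, folds, and log₂ folds are
reported, records are displayed at p < 10⁻³, and a strict count at
p < 10⁻⁵ is also emitted (both before and after tie resolution, since the
bookkeeping convention is ambiguous). A term significant in both
directions keeps the direction with the larger |log₂ fold|; exact ties
keep the positive direction. Trait clustering runs k-means (fixed seed,
10 restarts) on the signed fold matrix — negative-direction folds enter
negated, zero elsewhere — so conditions enriched for the same processes
in opposite directions separate cleanly. Signature averages are plain
means of correlation coefficients over externally supplied gene groups.

## Mediation

For hotspot marker g, mediator expression M, and outcome growth Y:
α from M ~ g; (β, γ) jointly from Y ~ g + M. On complete data
β + αγ equals the simple OLS slope of Y on g exactly, which the tests
assert to 10⁻¹⁰. Proportion mediated αγ/(β + αγ) is reported unclipped
with a suppression flag when β and αγ disagree in sign. Inference uses a
non-parametric case-resampling bootstrap of segregant triples (degenerate
resamples with a constant marker are redrawn) with the two-sided add-one
percentile test on αγ; BH FDR across candidate genes. Growth is
standardized before mediation, consistent with the rest of the pipeline.

## Synthetic data generator

The generator is first-class, tested code; its defaults define the
conditions under which the pipeline is validated.

* **Genome/map** — 16 chromosomes with yeast chromosome lengths
  (~12.1 Mb), constant 0.4 cM/kb, evenly spaced markers. Genotypes follow
  a per-chromosome two-state Markov chain with Haldane recombination
  fractions (no interference); chromosomes independent; allele frequency
  1/2.
* **Architecture** — hotspot peak markers are drawn with a ≥10 cM mutual
  separation; each hotspot's target-gene count is log-uniform over the
  26–4,594 range scaled by the simulated gene count (heavy-tailed). 55%
  of genes receive a local eQTL at the marker nearest the gene, with
  double weight in the variance partition (local effects tend to be
  stronger). Per-gene heritability is uniform on [0.2, 0.8], split across
  the gene's loci and rescaled so the realized genetic-score variance
  equals the target; noise SD = √(1−h²), so effects live on the
  standardized-phenotype scale and the marker–trait correlation at a
  causal marker converges to the stored effect. Conditions draw 4–10
  gQTLs, 80% at hotspot markers chosen with probability proportional to
  target count — hotspots with broader transcriptome effects carry more
  growth effects, mirroring the observed positive relation between a
  hotspot's breadth and the variance it explains. Condition h² is uniform
  on [0.4, 0.8].
* **Archetypes** — conditions alternate between two sign archetypes that
  flip the direction of every hotspot effect, planting two opposite
  transcriptome-response groups for the clustering stage (the full-scale
  study partitions its traits into three groups; the desk preset
  clusters into two to match what it plants).
* **Covariates and missingness** — expression receives batch offsets
  (8 batches, SD 0.3) and an OD600 effect (coefficient SD 0.2); growth
  receives independent noise and 5% missing values; the two matrices
  share no batch structure, mirroring the independent-experiments design
  the genetic interpretation rests on.
* **QTL catalogs** — truth-derived tables list the causal markers as peak
  markers with realized correlations as signed effects, closed-form LODs,
  and 1.5-LOD-drop confidence intervals, filtered at LOD ≥ 2.5: like real
  QTL catalogs they contain detected QTLs only. Undetected weak effects
  would otherwise contribute support intervals spanning whole
  chromosomes, which no catalog would report and which make
  non-overlapping random placement infeasible.
* **Truth files** — a single long-format TSV serializes every generative
  effect, noise scale, covariate, and archetype; an architecture rebuilt
  from it regenerates the phenotypes bit-for-bit given the seed.

What the generator does **not** emulate: diploid genetics, epistasis,
gene–environment interaction (all analyses here are additive, as in the
study design), linkage disequilibrium beyond the Haldane chain, read-count
noise models for expression, or shared batch structure between expression
and growth. Passing tests therefore demonstrate correctness of the
estimators and the qualitative architecture-recovery behaviour under an
additive, independently measured design — not robustness to confounding
that the real design excludes by construction.

## Problem sizes and presets

`RunConfig` defaults keep the full-scale analysis settings (1,000 random
sets, 1,000 bootstraps, 250/500/750 subsampling, pruning at r < 0.95,
5-kb padding, FDRs 5%/20%, stepwise p 0.05). The desk preset used by the
test-suite fixtures and the acceptance script simulates 200 segregants ×
500 markers × 300 genes × 8 conditions × 12 hotspots and scales the
resampling counts to 200 sets/bootstraps and 50/100/150 subsamples; these
are the package's chosen validation problem sizes, and at them the whole
pipeline runs in well under a minute. The `full_config` preset mirrors
979 × 11,530 × 5,643 × 46 × 102.

## Numerical choices and degenerate inputs

Fisher CI widths floored at 10⁻⁶; |r| clipped to [−1, 1] before
t-transforms; REML δ searched on log₁₀ scale in [−8, 8] with endpoint
checks; two-QTL determinants floored at 10⁻³⁰⁰ before logs; k-means seeds
reduced mod 2³¹−1; empirical p-values always add-one; stepwise ties break
to the lowest index; collinear removal sets reduced by pivoted QR;
genotype files reject any entry outside {−1, +1} naming the offending
cell; subsample sizes larger than the panel, infeasible interval
packings, and constant traits raise typed errors. Stage seeds derive from
the global seed by mixing a CRC-32 of the stage name into a SeedSequence,
so stages are independent but individually reproducible.

## Known limitations

Desk-scale power limits are visible exactly where real small panels would
struggle: with 12 hotspot entries per effect vector the hotspot
correlations have a floor on attainable p-values, so few pairs pass 5%
FDR even when coefficients agree strongly with the genetic correlations;
conditions with weak enrichment profiles can land in the wrong k-means
cluster in some simulation seeds; and the truth-catalog detection
threshold means genes can lose eligible eQTLs to sampling noise. The
mediation stage reports associations transmitted through expression given
one marker; in the generator growth is driven by genotype directly, so
pipeline-level mediation findings reflect shared trans-architecture
rather than planted causal chains, and the dedicated mediation tests use
explicitly constructed mediator→outcome chains instead.
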