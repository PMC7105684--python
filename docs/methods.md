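# Methods

`gsblup` implements the two-step genomic-selection analysis used in
multi-environment perennial-grain breeding trials, together with a
synthetic breeding-program generator that makes every stage verifiable by
parameter recovery.

## Genotype filtering

Input genotypes are biallelic SNP calls per genet (a unique heterozygous
individual; these populations have no clonal replication), optionally with
per-call read depths from genotyping-by-sequencing. Filtering proceeds in a
fixed order:

1. **Depth rules** (when depth is available). A homozygous call supported
   by fewer than `min_hom_depth` reads (default 4) is set to missing — at
   low depth a true heterozygote is easily read as homozygous. A
   heterozygous call needs at least `min_het_contrasting` reads of *each*
   allele (default 2); this requires per-allele depths (VCF `AD`), and when
   only total depth is present the rule is skipped with a warning rather
   than approximated.
2. **Marker filters**: biallelic only; minor allele frequency strictly
   above `min_maf` (default 0.01); call rate at least
   `min_marker_call_rate` (default 0.30, inclusive).
3. **Genet filter**: genets with strictly more than `max_genet_missing`
   (default 0.95) missing calls are discarded.

Boundary semantics follow the phrasing the defaults were taken from: the
MAF and genet-missingness bounds are strict, the marker call-rate bound is
inclusive. Marker statistics are recomputed when the dosage matrix is
built, a single pass.

Missing dosages are imputed naively: `marker_mean` fills with the expected
dosage 2p (continuous values allowed), `random_hwe` draws Binomial(2, p).
Haplotype-phasing imputation is deliberately out of scope: the kinship
matrix is dominated by common variants, for which mean imputation is a
standard, adequate choice, and the imputation method is recorded in the run
log.

PCA for population structure runs on the centered (not standardized)
imputed dosage matrix, restricted to markers with MAF > 0.05 and
pre-imputation call rate > 0.50 (both strict). Component signs are fixed by
making each component's largest-magnitude loading positive, so scores are
invariant to genet ordering.

## Kinship

The realized additive genomic relationship matrix is the VanRaden / `A.mat`
form K = M_c M_c' / (2 Σ_k p_k(1−p_k)), with dosage columns centered by
2p_k and allele frequencies estimated from the current filtered, imputed
data (not founders), matching `A.mat` defaults. Monomorphic columns carry
no information and are excluded from both the product and the normalizer.
Under this scaling the expected diagonal is 1 + f and full sibs average
≈ 0.5.

REML needs a positive (semi)definite K. The default repair adds
max(0, ε − λ_min)·I (ridge, ε = 10⁻⁶), which raises the smallest eigenvalue
to exactly ε; an eigenvalue-floor reconstruction is available by flag.

## Stage 1: spatially corrected BLUPs

Per cycle and trait(-year), the model is

    y = X b + Z u + e,   u ~ N(0, σ²_A K),
    e ~ N(0, ⊕_s σ²_e[s] · Σ_c(ρ_c[s]) ⊗ Σ_r(ρ_r[s]))

with a separable AR1 × AR1 residual per site (column-major plot ordering)
and an independent error variance per site. Fixed effects are an intercept
plus a site main effect when a cycle spans two locations; additional
categorical covariates can be supplied but none are assumed. Trait-years
are treated as separate traits throughout, and each cycle is analyzed
separately (two-step design; no one-stage multi-trait model).

Estimation:

* For fixed autocorrelations and a single site, the residual is whitened by
  the closed-form Cholesky of the Kronecker AR1 correlation and the
  restricted likelihood is profiled exactly over δ = σ²_e/σ²_A by
  eigen-rotating Z̃KZ̃′ in the metric of the fixed-effect complement (the
  EMMA device): a 57-point log-grid over δ followed by bounded scalar
  minimization. Multi-site fits (separate σ²_e per site) maximize the dense
  restricted likelihood over log-variances by Nelder-Mead.
* Autocorrelations are searched by coordinate ascent: each ρ parameter is
  scanned over the coarse grid {−0.9 … 0.9, step 0.1} using the dense
  restricted likelihood at the current variance components (one Cholesky
  per candidate), an accepted move triggers a full inner variance solve,
  and the final grid optimum gets one quadratic (parabolic-vertex)
  refinement per parameter, clipped to (−0.95, 0.95).
* Reported log-likelihoods use the convention
  −2 l_R = log|V| + log|X′V⁻¹X| + r′V⁻¹r with constants dropped; values are
  comparable across candidates within a fit and match a dense evaluation at
  the optimum exactly.
* Variances are floored at 10⁻⁸ to keep V invertible. Missing plots are
  handled by subsetting the Kronecker correlation to observed plots — an
  approximation to full separable-residual handling that is exact when the
  grid is complete.

BLUPs are u = σ²_A K Z′V⁻¹(y − Xb̂). A cycle-trait combination with fewer
than 350 recorded observations is ineligible for stage 2 (override flag
available).

## Stage 2: GBLUP

On the per-genet stage-1 values, y = 1μ + g + e with g ~ N(0, σ²_g K) over
the training genets; the sole fixed effect is the intercept because stage-1
values are already adjusted. REML is exact over the single ratio
λ = σ²_e/σ²_g by eigen-rotation of the training submatrix of K. GEBVs for
every genet in K — phenotyped or not — are
K[·, t](K_tt + λI)⁻¹(y_t − μ̂), which is algebraically identical to ridge
regression on centered markers with penalty matched through the VanRaden
normalizer (verified to 10⁻⁶ in the tests). Duplicate records per genet
are averaged with a log message. Genomic heritability is
h² = σ²_g/(σ²_g + σ²_e).

**A caution on two-step heritability.** When the stage-2 response is a
single cycle's stage-1 BLUPs, the response vector lies exactly in the range
of K (u is K times a vector), so stage-2 REML can interpolate it with
σ²_e → 0 and h² ≈ 1 regardless of the trait: the stage-2 ratio then
measures the smoothness/reliability of its inputs, not trait heritability.
This double-shrinkage artifact is inherent to refitting a kinship model on
kinship-shrunken values. The pipeline's recoverable estimate of plot-level
heritability is the stage-1 ratio σ²_A/(σ²_A + mean_s σ²_e[s]), and that is
the quantity checked against simulated truth; the stage-2 h² is still
reported because it is the conventional summary of a genomic-selection fit
on multi-cycle or cross-validated responses, where exact interpolation does
not occur.

## Evaluation schemes

Prediction ability is the Pearson correlation between GEBVs and the
phenotypic BLUPs of predicted genets. Schemes:

* **Within-cycle CV**: genets split into 5 folds by random sampling without
  replacement, repeated 100 times (defaults). The correlation is computed
  per repetition by pooling all five folds' held-out predictions (more
  stable at small n than per-fold averaging, which remains available by
  flag); the mean and SD over repetitions are reported. Sibling leakage
  between folds is allowed by design.
* **Across-cycle**: one cycle trains, each other cycle is predicted;
  predicting the training cycle itself is routed to within-cycle CV and
  flagged.
* **Leave-one-cycle-out**: the training set is the union of all other
  cycles' genets with the trait; a single-cycle union degenerates to
  across-cycle prediction and is flagged.
* **Subset training**: the training union can be restricted to a PCA
  similarity group (split on a principal-component score, default
  threshold 0 — the centroid line) or to one breeding program.

Any model needs at least 100 training genets. 95% intervals use the Fisher
z transform, tanh(atanh(r) ± 1.96/√(n−3)). A candidate model beats the
leave-one-out reference only when the 95% intervals do not overlap; no
multiple-testing correction is applied across trait/cycle combinations,
matching the CI-overlap procedure itself. Seeded runs are bit-reproducible.

## The generator

The simulator emulates the study design the pipeline targets: heterozygous
outcrossing genets descended from common founders through cycles of
recurrent truncation selection.

* **Founders**: allele frequencies ~ Uniform(0.05, 0.95), haplotypes iid
  Bernoulli(p) (HWE, unrelated). Markers are unlinked by default; a
  block-linkage mode is available for kinship realism.
* **Architecture**: `n_qtl` markers get additive effects; per-site effect
  vectors follow compound symmetry a_s = √ρ·a_shared + √(1−ρ)·a_s′, so
  breeding values correlate ≈ `ge_correlation` between any two sites. This
  models G×E as a between-site genetic correlation rather than explicit
  QTL×E terms — enough to produce the within- vs across-environment
  prediction gap with one knob. Presets: `domestication_like` (10 QTL,
  ρ_GE = 0.95) and `agronomic_like` (500 QTL, ρ_GE = 0.3).
* **Cycles**: top `selection_fraction` by a noisy phenotype of the shared
  genetic value (heritability `h2_target`), mated by random intermating
  (two distinct parents per progeny, Mendelian gametes) or open-pollination
  half-sib families.
* **Phenotypes**: each cycle grows at its own site on a near-square
  row/column grid with random plot assignment; plot error is an AR1 × AR1
  Gaussian field (share `spatial_variance_fraction` of the error variance,
  default 0.5) plus white noise, scaled so the realized single-site
  heritability matches `h2_target`.
* **GBS re-observation**: per-call depth ~ Poisson(`mean_depth`, default
  8×), allele reads Binomial(depth, g/2); depth 0 is missing and a
  heterozygote whose reads all come from one allele is miscalled
  homozygous — exactly the error the depth filters target.

Defaults (50 founders, 2,000 markers, 100 QTL, 3 cycles of 500 genets, 20%
selected, h² = 0.5) describe a mid-sized breeding program at desk scale.
What the generator does **not** emulate: a real genome (chromosome count,
allopolyploidy, recombination maps), dominance/epistasis, non-separable
spatial trends, or year-within-site structure — so passing recovery tests
demonstrate correctness of the estimators under their assumptions, not
performance on any particular real crop data set.

## Verification problem sizes

The recovery experiments run at: heritability — one cycle of 600 genets ×
2,000 markers, 10 simulations per target h² ∈ {0.3, 0.6}, medians compared;
spatial autocorrelation — 20 × 20 grids, truths {0.2, 0.5, 0.8}, 20
replicates, generated with fully spatial plot error so the data match the
no-nugget AR1 × AR1 residual being estimated; transferability — 20
simulated worlds of two 250-genet cycles × 1,000 markers per architecture
preset, within-cycle CV at 5 repetitions against across-cycle prediction.
Oracle checks use dense grid searches of the same restricted-likelihood
expression implemented independently of the fitting path.

## Known limitations

* The AR1 × AR1 residual has no independent nugget term; when real plot
  error mixes spatial and iid components the autocorrelation estimates are
  attenuated (the variance split σ²_A vs σ²_e is much less affected).
* Grid-gap handling subsets the separable correlation rather than
  augmenting phantom plots, which differs slightly from ASReml-style
  separable-residual handling on incomplete grids.
* The stage-2 heritability caveat above.
* Naive imputation understates dosage uncertainty; with very low read
  depth (< 4×) kinship attenuates noticeably even after filtering.
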