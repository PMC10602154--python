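# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and what the validation studies do and do not demonstrate.

## Scope and data model

The pipeline operates on a samples × peaks matrix of log-scale chromatin
accessibility with aligned per-sample metadata (diagnosis, age, sex,
technical covariates, optional polygenic score), a peak universe of sorted
0-based half-open genomic intervals, and — for the single-cell and genetic
stages — a sparse cell × peak count matrix with cell-type/donor labels and
a variant weight table with a dosage matrix. Coordinates are BED-convention
throughout; 1-based variant positions are converted at the boundary
(a variant at 1-based position p lies in peak [start, end) iff
start + 1 ≤ p ≤ end).

Normalization is counts-per-million followed by log2(x + 1): monotone,
scale-invariant per sample, and standard for accessibility matrices.
Covariate correction is OLS residualization per peak (intercept +
covariates); the diagnosis label is structurally protected from being
residualized out. Downstream models may additionally include covariates —
both idioms are supported deliberately.

## Synthetic cohort generator

The generator is the package's substitute for restricted cohort data and
defines the study conditions of every validation:

- **Layout.** `n_chromosomes` × `peaks_per_chromosome` non-overlapping
  500 bp peaks with random 0.2–2 kb gaps. Planted CRDs are contiguous index
  blocks (sizes from `crd_sizes`, dealt round-robin to chromosomes, placed
  at random non-overlapping offsets). CRD i belongs to TRD `i mod n_trds`;
  TRD 1 is the disease TRD.
- **Copula.** Accessibility is Gaussian on the log2 scale. Each TRD has a
  factor F; each CRD a factor G = √ρ_b·F + √(1−ρ_b)·e; each member peak
  X = √ρ_w·G + √(1−ρ_w)·ε, giving within-CRD correlation ρ_w
  (`within_crd_correlation`) and between-CRD-factor correlation ρ_b
  (`trd_cross_correlation`) inside a TRD, 0 across TRDs. Background peaks
  are independent. A per-peak N(4, 1) baseline keeps the exponential
  (counts-scale) view strictly positive.
- **Genetics and severity.** Dosages are Binomial(2, MAF) with MAF ~
  U(0.05, 0.5); about half the variants fall inside peaks. Variants inside
  affected peaks carry N(0, 1) weights; 10% of the rest carry small N(0,
  0.1) weights. The true genetic score g is the standardized weighted
  centered-dosage sum; latent severity is r·g + √(1−r²)·noise with r =
  `severity_prs_correlation`. Diagnosis labels the top `n_cases` samples of
  severity + N(0, 1) ranking noise, so cases stochastically dominate
  controls in severity while diagnosis remains probabilistic.
- **Disease effect.** Affected peaks (a `fraction_affected_peaks` share of
  the universe, drawn from disease-TRD members first, the remainder flagged
  background) receive a shift proportional to centered severity in *every*
  sample, scaled so the realized case-minus-control mean difference equals
  `disease_effect_size` exactly, with sign +1 for an `affected_up_fraction`
  share of peaks. Tying the shift to the continuous severity scale (rather
  than a flat case offset) is what makes disease pseudotime a recoverable
  quantity for controls as well as cases.
- **Covariates.** Sex and batch (binary) and age (N(60, 15), clipped) with
  per-peak N(0, 1) loadings scaled by `covariate_effects` coefficients.
- **Single cell.** Cell types and donors are assigned uniformly (12 donors,
  half labelled early / half late); per-peak propensities are exp(N(0, 1))
  with a per-donor log-normal wobble (σ = 0.2) that makes the per-donor
  random intercept of the enrichment model identifiable; peaks in a type's
  signal set get a fixed 2× propensity boost; counts are multinomial with
  log-normal depth (≥ 1, so no zero-depth cells).
- **Determinism.** One RNG stream per simulated object, derived from the
  master seed by fixed labels — identical configs give bit-identical
  outputs, and the genotype stream is replayed identically by
  `simulate_genotypes`.

Defaults mirror the cohort scale the package targets (392 samples, 157
cases) and plant 20 CRDs of 8–25 peaks at ρ_w = 0.7 in 3 TRDs at ρ_b = 0.6,
with a 0.8-SD disease effect on 10% of peaks — conditions under which every
stage should, and does, recover its planted structure.

What the generator does **not** emulate: fragment-level ATAC noise,
GC/sequence composition, LD between variants, peak-width variation,
batch-by-peak interactions beyond a single loading, and GWAS estimation
noise in the weight table. Passing validations demonstrate correctness of
the inference machinery under the stated generative model, not performance
on real tissue data.

## Stage-specific notes

**Differential peaks.** Vectorized OLS with a two-level group factor;
two-sided t p-values (n − p dof), BH across all peaks of the analysis
(genome-wide, no per-chromosome adjustment). Constant peaks report p = 1,
log2FC = 0 and belong to neither direction set. An optional
variance-moderation flag blends per-peak variances 50/50 with their grand
mean for small cohorts; the transparent unmoderated fit is the default.

**CRD calling.** Constrained agglomeration: only genomically adjacent
clusters may merge (contiguity is the defining cis property); similarity is
the mean cross-pair Pearson r, computed in O(1) per pair from a 2-D prefix
sum of the chromosome correlation matrix; ties take the leftmost pair.
Accepted domains are maximal subtrees that are *coherent* (every internal
merge reached `r_threshold`) with mean internal correlation ≥ `r_threshold`
and ≥ `min_peaks` members. The coherence condition was added after
measuring that the mean-internal criterion alone lets a strong core absorb
uncorrelated flanking peaks by dilution (a 20-peak block at r = 0.7 keeps
its mean above 0.3 until ~10 junk peaks have attached); with it, planted
blocks are recovered at peak-level ARI 1.0 under the default conditions.
Defaults r_threshold = 0.3, min_peaks = 3 put ~39% of peaks inside domains
under the default generator, matching the scale reported for neuronal
cohorts (roughly a third of OCRs inside CRDs, ~20 OCRs per CRD, ~25 kb
median length).

**Two-stage differential-CRD test.** Screening: per-CRD two-sample
Hotelling T² across member peaks (exact under Gaussianity), BH at α.
Confirmation: t test on the domain mean signal, Bonferroni within the
screened set; a CRD is differential iff both stages pass. With
n ≤ p + 2 the screen falls back to the domain-mean t (logged). Under the
global null the measured any-rejection rate is ~3% over 200 seeds (BH's
guarantee is ≤ 5%); sensitivity for 0.8-SD domain shifts at n = 300 is ~1.

**Gamma statistic.** Baker–Hubert convention: ties contribute to neither
s⁺ nor s⁻; computed by sorting between-pair distances and binary search
(O((w + b) log b)), verified exactly against full enumeration. Note an
inherent selection effect: under complete independence, cutting the tree at
large k picks the smallest chance distances as within-pairs, so the null
Gamma trace rises with k (≈0.6 at k = 9 for 30 independent CRDs). Gamma is
therefore used comparatively (argmax over k against a pronounced peak, with
smallest-k tie-breaking), not as an absolute threshold.

**TRDs.** Average linkage (complete available by flag) on 1 − r of
per-sample domain signals, restricted to two-stage-significant CRDs in the
published workflow (`crd_diff=None` clusters all CRDs, used by recovery
studies). Constant-signal CRDs are dropped with a warning. k is selected by
Gamma over `k_range` (ties → smallest k). A TRD is flagged "predominantly
upregulated" when its up-CRD fraction exceeds 0.75 (configurable).

**Pseudotime.** Signature peaks are z-scored; a union-symmetrized kNN graph
(Euclidean, default 15 neighbors) with adaptive Gaussian kernel (bandwidth
= distance to the k-th neighbor) is row-normalized into a transition
operator; its top nontrivial right eigenvectors (unit-norm, deterministic
sign) form the diffusion map, scaled by eigenvalues for reporting. DPT is
the Euclidean distance from the root in ψ-space weighted λ/(1 − λ), min–max
scaled to [0, 1] (root at 0). The root defaults to the control sample with
minimal mean signature accessibility — the least-perturbed pole — and is
overridable. Stages are Leiden communities (RB configuration, fixed seed)
on the same graph, relabeled 1..K by ascending mean pseudotime; the default
resolution 1.0 yields the planted cluster count on well-separated synthetic
data. Pseudotime is computed on cases and controls jointly; per-group runs
are possible by subsetting the matrix first. Exact duplicates embed
identically (self-exclusion in the kNN is by index, not by rank).

**Single-cell enrichment.** Observed statistic: fraction of a cell's depth
in the target set (depth-invariant). Background sets match the target's
per-peak mean-accessibility deciles (no sequence covariates — synthetic
data has no sequence; the binning is a hook for richer matching).
z = (obs − mean_bg)/sd_bg with B ≥ 20 background draws. Because all cells
share one target draw, a single random target yields one ~unit-variance
set-level deviation common to all cells; calibration statements are about
averages over many target draws, and the cell-type contrast (which is
within-dataset) is unaffected. The one-vs-rest test is a linear mixed model
with a per-donor random intercept, falling back to cluster-robust (or, with
a single donor, plain) OLS when the random effect is unidentifiable; BH is
applied across the (type × stage) scan. The inside-vs-outside-TRD
comparison is a paired per-cell contrast of two z-score sets within the
focal type.

**PRS.** Scores are weighted dosage sums (variant-order invariant; missing
dosages mean-imputed per variant, variants > 20% missing dropped).
Association is logistic regression of case status on the SD-standardized
score; variance explained is Nagelkerke pseudo-R², and the TRD-ranking
quantity is R²/n_variants. Complete separation falls back to an
L2-penalized fit with a notice.

## Validation studies and problem sizes

The studies in `chromdomains.validation` (run by `tests/test_acceptance.py`
and `scripts/acceptance.py`) use desk-scale versions of the default
conditions, chosen to keep the full suite fast while leaving planted
structure clearly recoverable: 300-sample cohorts; 2×400-peak universes for
CRD recovery (10 seeds); 1,000 five-peak null CRDs × 100 seeds for
false-discovery calibration (the per-seed FDP under a global null is an
any-rejection indicator, so 100 seeds are used for a stable mean); 45 CRDs
in 3 TRDs × 25 seeds for TRD recovery; 500 signature peaks × 25 seeds for
pseudotime; 200 brute-force instances each for the CRD, Gamma, and DPT
oracles; 10-seed end-to-end null runs with 500 cells; 25 seeds for the PRS
ranking; n = 3,000 peaks for fold-change correlation.

## Known limitations

- The CRD merge tree is greedy; no optimality guarantee beyond agreement
  with the stated rule (verified exactly against the naive oracle).
- Hotelling screening assumes approximate normality of residualized
  accessibility; heavy-tailed real data may need the domain-mean fallback.
- The two-stage FDR guarantee is inherited from BH under positive
  dependence; adversarial covariance structures are not characterized.
- The mixed model uses a random intercept only; donor-by-type interactions
  are not modelled.
- Interval PRS ignores LD: a variant is in or out by position alone.
- Repeated-donor designs (the same donor in two brain regions) are out of
  scope; one region/cell population at a time is the supported path.
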