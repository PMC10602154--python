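# chromdomains

Analysis of population-scale case/control chromatin accessibility (ATAC-seq)
through the hierarchy of regulatory organization: differential open-chromatin
regions (OCRs), **cis-regulatory domains** (CRDs) assembled from
inter-individual correlation, **trans-regulatory domains** (TRDs) found by
clustering CRDs, per-sample **disease pseudotime** staging, single-cell
enrichment of bulk-derived OCR sets, and **interval-restricted polygenic
scores** partitioned by TRD.

It is written for epigenomics groups analyzing cohort-scale accessibility
matrices (hundreds of samples × 10⁵–10⁶ peaks at full scale) who want the
domain-level view of disease dysregulation rather than peak-by-peak lists.
Because raw cohort data of this kind is rarely shareable, the package ships a
first-class synthetic cohort generator that plants recoverable ground truth —
every stage is validated end-to-end against what was planted.

## The models in brief

- **Differential OCRs** — per peak, `accessibility ~ group + covariates`
  (OLS); log₂FC is the group coefficient, significance by Benjamini–Hochberg
  FDR < 5%; significant peaks split into up/down by sign of log₂FC.
- **CRDs** — per chromosome, adjacent-only agglomerative clustering of peaks
  where cluster similarity is the mean cross-pair Pearson r of inter-individual
  accessibility. Called domains are maximal coherent subtrees: every internal
  merge reached `r_threshold` (default 0.3), mean internal correlation ≥
  `r_threshold`, size ≥ `min_peaks` (default 3).
- **Differential CRDs** — a two-stage test at FDR < 5%: screening by
  two-sample Hotelling T² across member peaks (BH), confirmation by a t test
  on the domain mean signal (Bonferroni within the screened set).
- **TRDs** — average-linkage hierarchical clustering of disease CRDs on
  `1 − r` of their per-sample mean signals; the number of clusters k is the
  argmax of the Goodman–Kruskal (Baker–Hubert) Gamma statistic
  `Γ = (s⁺ − s⁻)/(s⁺ + s⁻)` over candidate cuts.
- **Disease pseudotime** — diffusion-map embedding of samples on the
  upregulated-OCR signature; diffusion pseudotime (DPT) from a
  least-perturbed control root with components weighted λ/(1 − λ); Leiden
  communities on the sample kNN graph give ordinal stages; associations
  include logistic `case ~ pseudotime` and `stage ~ PRS + Age + Age² + Sex`.
- **Single-cell enrichment** — per-cell deviation z-scores of a target OCR
  set against accessibility-decile-matched background sets, tested per cell
  type with `z ~ celltype + (1|sample)` (one-vs-rest mixed model).
- **Partitioned PRS** — weighted dosage sums restricted to variants inside a
  TRD's peaks; logistic OR per SD, Nagelkerke R², and variance explained per
  variant for ranking TRDs.

## Worked example

```python
import chromdomains as cd

peaks, matrix, truth = cd.simulate_bulk(cd.SimConfig(seed=7))
resid = cd.residualize(matrix, ["age", "sex", "batch"])

diff = cd.differential_peaks(resid)
up, down = cd.direction_partition(diff)

domains = cd.build_crds(resid, peaks)
crd_diff = cd.two_stage_crd_test(domains, resid)
trds = cd.build_trds(domains, k_range=range(2, 10))
```

Running `python examples/03_crd_trd_domains.py` prints (seed 7):

```
CRD summaries: {'n_crds': 20.0, 'mean_peaks_per_crd': 15.7,
                'median_length_bp': 21890.5, 'fraction_peaks_in_crds': 0.3925}
inside/outside enrichment: OR per unit |t| = 1.571 (p = 2e-16)
differential CRDs (two-stage, FDR < 5%): 7
TRDs: Gamma selects k = 3; trace = {2: 0.873, 3: 1.0, 4: 0.989, ...}
```

All 20 planted CRDs are recovered (≈39% of peaks inside domains), peaks with
strong disease statistics are enriched inside domains (OR > 1), and the Gamma
trace peaks exactly at the three planted trans modules. The other scripts in
`examples/` walk through simulation, differential analysis, pseudotime
staging (Spearman ≈ 0.94 against planted severity at seed 7), single-cell
enrichment, and TRD-partitioned PRS (the disease TRD ranks first in variance
explained per variant).

A full pipeline run from one config, with a manifest of output hashes:

```bash
chromdomains run config.yaml --outdir run1
```

## Layout

```
src/chromdomains/
  simulate.py     # synthetic cohort generator (planted ground truth)
  peaks.py        # BED I/O, peak universe (0-based half-open throughout)
  matrix.py       # normalization (CPM + log2), residualization, links
  differential.py # per-peak model, up/down partition, BED export
  domains.py      # CRDs, two-stage test, Gamma, TRDs, fold-change corr.
  pseudotime.py   # diffusion map, DPT, Leiden staging, associations
  single_cell.py  # deviation z-scores, mixed-model cell-type test
  prs.py          # interval-restricted scoring and association
  workflow.py     # pipeline runner + manifest
  validation.py   # recovery studies and naive reference oracles
```

See `docs/methods.md` for assumptions, parameter choices, and limitations.
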