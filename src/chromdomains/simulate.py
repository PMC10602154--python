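"""Synthetic study generator with planted, recoverable ground truth.

Emulates a case/control chromatin-accessibility cohort: peaks laid out along
chromosomes, a Gaussian copula planting correlation blocks (cis-regulatory
domains, CRDs) whose block factors are cross-correlated within trans groups
(TRDs), a latent per-sample disease severity tied to a simulated polygenic
score, case/control mean shifts concentrated in one disease TRD, covariate
effects, a sparse single-cell matrix with cell-type-specific signal, and a
variant dosage/weight pair for polygenic scoring.

All randomness derives from one master seed through fixed per-object stream
labels, so e.g. regenerating the cell matrix never perturbs the bulk matrix,
and identical configs give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

from ._utils import stream_rng
from .matrix import AccessibilityMatrix
from .peaks import PeakSet

# Fixed generator constants (documented in docs/methods.md)
_PEAK_WIDTH = 500          # bp per synthetic peak
_BASELINE_MEAN = 4.0       # log2-scale baseline accessibility, per peak N(4,1)
_DIAGNOSIS_NOISE_SD = 1.0  # noise on the severity ranking that assigns cases
_CELL_SIGNAL_BOOST = 2.0   # open-probability multiplier for planted signal
_DONOR_WOBBLE_SD = 0.2     # per-donor log-scale accessibility wobble
_N_CELL_DONORS = 12        # donors represented in the single-cell matrix
_VARIANT_IN_PEAK_FRAC = 0.5
_BACKGROUND_WEIGHT_FRAC = 0.1   # fraction of outside-peak variants w/ weight
_BACKGROUND_WEIGHT_SD = 0.1


def _default_crd_sizes() -> tuple[int, ...]:
    # 20 planted CRDs spanning 8..25 peaks, mirroring reported CRD sizes
    # (~19-22 OCRs per CRD on average in the cohort this emulates).
    return tuple(8 + (i % 18) for i in range(20))


@dataclass(frozen=True)
class SimConfig:
    """Study design of the synthetic cohort.

    Defaults emulate the real cohort's scale where it is known (157
    schizophrenia cases vs 235 controls per region/cell type) and otherwise
    use desk-scale values that keep planted structure recoverable.
    """

    n_samples: int = 392
    n_cases: int = 157
    n_chromosomes: int = 2
    peaks_per_chromosome: int = 400
    crd_sizes: tuple[int, ...] = field(default_factory=_default_crd_sizes)
    within_crd_correlation: float = 0.7
    n_trds: int = 3
    trd_cross_correlation: float = 0.6
    disease_effect_size: float = 0.8
    fraction_affected_peaks: float = 0.1
    affected_up_fraction: float = 1.0
    severity_prs_correlation: float = 0.5
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: {"sex": 0.3, "batch": 0.5}
    )
    n_cells: int = 1000
    n_cell_types: int = 5
    celltype_signal_fraction: float = 0.1
    n_variants: int = 2000
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "crd_sizes", tuple(self.crd_sizes))
        self.validate()

    def validate(self) -> None:
        def bad(name, why):
            raise ValueError(f"invalid SimConfig.{name}: {why}")

        if self.n_cases >= self.n_samples:
            bad("n_cases", "must be < n_samples")
        if self.n_cases < 0 or self.n_samples < 2:
            bad("n_samples", "need >= 2 samples and n_cases >= 0")
        for name in ("within_crd_correlation", "trd_cross_correlation",
                     "severity_prs_correlation"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                bad(name, "must lie in [0, 1)")
        if self.within_crd_correlation <= 0.0:
            bad("within_crd_correlation", "must lie strictly in (0, 1)")
        if not (0.0 <= self.fraction_affected_peaks <= 1.0):
            bad("fraction_affected_peaks", "must be a proportion")
        if not (0.0 <= self.affected_up_fraction <= 1.0):
            bad("affected_up_fraction", "must be a proportion")
        if not (0.0 <= self.celltype_signal_fraction <= 1.0):
            bad("celltype_signal_fraction", "must be a proportion")
        if self.n_trds < 1 or self.n_trds > max(1, len(self.crd_sizes)):
            bad("n_trds", "must be between 1 and the number of CRDs")
        if min(self.crd_sizes, default=2) < 2:
            bad("crd_sizes", "every planted CRD needs >= 2 peaks")
        # CRDs are dealt round-robin to chromosomes; each chromosome must fit
        per_chrom = [0] * self.n_chromosomes
        for i, s in enumerate(self.crd_sizes):
            per_chrom[i % self.n_chromosomes] += s
        if max(per_chrom, default=0) > self.peaks_per_chromosome:
            bad("crd_sizes",
                f"sum of CRD sizes per chromosome ({max(per_chrom)}) exceeds "
                f"peaks_per_chromosome ({self.peaks_per_chromosome})")
        if self.n_cell_types < 1:
            bad("n_cell_types", "must be >= 1")
        if self.n_variants < 1:
            bad("n_variants", "must be >= 1")


@dataclass
class GroundTruth:
    """Planted structure: what a perfect analysis should recover."""

    peak_to_crd: dict[str, int | None]
    crd_to_trd: dict[int, int]
    crd_members: dict[int, list[str]]
    affected_peaks: dict[str, int]       # peak_id -> +1 / -1 shift sign
    affected_background: set[str]        # affected peaks outside any CRD
    sample_severity: pd.Series
    sample_prs_true: pd.Series
    celltype_signal_peaks: dict[str, list[str]]
    variant_weights_true: pd.Series
    disease_trd: int = 0
    _dosages: pd.DataFrame | None = None
    _variant_table: pd.DataFrame | None = None

    @property
    def trd_members(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {}
        for crd, trd in self.crd_to_trd.items():
            out.setdefault(trd, []).append(crd)
        return out


# ---------------------------------------------------------------------------
# Layout
# ---------------------------------------------------------------------------

def _layout(config: SimConfig):
    """Peak coordinates plus CRD block placement (index space) per chromosome."""
    rng = stream_rng(config.seed, "layout")
    chroms, starts, ends = [], [], []
    crd_blocks: list[tuple[int, int, int]] = []  # (crd_index, lo, hi) global idx
    crd_chrom_assign: dict[int, list[int]] = {
        c: [] for c in range(config.n_chromosomes)
    }
    for i in range(len(config.crd_sizes)):
        crd_chrom_assign[i % config.n_chromosomes].append(i)
    offset = 0
    for c in range(config.n_chromosomes):
        name = f"chr{c + 1}"
        n = config.peaks_per_chromosome
        gaps = rng.integers(200, 2000, size=n)
        pos = np.cumsum(gaps + _PEAK_WIDTH) - _PEAK_WIDTH
        chroms.extend([name] * n)
        starts.extend(pos.tolist())
        ends.extend((pos + _PEAK_WIDTH).tolist())
        # place this chromosome's CRDs as non-overlapping contiguous runs
        crds_here = crd_chrom_assign[c]
        sizes = [config.crd_sizes[i] for i in crds_here]
        free = n - sum(sizes)
        cuts = np.sort(rng.integers(0, free + 1, size=len(sizes)))
        cursor = 0
        for j, (crd_i, size) in enumerate(zip(crds_here, sizes)):
            lo = offset + cursor + int(cuts[j])
            crd_blocks.append((crd_i, lo, lo + size))
            cursor += size
        offset += n
    peaks = PeakSet.from_arrays(chroms, starts, ends)
    return peaks, crd_blocks


# ---------------------------------------------------------------------------
# Genotype internals (shared between simulate_bulk and simulate_genotypes)
# ---------------------------------------------------------------------------

def _genotype_internals(config: SimConfig, peaks: PeakSet,
                        affected: dict[str, int]):
    """Variants, dosages, true weights and the standardized genetic score.

    Deterministic given (seed, layout): simulate_bulk and simulate_genotypes
    both call this and obtain bit-identical objects.
    """
    rng = stream_rng(config.seed, "genotypes")
    n_s, n_v = config.n_samples, config.n_variants
    t = peaks.table
    n_p = len(t)
    in_peak = rng.random(n_v) < _VARIANT_IN_PEAK_FRAC
    host = rng.integers(0, n_p, size=n_v)
    offsets = rng.integers(0, _PEAK_WIDTH, size=n_v)
    chrom = np.empty(n_v, dtype=object)
    pos = np.empty(n_v, dtype=np.int64)
    host_peak = np.empty(n_v, dtype=object)
    chrom_arr = t["chrom"].to_numpy()
    start_arr = t["start"].to_numpy()
    end_arr = t["end"].to_numpy()
    pid_arr = t["peak_id"].to_numpy()
    for v in range(n_v):
        h = host[v]
        chrom[v] = chrom_arr[h]
        if in_peak[v]:
            pos[v] = start_arr[h] + offsets[v] + 1  # 1-based, inside [start,end)
            host_peak[v] = pid_arr[h]
        else:
            pos[v] = end_arr[h] + offsets[v] + 50  # intergenic, past the peak
            host_peak[v] = None
    maf = rng.uniform(0.05, 0.5, size=n_v)
    dosages = rng.binomial(2, maf, size=(n_s, n_v)).astype(np.int8)
    weights = np.zeros(n_v)
    in_affected = np.array(
        [hp is not None and hp in affected for hp in host_peak]
    )
    weights[in_affected] = rng.normal(0.0, 1.0, size=int(in_affected.sum()))
    bg = (~in_affected) & (rng.random(n_v) < _BACKGROUND_WEIGHT_FRAC)
    weights[bg] = rng.normal(0.0, _BACKGROUND_WEIGHT_SD, size=int(bg.sum()))
    # true genetic score: weighted centered dosage sum, standardized
    centered = dosages - 2.0 * maf
    g_raw = centered @ weights
    sd = g_raw.std(ddof=0)
    g = g_raw / sd if sd > 0 else np.zeros(n_s)
    variant_ids = [f"var_{v:06d}" for v in range(n_v)]
    vtab = pd.DataFrame(
        {
            "variant_id": variant_ids,
            "chrom": chrom,
            "pos": pos,
            "weight": weights,
            "host_peak": host_peak,
            "maf": maf,
        }
    )
    sample_ids = [f"S{s:04d}" for s in range(n_s)]
    dos = pd.DataFrame(dosages, index=sample_ids, columns=variant_ids)
    return vtab, dos, pd.Series(g, index=sample_ids, name="prs_true")


# ---------------------------------------------------------------------------
# Bulk simulation
# ---------------------------------------------------------------------------

def simulate_bulk(config: SimConfig):
    """Generate (PeakSet, AccessibilityMatrix, GroundTruth).

    Accessibility is Gaussian on the log2 scale: block factors give
    ``within_crd_correlation`` inside planted CRDs and
    ``trd_cross_correlation`` between CRD factors of one TRD; TRDs are
    mutually independent.  Affected peaks gain a severity-proportional shift
    scaled so the realized case-minus-control mean difference equals
    ``disease_effect_size``.
    """
    config.validate()
    peaks, crd_blocks = _layout(config)
    n_s = config.n_samples
    sample_ids = [f"S{s:04d}" for s in range(n_s)]
    pid = peaks.table["peak_id"].to_numpy()
    n_p = len(pid)

    # planted assignment maps
    peak_to_crd: dict[str, int | None] = {p: None for p in pid}
    crd_members: dict[int, list[str]] = {}
    for crd_i, lo, hi in crd_blocks:
        crd_members[crd_i] = list(pid[lo:hi])
        for p in pid[lo:hi]:
            peak_to_crd[p] = crd_i
    crd_to_trd = {i: i % config.n_trds for i in range(len(config.crd_sizes))}
    disease_trd = 0

    # affected peaks: disease-TRD members first, then flagged background
    rng = stream_rng(config.seed, "bulk")
    n_affected = int(round(config.fraction_affected_peaks * n_p))
    disease_peaks = [
        p for crd_i, trd in crd_to_trd.items() if trd == disease_trd
        for p in crd_members[crd_i]
    ]
    background_pool = [p for p in pid if peak_to_crd[p] is None]
    affected_ids: list[str] = []
    if n_affected <= len(disease_peaks):
        affected_ids = list(
            rng.choice(disease_peaks, size=n_affected, replace=False)
        )
    else:
        affected_ids = list(disease_peaks)
        extra = n_affected - len(disease_peaks)
        extra = min(extra, len(background_pool))
        affected_ids += list(
            rng.choice(background_pool, size=extra, replace=False)
        )
    signs = np.where(
        rng.random(len(affected_ids)) < config.affected_up_fraction, 1, -1
    )
    affected = {p: int(s) for p, s in zip(affected_ids, signs)}
    affected_background = {p for p in affected if peak_to_crd[p] is None}

    # genotype-driven liability and severity
    vtab, dosages, prs_true = _genotype_internals(config, peaks, affected)
    rng_sev = stream_rng(config.seed, "severity")
    r = config.severity_prs_correlation
    severity = r * prs_true.to_numpy() + math.sqrt(1 - r * r) * rng_sev.normal(
        size=n_s
    )
    severity = pd.Series(severity, index=sample_ids, name="severity")

    # diagnosis: noisy top-n_cases ranking of severity
    rng_dx = stream_rng(config.seed, "diagnosis")
    rank_score = severity.to_numpy() + rng_dx.normal(
        0.0, _DIAGNOSIS_NOISE_SD, size=n_s
    )
    case_idx = np.argsort(-rank_score, kind="stable")[: config.n_cases]
    is_case = np.zeros(n_s, dtype=bool)
    is_case[case_idx] = True

    # copula: TRD factors -> CRD factors -> peak values
    rho_w = config.within_crd_correlation
    rho_b = config.trd_cross_correlation
    F = rng.normal(size=(n_s, config.n_trds))
    X = np.empty((n_s, n_p))
    in_crd = np.zeros(n_p, dtype=bool)
    col_of = {p: j for j, p in enumerate(pid)}
    for crd_i, lo, hi in crd_blocks:
        e = rng.normal(size=n_s)
        G = math.sqrt(rho_b) * F[:, crd_to_trd[crd_i]] + math.sqrt(1 - rho_b) * e
        m = hi - lo
        eps = rng.normal(size=(n_s, m))
        X[:, lo:hi] = math.sqrt(rho_w) * G[:, None] + math.sqrt(1 - rho_w) * eps
        in_crd[lo:hi] = True
    X[:, ~in_crd] = rng.normal(size=(n_s, int((~in_crd).sum())))

    # disease shift: severity-proportional, calibrated so the case-control
    # mean difference equals disease_effect_size
    if config.disease_effect_size != 0.0 and affected:
        sc = severity.to_numpy() - severity.to_numpy().mean()
        delta_real = sc[is_case].mean() - sc[~is_case].mean()
        if delta_real <= 0:
            delta_real = 1.0  # degenerate (e.g. n_cases=0); uncalibrated
        scale = config.disease_effect_size / delta_real
        cols = np.array([col_of[p] for p in affected])
        sgn = np.array([affected[p] for p in affected], dtype=float)
        X[:, cols] += scale * sc[:, None] * sgn[None, :]

    # covariates
    rng_cov = stream_rng(config.seed, "covariates")
    sex = np.where(rng_cov.random(n_s) < 0.5, "M", "F")
    batch = np.where(rng_cov.random(n_s) < 0.5, "b1", "b2")
    age = np.clip(np.round(rng_cov.normal(60, 15, size=n_s)), 20, 95)
    cov_numeric = {
        "sex": (sex == "F").astype(float),
        "batch": (batch == "b2").astype(float),
        "age": (age - age.mean()) / age.std(ddof=0),
    }
    for name, coef in config.covariate_effects.items():
        if name not in cov_numeric:
            raise ValueError(f"unknown simulated covariate: {name}")
        loading = rng_cov.normal(size=n_p)
        X += coef * cov_numeric[name][:, None] * loading[None, :]

    X += rng.normal(_BASELINE_MEAN, 1.0, size=n_p)[None, :]

    metadata = pd.DataFrame(
        {
            "diagnosis": np.where(is_case, "case", "control"),
            "age": age,
            "sex": sex,
            "batch": batch,
            "prs": prs_true.to_numpy(),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    values = pd.DataFrame(X, index=metadata.index, columns=pid)
    m = AccessibilityMatrix(values, metadata)

    # cell-type signal peaks (disjoint subsets per type)
    rng_ct = stream_rng(config.seed, "celltype_truth")
    k = int(round(config.celltype_signal_fraction * n_p))
    perm = rng_ct.permutation(n_p)
    celltype_signal: dict[str, list[str]] = {}
    for t_i in range(config.n_cell_types):
        name = f"type_{t_i + 1}"
        block = perm[t_i * k: (t_i + 1) * k]
        celltype_signal[name] = list(pid[np.sort(block)]) if k else []

    truth = GroundTruth(
        peak_to_crd=peak_to_crd,
        crd_to_trd=crd_to_trd,
        crd_members=crd_members,
        affected_peaks=affected,
        affected_background=affected_background,
        sample_severity=severity,
        sample_prs_true=prs_true,
        celltype_signal_peaks=celltype_signal,
        variant_weights_true=pd.Series(
            vtab["weight"].to_numpy(), index=vtab["variant_id"], name="weight"
        ),
        disease_trd=disease_trd,
        _dosages=dosages,
        _variant_table=vtab,
    )
    return peaks, m, truth


# ---------------------------------------------------------------------------
# Single-cell simulation
# ---------------------------------------------------------------------------

def simulate_single_cell(
    config: SimConfig, truth: GroundTruth, peaks: PeakSet
) -> ad.AnnData:
    """Sparse cell x peak count matrix with planted cell-type signal.

    Per-cell depth is log-normal (never zero); peaks in a type's signal set
    have 2x open probability in cells of that type; a mild per-donor wobble
    makes the sample-level random intercept of the enrichment model real.
    """
    if config.n_cell_types > 26:
        raise ValueError("n_cell_types exceeds available label space (26)")
    rng = stream_rng(config.seed, "cells")
    pid = peaks.table["peak_id"].to_numpy()
    n_p = len(pid)
    col_of = {p: j for j, p in enumerate(pid)}
    types = [f"type_{t + 1}" for t in range(config.n_cell_types)]

    donors = list(truth.sample_prs_true.index[: min(_N_CELL_DONORS,
                                                    len(truth.sample_prs_true))])
    donor_stage = {
        d: ("early" if i < len(donors) / 2 else "late")
        for i, d in enumerate(donors)
    }
    cell_type = rng.choice(types, size=config.n_cells)
    cell_donor = rng.choice(donors, size=config.n_cells)

    base = np.exp(rng.normal(0.0, 1.0, size=n_p))
    donor_wobble = {
        d: np.exp(rng.normal(0.0, _DONOR_WOBBLE_SD, size=n_p)) for d in donors
    }
    boost = {t: np.ones(n_p) for t in types}
    for t, sig in truth.celltype_signal_peaks.items():
        if t in boost and sig:
            idx = np.array([col_of[p] for p in sig])
            boost[t][idx] = _CELL_SIGNAL_BOOST

    depth = np.maximum(
        1, np.round(rng.lognormal(np.log(1000), 0.5, size=config.n_cells))
    ).astype(np.int64)
    rows = []
    for c in range(config.n_cells):
        w = base * donor_wobble[cell_donor[c]] * boost[cell_type[c]]
        p = w / w.sum()
        rows.append(sparse.csr_matrix(rng.multinomial(depth[c], p)))
    Xc = sparse.vstack(rows, format="csr")
    obs = pd.DataFrame(
        {
            "cell_type": pd.Categorical(cell_type),
            "sample_id": pd.Categorical(cell_donor),
            "stage_group": pd.Categorical(
                [donor_stage[d] for d in cell_donor]
            ),
            "depth": depth,
        },
        index=pd.Index([f"cell_{c:05d}" for c in range(config.n_cells)],
                       name="cell_id"),
    )
    return ad.AnnData(
        X=Xc, obs=obs, var=pd.DataFrame(index=pd.Index(pid, name="peak_id"))
    )


# ---------------------------------------------------------------------------
# Genotypes (public view of the shared internals)
# ---------------------------------------------------------------------------

def simulate_genotypes(config: SimConfig, peaks: PeakSet, truth: GroundTruth):
    """Return (dosage DataFrame samples x variants, weight table).

    Deterministic replay of the stream used inside simulate_bulk, so the
    emitted polygenic weights are exactly the ones whose score the planted
    severity was built from.
    """
    if truth._dosages is not None and truth._variant_table is not None:
        vtab, dos = truth._variant_table, truth._dosages
    else:
        vtab, dos, _ = _genotype_internals(config, peaks, truth.affected_peaks)
    weights = vtab[["variant_id", "chrom", "pos", "weight"]].copy()
    return dos, weights


# ---------------------------------------------------------------------------
# Auxiliary generators for calibration studies
# ---------------------------------------------------------------------------

def simulate_fold_changes(
    n: int, target_spearman: float, seed: int = 0
) -> tuple[pd.Series, pd.Series]:
    """Two per-peak fold-change vectors sharing a latent effect.

    Emulates comparing disease fold changes with fold changes from an
    independent contrast (e.g. fetal vs adult accessibility) over the same
    peak set.  For a bivariate Gaussian, Spearman rho_s relates to Pearson
    rho_p via rho_s = (6/pi) asin(rho_p / 2); the latent loading is chosen to
    hit the requested Spearman correlation.
    """
    if not (-1.0 < target_spearman < 1.0):
        raise ValueError("target_spearman must lie in (-1, 1)")
    rho_p = 2.0 * math.sin(math.pi * target_spearman / 6.0)
    rng = np.random.default_rng(seed)
    lam = math.sqrt(abs(rho_p))
    latent = rng.normal(size=n)
    a = lam * latent + math.sqrt(1 - lam * lam) * rng.normal(size=n)
    b = math.copysign(lam, rho_p) * latent + math.sqrt(1 - lam * lam) * rng.normal(size=n)
    ids = [f"peak_{i:05d}" for i in range(n)]
    return (pd.Series(a, index=ids, name="log2fc_a"),
            pd.Series(b, index=ids, name="log2fc_b"))
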