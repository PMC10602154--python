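"""Cis-regulatory domains (CRDs) and trans-regulatory domains (TRDs).

CRDs are genomically contiguous runs of peaks whose accessibility co-varies
across individuals.  They are assembled per chromosome by constrained
agglomeration: only adjacent clusters may merge, similarity is the mean
cross-pair Pearson correlation, and the called domains are the maximal
coherent subtrees of the merge tree — every merge inside a domain reached
the correlation threshold (a dendrogram cut), the domain's mean internal
correlation clears the same threshold, and it holds at least ``min_peaks``
peaks.  The coherence condition keeps weakly-attached flanking peaks out of
a domain instead of letting a strong core dilute them in.

TRDs are clusters of (typically disease-associated) CRDs, found by
average-linkage hierarchical clustering of 1 - r between per-sample domain
signals, with the number of clusters selected by the Goodman-Kruskal /
Baker-Hubert Gamma concordance index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from ._utils import bh_adjust
from .matrix import AccessibilityMatrix
from .peaks import PeakSet

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class DomainSet:
    """Called CRDs: membership, genomic spans, and per-sample mean signal."""

    table: pd.DataFrame = field(repr=False)   # per CRD summary rows
    members: dict[str, list[str]] = field(repr=False)  # crd_id -> peak_ids
    signal: pd.DataFrame = field(repr=False)  # samples x crd_ids
    peak_assignment: pd.Series = field(repr=False)  # peak_id -> crd_id/None

    def __len__(self) -> int:
        return len(self.table)

    @property
    def crd_ids(self) -> pd.Index:
        return pd.Index(self.table["crd_id"])

    def inside_ids(self) -> pd.Index:
        a = self.peak_assignment
        return a.index[a.notna()]


@dataclass
class CrdDifferential:
    """Two-stage differential-CRD decisions."""

    table: pd.DataFrame = field(repr=False)
    alpha: float = 0.05

    def significant_ids(self) -> pd.Index:
        return self.table.index[self.table["significant"]]


@dataclass
class TrdPartition:
    """CRD -> TRD labels plus the Gamma trace over candidate cluster counts."""

    assignment: pd.Series = field(repr=False)  # crd_id -> int label 1..k
    k: int = 0
    gamma_trace: dict[int, float] = field(default_factory=dict)
    linkage_matrix: np.ndarray | None = field(default=None, repr=False)

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for crd, lab in self.assignment.items():
            out.setdefault(int(lab), []).append(crd)
        return out


# ---------------------------------------------------------------------------
# CRD assembly
# ---------------------------------------------------------------------------

def _block_sum(P: np.ndarray, a: int, b: int, c: int, d: int) -> float:
    """Sum of corr[a:b, c:d] from the 2-D prefix array P."""
    total = P[b - 1, d - 1]
    if a > 0:
        total -= P[a - 1, d - 1]
    if c > 0:
        total -= P[b - 1, c - 1]
    if a > 0 and c > 0:
        total += P[a - 1, c - 1]
    return float(total)


def _merge_tree(corr: np.ndarray):
    """Constrained agglomeration over adjacent clusters.

    Returns the root node of the binary merge tree; nodes are dicts with
    half-open index spans ``lo:hi`` and child links.  Ties in the best
    adjacent similarity resolve to the leftmost pair (deterministic).
    """
    k = corr.shape[0]
    P = corr.cumsum(axis=0).cumsum(axis=1)
    nodes = [{"lo": i, "hi": i + 1, "left": None, "right": None,
              "sim": float("inf")} for i in range(k)]
    sims = [
        _block_sum(P, i, i + 1, i + 1, i + 2) for i in range(k - 1)
    ]  # singleton-singleton mean = the single correlation entry
    while len(nodes) > 1:
        i = int(np.argmax(sims))  # leftmost max
        a, b = nodes[i], nodes[i + 1]
        merged = {"lo": a["lo"], "hi": b["hi"], "left": a, "right": b,
                  "sim": float(sims[i])}
        nodes[i: i + 2] = [merged]
        del sims[i]
        if i > 0:
            l = nodes[i - 1]
            sims[i - 1] = _block_sum(
                P, l["lo"], l["hi"], merged["lo"], merged["hi"]
            ) / ((l["hi"] - l["lo"]) * (merged["hi"] - merged["lo"]))
        if i < len(nodes) - 1:
            r = nodes[i + 1]
            sims[i] = _block_sum(
                P, merged["lo"], merged["hi"], r["lo"], r["hi"]
            ) / ((merged["hi"] - merged["lo"]) * (r["hi"] - r["lo"]))
    return nodes[0], P


def _mean_internal(P: np.ndarray, diag: np.ndarray, lo: int, hi: int) -> float:
    """Mean pairwise (off-diagonal) correlation of the block lo:hi."""
    k = hi - lo
    if k < 2:
        return float("nan")
    total = _block_sum(P, lo, hi, lo, hi) - float(diag[lo:hi].sum())
    return total / (k * (k - 1))


def build_crds(
    m: AccessibilityMatrix,
    peaks: PeakSet,
    r_threshold: float = 0.3,
    min_peaks: int = 3,
) -> DomainSet:
    """Assemble CRDs from inter-individual peak correlation, per chromosome.

    A chromosome with fewer than ``min_peaks`` peaks is skipped with a log
    notice.  Peaks not falling in any accepted subtree are reported as
    outside-CRD (assignment ``None``).
    """
    if m.n_samples < 30:
        raise ValueError("need >= 30 samples for stable correlations")
    vals = m.values
    assignment = pd.Series(
        [None] * len(peaks), index=peaks.ids, dtype=object, name="crd_id"
    )
    records = []
    members: dict[str, list[str]] = {}
    crd_counter = 0
    for chrom, sub in peaks.by_chromosome().items():
        pids = sub["peak_id"].to_numpy()
        if len(pids) < min_peaks:
            logger.info("skipping %s: fewer than %d peaks", chrom, min_peaks)
            continue
        X = vals.loc[:, pids].to_numpy(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(X, rowvar=False)
        corr = np.nan_to_num(corr, nan=0.0)
        diag = np.diag(corr).copy()
        root, P = _merge_tree(corr)

        accepted: list[tuple[int, int, float]] = []

        def coherent(node) -> bool:
            # every merge inside the subtree reached the similarity threshold
            if node["left"] is None:
                return True
            return (node["sim"] >= r_threshold
                    and coherent(node["left"]) and coherent(node["right"]))

        def collect(node):
            lo, hi = node["lo"], node["hi"]
            size = hi - lo
            if size >= min_peaks and coherent(node):
                mic = _mean_internal(P, diag, lo, hi)
                if mic >= r_threshold:
                    accepted.append((lo, hi, mic))
                    return
            if node["left"] is not None:
                collect(node["left"])
                collect(node["right"])

        collect(root)
        for lo, hi, mic in sorted(accepted):
            crd_counter += 1
            cid = f"crd_{crd_counter:05d}"
            mem = list(pids[lo:hi])
            members[cid] = mem
            assignment.loc[mem] = cid
            records.append(
                {
                    "crd_id": cid,
                    "chrom": chrom,
                    "start": int(sub["start"].iloc[lo]),
                    "end": int(sub["end"].iloc[hi - 1]),
                    "n_peaks": hi - lo,
                    "mean_internal_correlation": mic,
                }
            )
    table = pd.DataFrame(
        records,
        columns=["crd_id", "chrom", "start", "end", "n_peaks",
                 "mean_internal_correlation"],
    )
    signal = pd.DataFrame(
        {cid: vals.loc[:, mem].mean(axis=1) for cid, mem in members.items()},
        index=vals.index,
    )
    return DomainSet(table=table, members=members, signal=signal,
                     peak_assignment=assignment)


def domains_from_truth(
    truth, peaks: PeakSet, m: AccessibilityMatrix
) -> DomainSet:
    """DomainSet built directly from planted ground truth (for recovery and
    calibration studies that isolate a downstream stage from CRD calling)."""
    records, members = [], {}
    assignment = pd.Series([None] * len(peaks), index=peaks.ids, dtype=object)
    coords = peaks.table.set_index("peak_id")
    for crd_i in sorted(truth.crd_members):
        mem = truth.crd_members[crd_i]
        cid = f"crd_{crd_i + 1:05d}"
        members[cid] = list(mem)
        assignment.loc[mem] = cid
        rows = coords.loc[mem]
        records.append(
            {
                "crd_id": cid,
                "chrom": rows["chrom"].iloc[0],
                "start": int(rows["start"].min()),
                "end": int(rows["end"].max()),
                "n_peaks": len(mem),
                "mean_internal_correlation": float("nan"),
            }
        )
    table = pd.DataFrame(records)
    signal = pd.DataFrame(
        {cid: m.values.loc[:, mem].mean(axis=1) for cid, mem in members.items()},
        index=m.values.index,
    )
    return DomainSet(table=table, members=members, signal=signal,
                     peak_assignment=assignment)


def crd_summaries(d: DomainSet) -> dict[str, float]:
    """Mean peaks per CRD, median domain length (bp), fraction of peaks inside."""
    if len(d) == 0:
        raise ValueError("crd_summaries requires a nonempty DomainSet")
    lengths = d.table["end"] - d.table["start"]
    n_inside = int(d.peak_assignment.notna().sum())
    return {
        "n_crds": float(len(d)),
        "mean_peaks_per_crd": float(d.table["n_peaks"].mean()),
        "median_length_bp": float(lengths.median()),
        "fraction_peaks_in_crds": n_inside / len(d.peak_assignment),
    }


# ---------------------------------------------------------------------------
# Inside/outside enrichment GLM
# ---------------------------------------------------------------------------

def inside_outside_glm(diff, d: DomainSet) -> tuple[float, float]:
    """Logistic regression of inside-CRD membership on |t| of the disease test.

    Returns (odds ratio per unit |t|, Wald p).  Mirrors the check that
    disease-associated peaks concentrate inside domains.
    """
    table = diff.table
    inside = d.peak_assignment.loc[table.index].notna().to_numpy(float)
    if inside.all() or not inside.any():
        raise ValueError("all peaks on one side (inside/outside) — separation")
    X = sm.add_constant(np.abs(table["t"].to_numpy(float)))
    fit = sm.Logit(inside, X).fit(disp=0)
    return float(np.exp(fit.params[1])), float(fit.pvalues[1])


# ---------------------------------------------------------------------------
# Two-stage differential-CRD test
# ---------------------------------------------------------------------------

def _hotelling_p(Xa: np.ndarray, Xb: np.ndarray) -> float:
    """Two-sample Hotelling T^2 p-value (any-member-peak group effect)."""
    n1, n2, p = Xa.shape[0], Xb.shape[0], Xa.shape[1]
    n = n1 + n2
    if n - p - 1 <= 0:
        raise np.linalg.LinAlgError("too many peaks for Hotelling T^2")
    d = Xa.mean(axis=0) - Xb.mean(axis=0)
    S = ((n1 - 1) * np.cov(Xa, rowvar=False, ddof=1)
         + (n2 - 1) * np.cov(Xb, rowvar=False, ddof=1)) / (n - 2)
    S = np.atleast_2d(S)
    t2 = (n1 * n2 / n) * float(d @ np.linalg.solve(S, d))
    f = (n - p - 1) / ((n - 2) * p) * t2
    return float(stats.f.sf(f, p, n - p - 1))


def two_stage_crd_test(
    d: DomainSet,
    m: AccessibilityMatrix,
    group: str = "diagnosis",
    case_level: str = "case",
    alpha: float = 0.05,
) -> CrdDifferential:
    """Screen-then-confirm differential test of CRDs at FDR ``alpha``.

    Stage 1 screens every CRD with an omnibus two-sample Hotelling T^2
    across its member peaks, Benjamini-Hochberg at ``alpha``.  Stage 2
    confirms screened CRDs with a t test on the domain mean signal,
    Bonferroni-corrected within the screened set.  A CRD is differential iff
    both stages pass; direction is the sign of the domain-signal log2fc.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    meta = m.metadata
    is_case = (meta[group].astype(str) == case_level).to_numpy()
    if is_case.sum() < 2 or (~is_case).sum() < 2:
        raise ValueError("need >= 2 samples per group")
    crd_ids = list(d.crd_ids)
    p_screen = np.empty(len(crd_ids))
    for i, cid in enumerate(crd_ids):
        X = m.values.loc[:, d.members[cid]].to_numpy(float)
        try:
            p_screen[i] = _hotelling_p(X[is_case], X[~is_case])
        except np.linalg.LinAlgError:
            # small-cohort fallback: domain-mean t as the omnibus screen
            sig = X.mean(axis=1)
            p_screen[i] = stats.ttest_ind(sig[is_case], sig[~is_case]).pvalue
    fdr_screen = bh_adjust(p_screen)
    screened = fdr_screen < alpha
    n_screened = int(screened.sum())

    sigs = d.signal.loc[:, crd_ids].to_numpy(float)
    mean_case = sigs[is_case].mean(axis=0)
    mean_ctrl = sigs[~is_case].mean(axis=0)
    log2fc = mean_case - mean_ctrl
    p_confirm = np.full(len(crd_ids), np.nan)
    p_confirm_adj = np.full(len(crd_ids), np.nan)
    significant = np.zeros(len(crd_ids), dtype=bool)
    for i in np.flatnonzero(screened):
        t_res = stats.ttest_ind(sigs[is_case, i], sigs[~is_case, i])
        p_confirm[i] = t_res.pvalue
        p_confirm_adj[i] = min(1.0, t_res.pvalue * n_screened)
        significant[i] = p_confirm_adj[i] < alpha
    direction = np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "none"))
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p_screen": p_screen,
            "fdr_screen": fdr_screen,
            "p_confirm": p_confirm,
            "p_confirm_adj": p_confirm_adj,
            "significant": significant,
            "direction": direction,
        },
        index=pd.Index(crd_ids, name="crd_id"),
    )
    return CrdDifferential(table=table, alpha=alpha)


# ---------------------------------------------------------------------------
# Goodman-Kruskal / Baker-Hubert Gamma
# ---------------------------------------------------------------------------

def gamma_statistic(dist: np.ndarray, labels: Sequence) -> float:
    """Concordance between pairwise distances and cluster co-membership.

    ``dist`` is a condensed distance vector (as from ``pdist``/``squareform``);
    ``labels`` assigns each point to a cluster.  Gamma = (s+ - s-)/(s+ + s-),
    where s+ counts (within-pair, between-pair) comparisons with the
    between-cluster distance strictly larger, s- strictly smaller; exact ties
    count toward neither (Baker-Hubert convention).
    """
    labels = np.asarray(labels)
    n = len(labels)
    dist = np.asarray(dist, dtype=float)
    if dist.shape[0] != n * (n - 1) // 2:
        raise ValueError("condensed distance length does not match labels")
    if len(np.unique(labels)) < 2:
        raise ValueError("gamma undefined for a single cluster")
    iu, ju = np.triu_indices(n, k=1)
    within_mask = labels[iu] == labels[ju]
    w = dist[within_mask]
    b = dist[~within_mask]
    if w.size < 2 or b.size < 2:
        raise ValueError("need >= 2 within-cluster and >= 2 between-cluster pairs")
    b_sorted = np.sort(b)
    gt = b_sorted.size - np.searchsorted(b_sorted, w, side="right")
    lt = np.searchsorted(b_sorted, w, side="left")
    s_plus = int(gt.sum())
    s_minus = int(lt.sum())
    if s_plus + s_minus == 0:
        return 0.0
    return (s_plus - s_minus) / (s_plus + s_minus)


# ---------------------------------------------------------------------------
# TRD discovery
# ---------------------------------------------------------------------------

def build_trds(
    d: DomainSet,
    k_range: Iterable[int] = range(2, 16),
    crd_diff: CrdDifferential | None = None,
    method: str = "average",
) -> TrdPartition:
    """Cluster CRDs into TRDs on 1 - r of their per-sample signals.

    When ``crd_diff`` is given, only its significant (disease) CRDs are
    clustered — the published workflow; with ``None`` all CRDs are used.
    The tree is cut at every k in ``k_range`` and the partition maximizing
    the Gamma statistic is returned (smallest k on ties) with the full trace.
    """
    ids = list(d.crd_ids)
    if crd_diff is not None:
        keep = set(crd_diff.significant_ids())
        ids = [c for c in ids if c in keep]
    sig = d.signal.loc[:, ids]
    const = sig.std(axis=0) == 0
    if const.any():
        logger.warning("dropping %d constant-signal CRDs", int(const.sum()))
        ids = [c for c in ids if not const[c]]
        sig = sig.loc[:, ids]
    if len(ids) < 2:
        raise ValueError("need >= 2 (significant) CRDs to build TRDs")
    corr = np.corrcoef(sig.to_numpy(float), rowvar=False)
    dist_sq = 1.0 - corr
    np.fill_diagonal(dist_sq, 0.0)
    dist_sq = np.clip((dist_sq + dist_sq.T) / 2.0, 0.0, None)
    condensed = squareform(dist_sq, checks=False)
    Z = linkage(condensed, method=method)
    trace: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in sorted(set(int(k) for k in k_range)):
        if not (2 <= k <= len(ids) - 1):
            continue
        lab = fcluster(Z, t=k, criterion="maxclust")
        try:
            trace[k] = gamma_statistic(condensed, lab)
        except ValueError:
            continue
        labels_by_k[k] = lab
    if not trace:
        raise ValueError("no k in k_range yielded a valid partition")
    best_k = min(
        (k for k in trace), key=lambda k: (-trace[k], k)
    )
    lab = labels_by_k[best_k]
    # relabel 1..k by first appearance for determinism
    remap, nxt = {}, 1
    out = np.empty_like(lab)
    for i, l in enumerate(lab):
        if l not in remap:
            remap[l] = nxt
            nxt += 1
        out[i] = remap[l]
    assignment = pd.Series(out, index=pd.Index(ids, name="crd_id"), name="trd")
    return TrdPartition(
        assignment=assignment, k=int(len(np.unique(out))),
        gamma_trace=trace, linkage_matrix=Z,
    )


def trd_direction_profile(
    p: TrdPartition,
    crd_diff: CrdDifferential,
    up_threshold: float = 0.75,
) -> pd.DataFrame:
    """Per-TRD counts of up/down CRDs; flag predominantly upregulated TRDs."""
    rows = []
    for trd, crds in sorted(p.members().items()):
        dirs = crd_diff.table.loc[
            [c for c in crds if c in crd_diff.table.index], "direction"
        ]
        n_up = int((dirs == "up").sum())
        n_down = int((dirs == "down").sum())
        frac = n_up / (n_up + n_down) if (n_up + n_down) else float("nan")
        rows.append(
            {
                "trd": trd,
                "n_crds": len(crds),
                "n_up": n_up,
                "n_down": n_down,
                "up_fraction": frac,
                "predominantly_up": bool(frac > up_threshold)
                if not np.isnan(frac) else False,
            }
        )
    return pd.DataFrame(rows).set_index("trd")


def fold_change_correlation(
    set_a_log2fc: pd.Series, set_b_log2fc: pd.Series
) -> tuple[float, float, int]:
    """Spearman correlation of two fold-change vectors over shared peaks."""
    shared = set_a_log2fc.index.intersection(set_b_log2fc.index)
    n = len(shared)
    if n < 10:
        raise ValueError(f"need >= 10 shared peaks, got {n}")
    rho, p = stats.spearmanr(
        set_a_log2fc.loc[shared], set_b_log2fc.loc[shared]
    )
    return float(rho), float(p), n
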