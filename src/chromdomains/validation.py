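"""Validation studies: planted-truth recovery, null calibration, oracles.

Every function here re-runs a piece of the pipeline on freshly simulated
data with known ground truth and measures how well the planted structure is
recovered (or how clean the null is).  The reference oracles are deliberate
naive re-derivations — explicit double loops, per-pair ``pearsonr``, dense
``numpy.linalg.eig`` — sharing no code with the optimized implementations
they check.

Used by the test suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from . import (
    SimConfig,
    build_crds,
    build_trds,
    cell_set_zscores,
    diffusion_pseudotime,
    differential_peaks,
    domains_from_truth,
    embed_samples,
    enrichment_scan,
    fold_change_correlation,
    gamma_statistic,
    partitioned_prs,
    residualize,
    simulate_bulk,
    simulate_fold_changes,
    simulate_genotypes,
    simulate_single_cell,
    stage_pipeline,
    trd_direction_profile,
    two_stage_crd_test,
)
from .matrix import AccessibilityMatrix

_COVARS = ["age", "sex", "batch"]


def _seed(base: int, i: int) -> int:
    return int((int(base) + i) % (2**31 - 1))


# ---------------------------------------------------------------------------
# Reference oracles (naive, independent code paths)
# ---------------------------------------------------------------------------

def naive_crd_intervals(X: np.ndarray, r_threshold: float,
                        min_peaks: int) -> list[tuple[int, ...]]:
    """Brute-force CRD calls for one chromosome: per-pair pearsonr, merges
    recomputed by double loops over members, every acceptance condition
    checked from scratch.  Leftmost tie rule, as in the optimized caller."""
    k = X.shape[1]
    corr = np.ones((k, k))
    for i in range(k):
        for j in range(k):
            if i != j:
                corr[i, j] = stats.pearsonr(X[:, i], X[:, j])[0]

    def cross_mean(a, b):
        return float(np.mean([corr[i, j] for i in a for j in b]))

    nodes = [{"members": [i], "sim": float("inf"), "children": None}
             for i in range(k)]
    while len(nodes) > 1:
        best, best_val = 0, -np.inf
        for i in range(len(nodes) - 1):
            s = cross_mean(nodes[i]["members"], nodes[i + 1]["members"])
            if s > best_val:
                best, best_val = i, s
        a, b = nodes[best], nodes[best + 1]
        nodes[best: best + 2] = [
            {"members": a["members"] + b["members"], "sim": best_val,
             "children": (a, b)}
        ]

    def coherent(node):
        if node["children"] is None:
            return True
        return (node["sim"] >= r_threshold
                and all(coherent(c) for c in node["children"]))

    def internal_mean(members):
        return float(
            np.mean([corr[i, j] for i in members for j in members if i < j])
        )

    accepted: list[tuple[int, ...]] = []

    def collect(node):
        mem = node["members"]
        if (len(mem) >= min_peaks and coherent(node)
                and internal_mean(mem) >= r_threshold):
            accepted.append(tuple(sorted(mem)))
            return
        if node["children"] is not None:
            for c in node["children"]:
                collect(c)

    collect(nodes[0])
    return sorted(accepted)


def gamma_brute(dist_condensed: np.ndarray, labels) -> float:
    """Gamma by explicit enumeration of every (within, between) pair."""
    D = squareform(dist_condensed)
    n = len(labels)
    within, between = [], []
    for i in range(n):
        for j in range(i + 1, n):
            (within if labels[i] == labels[j] else between).append(D[i, j])
    s_plus = sum(1 for w in within for b in between if b > w)
    s_minus = sum(1 for w in within for b in between if b < w)
    if s_plus + s_minus == 0:
        return 0.0
    return (s_plus - s_minus) / (s_plus + s_minus)


def dense_dpt_oracle(X: np.ndarray, n_neighbors: int, d: int,
                     root_idx: int) -> np.ndarray:
    """Dense recomputation of diffusion pseudotime with numpy.linalg.eig."""
    n = X.shape[0]
    Xz = (X - X.mean(axis=0)) / np.where(X.std(axis=0) == 0, 1, X.std(axis=0))
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            D[i, j] = np.sqrt(((Xz[i] - Xz[j]) ** 2).sum())
    W = np.zeros((n, n))
    sigma = np.empty(n)
    for i in range(n):
        others = np.argsort(np.where(np.arange(n) == i, -1.0, D[i]),
                            kind="stable")
        sigma[i] = max(D[i, others[n_neighbors]], 1e-12)
    for i in range(n):
        others = np.argsort(np.where(np.arange(n) == i, -1.0, D[i]),
                            kind="stable")
        for j in others[1: n_neighbors + 1]:
            w = np.exp(-D[i, j] ** 2 / (sigma[i] * sigma[j]))
            W[i, j] = max(W[i, j], w)
            W[j, i] = max(W[j, i], w)
    P = W / W.sum(axis=1, keepdims=True)
    evals, evecs = np.linalg.eig(P)
    evals, evecs = np.real(evals), np.real(evecs)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    d_eff = min(d, n - 1)
    lam = np.clip(evals[1: d_eff + 1], None, 1 - 1e-9)
    psi = evecs[:, 1: d_eff + 1]
    psi = psi / np.linalg.norm(psi, axis=0, keepdims=True)
    w = lam / (1 - lam)
    diff = (psi - psi[root_idx]) * w[None, :]
    dpt = np.sqrt((diff ** 2).sum(axis=1))
    return dpt / dpt.max() if dpt.max() > 0 else dpt


# ---------------------------------------------------------------------------
# Study helpers
# ---------------------------------------------------------------------------

def peak_level_ari(truth, dom, peaks) -> float:
    """ARI over all peaks; unassigned peaks count as singleton clusters."""
    t_lab, c_lab = [], []
    tn = cn = 0
    for p in peaks.ids:
        t = truth.peak_to_crd[p]
        if t is None:
            t_lab.append(f"tn{tn}")
            tn += 1
        else:
            t_lab.append(f"t{t}")
        c = dom.peak_assignment[p]
        if c is None:
            c_lab.append(f"cn{cn}")
            cn += 1
        else:
            c_lab.append(c)
    return float(adjusted_rand_score(t_lab, c_lab))


# ---------------------------------------------------------------------------
# Studies
# ---------------------------------------------------------------------------

def crd_recovery_study(n_seeds: int = 10, base_seed: int = 0) -> dict:
    """Peak-level recovery of 20 planted CRDs (8-25 peaks, r=0.7) by
    build_crds at r_threshold 0.3 / min_peaks 3; 300 samples, 2 x 400 peaks."""
    aris = []
    for i in range(n_seeds):
        cfg = SimConfig(n_samples=300, n_cases=150, seed=_seed(base_seed, i))
        peaks, m, truth = simulate_bulk(cfg)
        mr = residualize(m, _COVARS)
        dom = build_crds(mr, peaks, r_threshold=0.3, min_peaks=3)
        aris.append(peak_level_ari(truth, dom, peaks))
    return {"mean_ari": float(np.mean(aris)), "min_ari": float(min(aris)),
            "n": n_seeds}


def crd_oracle_study(n_instances: int = 200, base_seed: int = 0) -> dict:
    """Exact agreement of build_crds with the naive re-derivation on random
    small instances (3-8 peaks, occasional planted block)."""
    from .peaks import PeakSet

    agree = 0
    for i in range(n_instances):
        r = np.random.default_rng(_seed(base_seed, i))
        k = int(r.integers(3, 9))
        X = r.normal(size=(60, k))
        if i % 2 == 0 and k >= 4:
            size = int(r.integers(3, min(k, 5) + 1))
            lo = int(r.integers(0, k - size + 1))
            f = r.normal(size=60)
            X[:, lo: lo + size] = (np.sqrt(0.6) * f[:, None]
                                   + np.sqrt(0.4) * r.normal(size=(60, size)))
        cols = [f"p{j:03d}" for j in range(k)]
        samples = [f"s{i}" for i in range(60)]
        meta = pd.DataFrame({"diagnosis": "control"},
                            index=pd.Index(samples, name="sample_id"))
        m = AccessibilityMatrix(
            pd.DataFrame(X, index=meta.index, columns=cols), meta
        )
        starts = np.arange(k) * 1000
        ps = PeakSet.from_arrays(["chr1"] * k, starts, starts + 500, cols)
        dom = build_crds(m, ps, r_threshold=0.3, min_peaks=3)
        got = sorted(
            tuple(sorted(int(p[1:]) for p in mem))
            for mem in dom.members.values()
        )
        agree += got == naive_crd_intervals(X, 0.3, 3)
    return {"agreement": agree / n_instances, "n": n_instances}


def two_stage_null_study(n_seeds: int = 100, base_seed: int = 0) -> dict:
    """Mean false-discovery proportion of the two-stage test over seeds with
    1,000 null CRDs each (global null: zero disease and genetic effects)."""
    fdps = []
    for i in range(n_seeds):
        cfg = SimConfig(
            n_samples=300, n_cases=150, n_chromosomes=5,
            peaks_per_chromosome=1100, crd_sizes=tuple([5] * 1000),
            n_trds=3, disease_effect_size=0.0, severity_prs_correlation=0.0,
            seed=_seed(base_seed, i),
        )
        peaks, m, truth = simulate_bulk(cfg)
        mr = residualize(m, _COVARS)
        dom = domains_from_truth(truth, peaks, mr)
        res = two_stage_crd_test(dom, mr)
        n_disc = int(res.table["significant"].sum())
        fdps.append(1.0 if n_disc else 0.0)  # all discoveries are false
    return {"mean_fdp": float(np.mean(fdps)), "n": n_seeds}


def two_stage_sensitivity_study(n_seeds: int = 10, base_seed: int = 0) -> dict:
    """Sensitivity for CRDs carrying a planted delta=0.8 shift at n=300."""
    hits = total = 0
    for i in range(n_seeds):
        cfg = SimConfig(
            n_samples=300, n_cases=150, n_chromosomes=2,
            peaks_per_chromosome=200, crd_sizes=tuple([8] * 15), n_trds=3,
            disease_effect_size=0.8, fraction_affected_peaks=0.1,
            seed=_seed(base_seed, i),
        )
        peaks, m, truth = simulate_bulk(cfg)
        mr = residualize(m, _COVARS)
        dom = domains_from_truth(truth, peaks, mr)
        res = two_stage_crd_test(dom, mr)
        shifted = {
            f"crd_{truth.peak_to_crd[p] + 1:05d}"
            for p in truth.affected_peaks
            if truth.peak_to_crd[p] is not None
        }
        called = set(res.significant_ids())
        hits += len(called & shifted)
        total += len(shifted)
    return {"sensitivity": hits / total, "n": total}


def gamma_oracle_study(n_instances: int = 200, base_seed: int = 0) -> dict:
    """Exact agreement of gamma_statistic with brute-force enumeration."""
    agree = tried = 0
    for i in range(n_instances):
        r = np.random.default_rng(_seed(base_seed, i))
        n = int(r.integers(5, 16))
        X = r.normal(size=(n, 2))
        k = int(r.integers(2, max(3, n // 2)))
        labels = np.concatenate([np.arange(k), r.integers(0, k, size=n - k)])
        d = pdist(X)
        try:
            got = gamma_statistic(d, labels)
        except ValueError:
            continue
        tried += 1
        agree += got == gamma_brute(d, labels)
    # perfect partition of separated blobs: Gamma must be exactly 1
    r = np.random.default_rng(_seed(base_seed, 999))
    X = np.vstack([r.normal(0, 0.1, size=(10, 2)),
                   r.normal(10, 0.1, size=(10, 2))])
    blob_gamma = gamma_statistic(pdist(X), [0] * 10 + [1] * 10)
    return {"agreement": agree / tried if tried else float("nan"),
            "n": tried, "separated_blob_gamma": float(blob_gamma)}


def trd_recovery_study(n_seeds: int = 25, base_seed: int = 0) -> dict:
    """Recovery of 3 planted TRDs x 15 CRDs at cross-correlation 0.6:
    fraction of seeds where Gamma selects k=3 and CRD-level ARI >= 0.9."""
    ok = 0
    aris, ks = [], []
    for i in range(n_seeds):
        cfg = SimConfig(
            n_samples=300, n_cases=150, n_chromosomes=3,
            peaks_per_chromosome=200, crd_sizes=tuple([10] * 45), n_trds=3,
            trd_cross_correlation=0.6, disease_effect_size=0.0,
            severity_prs_correlation=0.0, seed=_seed(base_seed, i),
        )
        peaks, m, truth = simulate_bulk(cfg)
        dom = domains_from_truth(truth, peaks, m)
        part = build_trds(dom, k_range=range(2, 9))
        truth_lab = [truth.crd_to_trd[int(c.split("_")[1]) - 1]
                     for c in part.assignment.index]
        ari = adjusted_rand_score(truth_lab, part.assignment)
        aris.append(ari)
        ks.append(part.k)
        ok += (part.k == 3) and (ari >= 0.9)
    return {"success_rate": ok / n_seeds, "mean_ari": float(np.mean(aris)),
            "mode_k": int(stats.mode(ks, keepdims=False).mode), "n": n_seeds}


def pseudotime_recovery_study(n_seeds: int = 25, base_seed: int = 0) -> dict:
    """Severity-gradient recovery: |Spearman(pseudotime, severity)| and the
    stage ~ PRS + Age + Age^2 + Sex association (n=300, 500 signature peaks,
    1 SD effect, severity-PRS correlation 0.5)."""
    rhos, beta_ok = [], 0
    for i in range(n_seeds):
        cfg = SimConfig(
            n_samples=300, n_cases=150, disease_effect_size=1.0,
            fraction_affected_peaks=500 / 800, severity_prs_correlation=0.5,
            seed=_seed(base_seed, i),
        )
        peaks, m, truth = simulate_bulk(cfg)
        mr = residualize(m, _COVARS)
        res = stage_pipeline(mr, list(truth.affected_peaks),
                             seed=_seed(base_seed, i))
        rho = stats.spearmanr(
            res.table["pseudotime"],
            truth.sample_severity.loc[res.table.index],
        )[0]
        rhos.append(abs(rho))
        a = res.associations
        beta_ok += (a.get("stage_prs_beta") or 0) > 0 and (
            a.get("stage_prs_p", 1.0) < 0.05
        )
    return {"mean_abs_spearman": float(np.mean(rhos)),
            "min_abs_spearman": float(min(rhos)),
            "beta_recovery_rate": beta_ok / n_seeds, "n": n_seeds}


def dpt_oracle_study(n_instances: int = 20, base_seed: int = 0) -> dict:
    """Max |DPT - dense oracle| on tiny graphs, plus chain monotonicity."""
    max_err = 0.0
    for i in range(n_instances):
        r = np.random.default_rng(_seed(base_seed, i))
        n = int(r.integers(7, 11))
        X = r.normal(size=(n, 6))
        samples = [f"s{j:03d}" for j in range(n)]
        meta = pd.DataFrame({"diagnosis": "control"},
                            index=pd.Index(samples, name="sample_id"))
        m = AccessibilityMatrix(
            pd.DataFrame(X, index=meta.index,
                         columns=[f"p{j}" for j in range(6)]), meta
        )
        emb = embed_samples(m, list(m.peak_ids), n_neighbors=3, d=4)
        pt = diffusion_pseudotime(emb, samples[0]).to_numpy()
        oracle = dense_dpt_oracle(X, n_neighbors=3, d=4, root_idx=0)
        max_err = max(max_err, float(np.abs(pt - oracle).max()))
    # chain graph: equally spaced samples on a line
    n = 30
    pos = np.arange(n, dtype=float)
    X = np.column_stack([pos, pos, pos])
    samples = [f"s{j:03d}" for j in range(n)]
    meta = pd.DataFrame({"diagnosis": "control"},
                        index=pd.Index(samples, name="sample_id"))
    m = AccessibilityMatrix(
        pd.DataFrame(X, index=meta.index, columns=["a", "b", "c"]), meta
    )
    emb = embed_samples(m, ["a", "b", "c"], n_neighbors=4, d=8)
    pt = diffusion_pseudotime(emb, samples[0]).to_numpy()
    return {"max_abs_error": max_err,
            "chain_monotone": bool((np.diff(pt) > 0).all()),
            "n": n_instances}


def null_pipeline_study(n_seeds: int = 10, base_seed: int = 0) -> dict:
    """End-to-end null: zero disease effect and zero severity-PRS
    correlation.  Measures differential false-positive fraction, TRD
    upregulation flags, single-cell mixed-model significance rate, and PRS
    confidence-interval coverage of OR=1."""
    diff_fracs, flags, prs_cover = [], 0, 0
    sc_sig = sc_tot = 0
    for i in range(n_seeds):
        cfg = SimConfig(
            n_samples=200, n_cases=100, n_chromosomes=2,
            peaks_per_chromosome=200, crd_sizes=tuple([5] * 20), n_trds=2,
            disease_effect_size=0.0, severity_prs_correlation=0.0,
            celltype_signal_fraction=0.0, n_cells=500, n_cell_types=5,
            n_variants=500, seed=_seed(base_seed, i),
        )
        peaks, m, truth = simulate_bulk(cfg)
        mr = residualize(m, _COVARS)
        diff = differential_peaks(mr)
        diff_fracs.append(float((diff.table["fdr"] < 0.05).mean()))
        dom = build_crds(mr, peaks)
        flagged = False
        if len(dom) >= 2:
            crd_diff = two_stage_crd_test(dom, mr)
            if int(crd_diff.table["significant"].sum()) >= 2:
                try:
                    part = build_trds(dom, range(2, 8), crd_diff=crd_diff)
                    prof = trd_direction_profile(part, crd_diff)
                    flagged = bool(prof["predominantly_up"].any())
                except ValueError:
                    flagged = False
        flags += flagged
        cells = simulate_single_cell(cfg, truth, peaks)
        r = np.random.default_rng(_seed(base_seed, 10_000 + i))
        target = list(r.choice(peaks.ids, size=40, replace=False))
        z = cell_set_zscores(cells, target, B=20, seed=_seed(base_seed, i))
        scan = enrichment_scan(z, cells)
        sc_sig += int((scan["fdr"] < 0.05).sum())
        sc_tot += len(scan)
        dosages, weights = simulate_genotypes(cfg, peaks, truth)
        from .prs import prs_association, score_samples

        scores = score_samples(weights, dosages)
        res = prs_association(scores, m.metadata, n_variants=len(weights))
        lo, hi = res.or_ci
        prs_cover += lo <= 1.0 <= hi
    return {
        "differential_sig_fraction": float(np.mean(diff_fracs)),
        "trd_up_flag_rate": flags / n_seeds,
        "scenrich_sig_rate": sc_sig / sc_tot,
        "prs_ci_coverage": prs_cover / n_seeds,
        "n": n_seeds,
    }


def prs_ranking_study(n_seeds: int = 25, base_seed: int = 0) -> dict:
    """How often the disease TRD's interval-restricted PRS has the highest
    variance explained per variant (vs other TRDs and genome-wide)."""
    wins = 0
    for i in range(n_seeds):
        cfg = SimConfig(
            n_samples=300, n_cases=150, n_chromosomes=2,
            peaks_per_chromosome=200, crd_sizes=tuple([10] * 12), n_trds=3,
            disease_effect_size=0.8, fraction_affected_peaks=0.1,
            severity_prs_correlation=0.5, n_variants=1000,
            seed=_seed(base_seed, i),
        )
        peaks, m, truth = simulate_bulk(cfg)
        dosages, weights = simulate_genotypes(cfg, peaks, truth)
        partitions = {
            f"TRD{t + 1}": [p for c in crds for p in truth.crd_members[c]]
            for t, crds in sorted(truth.trd_members.items())
        }
        table = partitioned_prs(weights, dosages, peaks, partitions,
                                m.metadata)
        vpv = table["variance_per_variant"].dropna()
        wins += vpv.idxmax() == f"TRD{truth.disease_trd + 1}"
    return {"first_rank_rate": wins / n_seeds, "n": n_seeds}


def fold_change_study(n: int = 3000, target: float = 0.4,
                      base_seed: int = 0) -> dict:
    """Spearman recovery of a shared-latent fold-change correlation."""
    a, b = simulate_fold_changes(n, target, seed=_seed(base_seed, 0))
    rho, p, n_used = fold_change_correlation(a, b)
    return {"rho": rho, "p": p, "n": n_used}
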