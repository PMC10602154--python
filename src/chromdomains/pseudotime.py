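"""Per-sample disease staging on a diffusion-map embedding.

Samples are embedded on the upregulated disease peak signature (z-scored,
kNN graph, adaptive Gaussian kernel, row-normalized transition operator),
staged by Leiden community detection on the same graph, and ordered by
diffusion pseudotime (DPT) from a least-perturbed root.  Pseudotime and
stage are then associated with diagnosis and polygenic risk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import igraph
import leidenalg
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .matrix import AccessibilityMatrix

logger = logging.getLogger(__name__)


@dataclass
class DiffusionEmbedding:
    """Diffusion components of the sample graph.

    ``psi`` holds unit-norm nontrivial right eigenvectors of the transition
    operator; ``components`` are the same vectors scaled by their
    eigenvalues (the diffusion map).
    """

    components: np.ndarray = field(repr=False)  # n x d, psi * lambda
    psi: np.ndarray = field(repr=False)         # n x d, unit-norm
    eigenvalues: np.ndarray = field(repr=False)
    sample_ids: pd.Index = field(repr=False)
    adjacency: sparse.csr_matrix = field(repr=False)


@dataclass
class StageResult:
    """Per-sample staging output plus association statistics."""

    table: pd.DataFrame = field(repr=False)  # dc1..dcd, stage, pseudotime
    root_sample_id: str = ""
    associations: dict = field(default_factory=dict)


def embed_samples(
    m: AccessibilityMatrix,
    signature: Sequence[str],
    n_neighbors: int = 15,
    d: int = 10,
) -> DiffusionEmbedding:
    """Diffusion-map embedding of samples on a peak signature.

    The signature submatrix is z-scored per peak; a symmetric kNN graph with
    an adaptive Gaussian kernel (per-sample bandwidth = distance to the
    n_neighbors-th neighbor) is row-normalized into a transition operator
    whose top nontrivial right eigenvectors form the embedding.
    """
    signature = list(signature)
    if not signature:
        raise ValueError("signature peak set is empty")
    n = m.n_samples
    if not (2 <= n_neighbors < n):
        raise ValueError("need n_samples > n_neighbors >= 2")
    X = m.values.loc[:, signature].to_numpy(float)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = (X - X.mean(axis=0)) / sd

    D = squareform(pdist(X))
    np.fill_diagonal(D, -1.0)  # self always sorts first (duplicates exist)
    order = np.argsort(D, axis=1, kind="stable")
    np.fill_diagonal(D, 0.0)
    sigma = np.maximum(D[np.arange(n), order[:, n_neighbors]], 1e-12)
    mask = np.zeros((n, n), dtype=bool)
    mask[np.arange(n)[:, None], order[:, 1: n_neighbors + 1]] = True
    mask |= mask.T  # union kNN
    W = np.zeros((n, n))
    W[mask] = np.exp(-(D[mask] ** 2) / (sigma[:, None] * sigma[None, :])[mask])
    W = (W + W.T) / 2.0

    n_comp, _ = connected_components(sparse.csr_matrix(W), directed=False)
    if n_comp > 1:
        raise ValueError(
            f"sample graph has {n_comp} components; increase n_neighbors"
        )
    deg = W.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(deg)
    S = W * inv_sqrt[:, None] * inv_sqrt[None, :]
    evals, evecs = np.linalg.eigh((S + S.T) / 2.0)
    idx = np.argsort(evals)[::-1]
    evals, evecs = evals[idx], evecs[:, idx]
    d_eff = min(d, n - 1)
    lam = evals[1: d_eff + 1]
    psi = evecs[:, 1: d_eff + 1] * inv_sqrt[:, None]
    psi /= np.linalg.norm(psi, axis=0, keepdims=True)
    # deterministic sign: largest-magnitude entry positive
    flip = psi[np.abs(psi).argmax(axis=0), np.arange(d_eff)] < 0
    psi[:, flip] *= -1.0
    return DiffusionEmbedding(
        components=psi * lam[None, :],
        psi=psi,
        eigenvalues=lam,
        sample_ids=m.sample_ids,
        adjacency=sparse.csr_matrix(W),
    )


def select_root(
    m: AccessibilityMatrix,
    signature: Sequence[str],
    group: str = "diagnosis",
    control_level: str = "control",
) -> str:
    """Default DPT root: the control sample with minimal mean signature
    accessibility (the least-perturbed pole of the trajectory)."""
    sig_mean = m.values.loc[:, list(signature)].mean(axis=1)
    controls = m.metadata[group].astype(str) == control_level
    pool = sig_mean[controls] if controls.any() else sig_mean
    return str(pool.idxmin())


def diffusion_pseudotime(
    emb: DiffusionEmbedding, root: str, rescale: bool = True
) -> pd.Series:
    """DPT distance from the root in eigenvalue-rescaled diffusion space.

    Components are weighted lambda/(1-lambda); the result is min-max scaled
    to [0, 1] (root at 0) unless ``rescale=False``.
    """
    ids = emb.sample_ids
    if root not in ids:
        raise KeyError(f"root sample not in graph: {root}")
    r = ids.get_loc(root)
    lam = np.clip(emb.eigenvalues, None, 1.0 - 1e-9)
    w = lam / (1.0 - lam)
    diff = (emb.psi - emb.psi[r]) * w[None, :]
    dpt = np.sqrt((diff ** 2).sum(axis=1))
    if rescale and dpt.max() > 0:
        dpt = dpt / dpt.max()
    return pd.Series(dpt, index=ids, name="pseudotime")


def stage_samples(
    emb: DiffusionEmbedding,
    pseudotime: pd.Series,
    resolution: float = 1.0,
    seed: int = 0,
) -> pd.Series:
    """Leiden communities on the sample kNN graph, relabeled 1..K by
    ascending mean pseudotime (stage 1 = least perturbed)."""
    W = emb.adjacency.tocoo()
    upper = W.row < W.col
    g = igraph.Graph(
        n=W.shape[0],
        edges=list(zip(W.row[upper], W.col[upper])),
        edge_attrs={"weight": W.data[upper].tolist()},
    )
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
    )
    labels = np.array(part.membership)
    k = len(np.unique(labels))
    if k == 1:
        logger.warning("single community found; staging is uninformative")
        return pd.Series(1, index=emb.sample_ids, name="stage")
    pt = pseudotime.loc[emb.sample_ids].to_numpy()
    means = [pt[labels == c].mean() for c in range(k)]
    order = np.argsort(means, kind="stable")
    remap = {int(c): i + 1 for i, c in enumerate(order)}
    stages = pd.Series(
        [remap[int(l)] for l in labels], index=emb.sample_ids, name="stage"
    )
    return stages


def stage_associations(
    stages: pd.Series,
    pseudotime: pd.Series,
    metadata: pd.DataFrame,
    group: str = "diagnosis",
    case_level: str = "case",
    prs_col: str = "prs",
) -> dict:
    """Associations of staging with diagnosis and polygenic risk.

    (i) logistic regression of case status on standardized pseudotime (OR
    per SD with 95% CI); (ii) linear model stage ~ PRS + Age + Age^2 + Sex
    (beta and p for PRS); (iii) Spearman correlation of pseudotime with PRS.
    PRS analyses are skipped with a notice when the column is absent.
    """
    out: dict = {}
    if stages.nunique() == 1:
        raise ValueError("no stage variance: all samples share one stage")
    y = (metadata[group].astype(str) == case_level).to_numpy(float)
    pt = pseudotime.loc[metadata.index].to_numpy()
    pt_std = (pt - pt.mean()) / pt.std(ddof=0)
    logit = sm.Logit(y, sm.add_constant(pt_std)).fit(disp=0)
    ci = logit.conf_int()[1]
    out["pseudotime_or"] = float(np.exp(logit.params[1]))
    out["pseudotime_or_ci"] = (float(np.exp(ci[0])), float(np.exp(ci[1])))
    out["pseudotime_or_p"] = float(logit.pvalues[1])

    if prs_col not in metadata.columns or metadata[prs_col].isna().all():
        logger.info("PRS column missing; skipping PRS associations")
        out["stage_prs_beta"] = None
        return out
    prs = metadata[prs_col].to_numpy(float)
    age = metadata["age"].to_numpy(float)
    sex = (metadata["sex"].astype(str) == "F").to_numpy(float)
    X = sm.add_constant(
        np.column_stack([prs, age, age ** 2, sex])
    )
    ols = sm.OLS(stages.loc[metadata.index].to_numpy(float), X).fit()
    out["stage_prs_beta"] = float(ols.params[1])
    out["stage_prs_p"] = float(ols.pvalues[1])
    rho, p = stats.spearmanr(pt, prs)
    out["pseudotime_prs_spearman"] = float(rho)
    out["pseudotime_prs_spearman_p"] = float(p)
    return out


def stage_pipeline(
    m: AccessibilityMatrix,
    signature: Sequence[str],
    n_neighbors: int = 15,
    d: int = 10,
    resolution: float = 1.0,
    seed: int = 0,
    root: str | None = None,
) -> StageResult:
    """Embed, root, order and stage samples; attach association statistics."""
    emb = embed_samples(m, signature, n_neighbors=n_neighbors, d=d)
    if root is None:
        root = select_root(m, signature)
    pt = diffusion_pseudotime(emb, root)
    stages = stage_samples(emb, pt, resolution=resolution, seed=seed)
    try:
        assoc = stage_associations(stages, pt, m.metadata)
    except ValueError as exc:
        logger.warning("stage associations skipped: %s", exc)
        assoc = {"error": str(exc)}
    tab = pd.DataFrame(
        emb.components,
        index=emb.sample_ids,
        columns=[f"dc{i + 1}" for i in range(emb.components.shape[1])],
    )
    tab["stage"] = stages
    tab["pseudotime"] = pt
    return StageResult(table=tab, root_sample_id=root, associations=assoc)
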