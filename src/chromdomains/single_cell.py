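"""Single-cell enrichment of bulk-derived peak sets.

Scores every cell for a target OCR set against accessibility-matched
background sets (a chromVAR-style deviation z-score without sequence
covariates), then tests cell-type specificity with a one-vs-rest linear
mixed model with a per-donor random intercept.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import sparse, stats

from ._utils import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentScores:
    """Per-cell deviation z-scores for one target peak set."""

    z: pd.Series = field(repr=False)
    target_id: str = "target"
    n_background: int = 0
    degenerate: bool = False  # sd of background was zero somewhere


def _cell_fractions(X: sparse.spmatrix, cols: np.ndarray,
                    depth: np.ndarray) -> np.ndarray:
    sub = X[:, cols]
    return np.asarray(sub.sum(axis=1)).ravel() / depth


def cell_set_zscores(
    cells: ad.AnnData,
    target: Sequence[str],
    B: int = 50,
    seed: int = 0,
    n_bins: int = 10,
    target_id: str = "target",
) -> EnrichmentScores:
    """Deviation z-score of a target peak set per cell.

    Observed statistic: fraction of a cell's depth falling in target peaks.
    Background: ``B`` peak sets sampled to match the target's per-peak mean
    accessibility deciles.  z = (obs - mean_bg) / sd_bg.  Depth-invariant by
    construction.
    """
    if B < 20:
        raise ValueError("need B >= 20 background sets")
    var_index = cells.var_names
    target = list(target)
    unknown = set(target) - set(var_index)
    if unknown:
        raise KeyError(f"target peaks outside universe: {sorted(unknown)[:5]}")
    if len(target) < 10:
        warnings.warn("target set smaller than 10 peaks; z-scores unstable",
                      stacklevel=2)
    X = cells.X.tocsr() if sparse.issparse(cells.X) else sparse.csr_matrix(cells.X)
    depth = np.asarray(X.sum(axis=1)).ravel()
    if (depth == 0).any():
        raise ValueError("zero-depth cell encountered")

    # accessibility bins from depth-normalized per-peak means
    norm_mean = np.asarray(
        X.multiply(1.0 / depth[:, None]).mean(axis=0)
    ).ravel()
    ranks = stats.rankdata(norm_mean, method="average")
    bins = np.minimum(
        (ranks - 1) / len(ranks) * n_bins, n_bins - 1
    ).astype(int)
    bin_pool = {b: np.flatnonzero(bins == b) for b in range(n_bins)}
    t_cols = np.array([var_index.get_loc(p) for p in target])
    t_bins = bins[t_cols]

    rng = np.random.default_rng(seed)
    obs = _cell_fractions(X, t_cols, depth)
    bg = np.empty((X.shape[0], B))
    for b in range(B):
        cols = np.array(
            [rng.choice(bin_pool[tb]) for tb in t_bins]
        )
        bg[:, b] = _cell_fractions(X, cols, depth)
    mu = bg.mean(axis=1)
    sd = bg.std(axis=1, ddof=1)
    degenerate = bool((sd == 0).any())
    z = np.where(sd > 0, (obs - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return EnrichmentScores(
        z=pd.Series(z, index=cells.obs_names, name="z"),
        target_id=target_id,
        n_background=B,
        degenerate=degenerate,
    )


def celltype_mixed_model(
    scores: EnrichmentScores,
    cells: ad.AnnData,
    focal_type: str,
    stage_subset: str | None = None,
) -> tuple[float, float, bool]:
    """One-vs-rest mixed model: z ~ 1(cell_type == focal) + (1 | sample_id).

    Fit on cells of ``stage_subset`` when given.  Returns (fixed-effect
    coefficient, Wald p, fallback_used).  A singular/unidentifiable random
    intercept (e.g. a single donor) falls back to OLS with cluster-robust
    standard errors, logged.
    """
    obs = cells.obs
    mask = np.ones(len(obs), dtype=bool)
    if stage_subset is not None:
        mask &= (obs["stage_group"].astype(str) == stage_subset).to_numpy()
    if not (obs.loc[mask, "cell_type"].astype(str) == focal_type).any():
        raise ValueError(f"focal type {focal_type!r} absent from subset")
    df = pd.DataFrame(
        {
            "z": scores.z.loc[obs.index[mask]].to_numpy(),
            "focal": (obs.loc[mask, "cell_type"].astype(str) == focal_type)
            .to_numpy(float),
            "donor": obs.loc[mask, "sample_id"].astype(str).to_numpy(),
        }
    )
    n_donors = df["donor"].nunique()
    if n_donors >= 2:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                md = smf.mixedlm("z ~ focal", df, groups=df["donor"])
                fit = md.fit(reml=True, method="lbfgs")
            if np.isfinite(fit.bse["focal"]) and fit.bse["focal"] > 0:
                return float(fit.params["focal"]), float(fit.pvalues["focal"]), False
        except Exception as exc:  # singular fit
            logger.info("mixed model failed (%s); cluster-robust fallback", exc)
    X = sm.add_constant(df["focal"].to_numpy())
    if n_donors >= 2:
        ols = sm.OLS(df["z"].to_numpy(), X).fit(
            cov_type="cluster", cov_kwds={"groups": df["donor"].to_numpy()}
        )
    else:  # one donor: clustering degenerate, plain OLS inference
        ols = sm.OLS(df["z"].to_numpy(), X).fit()
    return float(ols.params[1]), float(ols.pvalues[1]), True


def enrichment_scan(
    scores: EnrichmentScores,
    cells: ad.AnnData,
    types: Sequence[str] | None = None,
    stages: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Mixed-model coefficients for every (cell type, stage) combination,
    BH-adjusted across all tests of the scan."""
    obs = cells.obs
    if types is None:
        types = sorted(obs["cell_type"].astype(str).unique())
    if stages is None:
        stages = sorted(obs["stage_group"].astype(str).unique())
    rows = []
    for st in stages:
        for t in types:
            try:
                coef, p, fb = celltype_mixed_model(scores, cells, t, st)
            except ValueError:
                continue
            rows.append({"stage_group": st, "cell_type": t, "coef": coef,
                         "p": p, "fallback": fb})
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out


def paired_set_contrast(
    z_target: EnrichmentScores,
    z_other: EnrichmentScores,
    cells: ad.AnnData,
    focal_type: str,
) -> tuple[float, float]:
    """Paired per-cell contrast of two target sets within a focal cell type
    (e.g. disease peaks inside vs outside TRDs): mean difference and paired-t p."""
    mask = cells.obs["cell_type"].astype(str) == focal_type
    a = z_target.z.loc[cells.obs_names[mask]]
    b = z_other.z.loc[cells.obs_names[mask]]
    res = stats.ttest_rel(a, b)
    return float((a - b).mean()), float(res.pvalue)
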