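"""Per-peak case/control differential accessibility.

Fits, for every peak, the linear model ``accessibility ~ group + covariates``
and reports the group coefficient as log2 fold change (case minus control on
the log scale), its t statistic, two-sided p-value and Benjamini-Hochberg
FDR.  The up/down partition of significant peaks by fold-change sign feeds
every later stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import bh_adjust
from .matrix import AccessibilityMatrix, _design_matrix
from .peaks import PeakSet, write_bed


@dataclass
class DifferentialResult:
    """Per-peak differential statistics.

    ``direction`` is ``up`` iff log2fc > 0, ``down`` iff < 0; exact zeros
    (e.g. constant peaks) belong to neither set.
    """

    table: pd.DataFrame = field(repr=False)
    group: str = "diagnosis"
    alpha: float = 0.05

    def significant_ids(self, alpha: float | None = None) -> pd.Index:
        a = self.alpha if alpha is None else alpha
        return self.table.index[self.table["fdr"] < a]

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="peak_id")


def differential_peaks(
    m: AccessibilityMatrix,
    group: str = "diagnosis",
    covariates: Sequence[str] = (),
    case_level: str = "case",
    moderated: bool = False,
) -> DifferentialResult:
    """Per-peak linear-model test of the two-level group effect.

    Ordinary (non-moderated) t statistics by default; ``moderated=True``
    applies a simple empirical-Bayes shrink of per-peak variances toward
    their grand mean (equal-weight blend), an idiomatic option for small
    cohorts.
    """
    meta = m.metadata
    if group not in meta.columns:
        raise KeyError(f"group column not in metadata: {group}")
    levels = pd.unique(meta[group])
    if len(levels) != 2:
        raise ValueError(f"group must have exactly 2 levels, got {list(levels)}")
    counts = meta[group].value_counts()
    if counts.min() < 3:
        raise ValueError("each group level needs >= 3 samples")
    if case_level not in levels:
        case_level = sorted(map(str, levels))[0]
    indicator = (meta[group].astype(str) == str(case_level)).to_numpy(float)

    Xcov = _design_matrix(meta, covariates).to_numpy(float)
    X = np.column_stack([Xcov, indicator])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient (group collinear "
                         "with covariates?)")
    Y = m.values.to_numpy(float)
    n, p = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ Y)
    resid = Y - X @ beta
    dof = n - p
    rss = (resid ** 2).sum(axis=0)
    sigma2 = rss / dof
    if moderated:
        sigma2 = 0.5 * sigma2 + 0.5 * sigma2.mean()
    g = p - 1  # group coefficient index
    se = np.sqrt(sigma2 * XtX_inv[g, g])
    log2fc = beta[g]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log2fc / se, 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(t), dof)
    constant = Y.std(axis=0) == 0
    log2fc = np.where(constant, 0.0, log2fc)
    t = np.where(constant, 0.0, t)
    pvals = np.where(constant | (se == 0), 1.0, pvals)
    fdr = bh_adjust(pvals)
    direction = np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "none"))
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "t": t,
            "p": pvals,
            "fdr": fdr,
            "direction": direction,
        },
        index=m.peak_ids.rename("peak_id"),
    )
    return DifferentialResult(table=table, group=group)


def direction_partition(
    d: DifferentialResult, alpha: float = 0.05
) -> tuple[pd.Index, pd.Index]:
    """Split significant peaks into disjoint (up, down) ID sets."""
    sig = d.table[d.table["fdr"] < alpha]
    up = sig.index[sig["log2fc"] > 0]
    down = sig.index[sig["log2fc"] < 0]
    return up, down


def export_annotation_bed(
    peaks: PeakSet, subset: Iterable[str], path: str | Path
) -> None:
    """Write a sorted BED of a peak subset for external heritability tools."""
    subset = list(subset)
    unknown = set(subset) - set(peaks.ids)
    if unknown:
        raise KeyError(f"unknown peak ids in subset: {sorted(unknown)[:5]}")
    write_bed(peaks, path, subset=subset, header_when_empty=True)
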