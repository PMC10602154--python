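"""Interval-restricted polygenic scoring.

Scores samples as weighted dosage sums, optionally restricting the weight
table to variants falling inside a chosen peak subset (e.g. the OCRs of one
TRD), then reports the logistic case/control odds ratio per SD of score,
Nagelkerke pseudo-R^2 and the average variance explained per variant — the
quantity that ranks TRDs by per-variant information content.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

_WEIGHT_COLS = ["variant_id", "chrom", "pos", "weight"]


def validate_weights(w: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _WEIGHT_COLS if c not in w.columns]
    if missing:
        raise ValueError(f"weight table missing columns {missing}")
    if w["variant_id"].duplicated().any():
        raise ValueError("duplicate variant_ids in weight table")
    if (w["pos"] < 1).any():
        raise ValueError("positions must be 1-based (>= 1)")
    return w


def subset_variants_by_intervals(
    w: pd.DataFrame, peaks, subset: Iterable[str] | None = None
) -> pd.DataFrame:
    """Restrict a weight table to variants inside a peak subset.

    Peak coordinates are 0-based half-open; a 1-based variant position falls
    inside [start, end) iff start + 1 <= pos <= end.
    """
    validate_weights(w)
    table = peaks.table if subset is None else peaks.subset(subset).table
    keep = np.zeros(len(w), dtype=bool)
    pos = w["pos"].to_numpy(np.int64)
    for chrom, sub in table.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy(np.int64)
        ends_cummax = np.maximum.accumulate(sub["end"].to_numpy(np.int64))
        on_chrom = (w["chrom"].astype(str) == str(chrom)).to_numpy()
        if not on_chrom.any():
            continue
        p = pos[on_chrom]
        # candidate intervals with start <= pos - 1  (i.e. start + 1 <= pos)
        idx = np.searchsorted(starts, p - 1, side="right")
        hit = (idx > 0) & (ends_cummax[np.maximum(idx - 1, 0)] >= p)
        keep[np.flatnonzero(on_chrom)] = hit
    out = w[keep].reset_index(drop=True)
    if len(out) == 0:
        raise ValueError("no variants in intervals")
    return out


def score_samples(
    w: pd.DataFrame, dosages: pd.DataFrame, max_missing: float = 0.2
) -> pd.Series:
    """Per-sample weighted dosage sum.

    Missing dosages are mean-imputed per variant (count logged); a variant
    missing in more than ``max_missing`` of samples is dropped with a
    warning.  All weight-table variants must exist in the dosage matrix.
    """
    validate_weights(w)
    absent = set(w["variant_id"]) - set(dosages.columns)
    if absent:
        raise KeyError(f"variants absent from dosage matrix: {sorted(absent)[:5]}")
    D = dosages.loc[:, list(w["variant_id"])].to_numpy(float)
    weights = w["weight"].to_numpy(float)
    miss = np.isnan(D)
    frac_missing = miss.mean(axis=0)
    drop = frac_missing > max_missing
    if drop.any():
        logger.warning("dropping %d variants with > %.0f%% missing dosages",
                       int(drop.sum()), 100 * max_missing)
        D, weights, miss = D[:, ~drop], weights[~drop], miss[:, ~drop]
    if miss.any():
        logger.info("mean-imputing %d missing dosage entries", int(miss.sum()))
        col_mean = np.nanmean(D, axis=0)
        D = np.where(miss, col_mean[None, :], D)
    return pd.Series(D @ weights, index=dosages.index, name="score")


@dataclass
class PrsResult:
    """Association of one score set with case status."""

    scores: pd.Series = field(repr=False)
    n_variants: int = 0
    odds_ratio: float = float("nan")
    se_log_or: float = float("nan")
    or_ci: tuple[float, float] = (float("nan"), float("nan"))
    p: float = float("nan")
    nagelkerke_r2: float = float("nan")
    variance_per_variant: float = float("nan")
    penalized: bool = False


def prs_association(
    scores: pd.Series,
    metadata: pd.DataFrame,
    n_variants: int,
    group: str = "diagnosis",
    case_level: str = "case",
    covariates: Sequence[str] = (),
) -> PrsResult:
    """Logistic regression of case status on the standardized score.

    Reports the OR per SD of score with Wald SE/CI, Nagelkerke pseudo-R^2,
    and variance explained per variant (R^2 / n_variants).  Complete
    separation falls back to an L2-penalized fit with a notice.
    """
    if n_variants <= 0:
        raise ValueError("n_variants must be > 0 for a reported score set")
    y = (metadata[group].astype(str) == case_level).to_numpy(float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both case and control samples are required")
    s = scores.loc[metadata.index].to_numpy(float)
    sd = s.std(ddof=0)
    if sd == 0:
        raise ValueError("score has zero variance")
    s = (s - s.mean()) / sd
    cols = [s]
    for c in covariates:
        v = metadata[c]
        cols.append(
            v.to_numpy(float)
            if pd.api.types.is_numeric_dtype(v)
            else pd.get_dummies(v, drop_first=True).to_numpy(float)[:, 0]
        )
    X = sm.add_constant(np.column_stack(cols))
    penalized = False
    try:
        fit = sm.Logit(y, X).fit(disp=0)
        if not np.isfinite(fit.bse[1]) or fit.bse[1] > 1e3:
            raise np.linalg.LinAlgError("separation")
        llf, llnull = fit.llf, fit.llnull
        params, bse, pval = fit.params, fit.bse, fit.pvalues[1]
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
        logger.warning("separation detected; using L2-penalized logistic fit")
        penalized = True
        model = sm.Logit(y, X)
        fit = model.fit_regularized(alpha=1.0, L1_wt=0.0, disp=0)
        params = fit.params
        llf = model.loglike(params)
        llnull = sm.Logit(y, np.ones((len(y), 1))).fit(disp=0).llf
        bse = np.full_like(params, np.nan)
        pval = float("nan")
    n = len(y)
    r2_cs = 1.0 - np.exp(2.0 * (llnull - llf) / n)
    r2_max = 1.0 - np.exp(2.0 * llnull / n)
    nagelkerke = float(r2_cs / r2_max) if r2_max > 0 else float("nan")
    log_or, se = float(params[1]), float(bse[1])
    ci = (np.exp(log_or - 1.96 * se), np.exp(log_or + 1.96 * se))
    return PrsResult(
        scores=pd.Series(s, index=metadata.index, name="score_std"),
        n_variants=n_variants,
        odds_ratio=float(np.exp(log_or)),
        se_log_or=se,
        or_ci=(float(ci[0]), float(ci[1])),
        p=float(pval),
        nagelkerke_r2=nagelkerke,
        variance_per_variant=nagelkerke / n_variants,
        penalized=penalized,
    )


def partitioned_prs(
    weights: pd.DataFrame,
    dosages: pd.DataFrame,
    peaks,
    partitions: Mapping[str, Sequence[str]],
    metadata: pd.DataFrame,
    include_genome_wide: bool = True,
    covariates: Sequence[str] = (),
) -> pd.DataFrame:
    """Score and test one interval-restricted PRS per named peak partition.

    ``partitions`` maps a set name (e.g. ``"TRD1"``) to its peak IDs.  Rows
    with no variants in intervals are reported with NaN statistics rather
    than aborting the scan.
    """
    rows = []
    items = list(partitions.items())
    if include_genome_wide:
        items.append(("genome_wide", None))
    for name, subset in items:
        try:
            if subset is None:
                w = validate_weights(weights)
            else:
                w = subset_variants_by_intervals(weights, peaks, subset)
            s = score_samples(w, dosages)
            res = prs_association(
                s, metadata, n_variants=len(w), covariates=covariates
            )
            rows.append(
                {
                    "set": name,
                    "n_variants": len(w),
                    "odds_ratio": res.odds_ratio,
                    "p": res.p,
                    "nagelkerke_r2": res.nagelkerke_r2,
                    "variance_per_variant": res.variance_per_variant,
                }
            )
        except ValueError as exc:
            logger.warning("PRS set %s skipped: %s", name, exc)
            rows.append(
                {"set": name, "n_variants": 0, "odds_ratio": np.nan,
                 "p": np.nan, "nagelkerke_r2": np.nan,
                 "variance_per_variant": np.nan}
            )
    return pd.DataFrame(rows).set_index("set")
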