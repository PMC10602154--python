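"""Samples x peaks accessibility matrix: I/O, normalization, residualization.

The matrix holds log-scale accessibility ("OCR expression") with one row per
sample and one column per peak, aligned to a :class:`~chromdomains.peaks.PeakSet`.
Per-sample metadata (diagnosis, age, sex, technical covariates, optional PRS)
rides along in a parallel table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass
class AccessibilityMatrix:
    """Log-scale accessibility values plus aligned per-sample metadata."""

    values: pd.DataFrame = field(repr=False)  # samples x peaks
    metadata: pd.DataFrame = field(repr=False)  # indexed by sample_id

    def __post_init__(self):
        if not self.values.index.equals(self.metadata.index):
            raise ValueError("metadata rows must align one-to-one with samples")
        if self.values.isna().any().any():
            bad = self.values.columns[self.values.isna().any()][0]
            raise ValueError(f"missing values in accessibility matrix (e.g. {bad})")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate peak ids in matrix columns")

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def peak_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def subset_peaks(self, ids: Sequence[str]) -> "AccessibilityMatrix":
        return AccessibilityMatrix(self.values.loc[:, list(ids)], self.metadata)

    def to_counts(self) -> pd.DataFrame:
        """Strictly positive log-normal counts-scale view (2**values)."""
        return np.power(2.0, self.values)


def normalize(
    counts: pd.DataFrame, metadata: pd.DataFrame | None = None
) -> AccessibilityMatrix:
    """Library-size normalize raw counts: counts-per-million then log2(x+1).

    Scale-invariant per sample (doubling a sample's counts leaves its row
    unchanged) and maps zero counts to exactly zero.
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    depth = counts.sum(axis=1)
    zero = depth[depth == 0]
    if len(zero):
        raise ValueError(f"all-zero sample: {zero.index[0]}")
    cpm = counts.div(depth, axis=0) * 1e6
    vals = np.log2(cpm + 1.0)
    if metadata is None:
        metadata = pd.DataFrame(index=counts.index)
    return AccessibilityMatrix(vals, metadata.loc[counts.index])


def _design_matrix(
    metadata: pd.DataFrame, covariates: Sequence[str]
) -> pd.DataFrame:
    """Intercept + numeric/dummy-coded covariate design."""
    cols = {"intercept": np.ones(len(metadata))}
    for name in covariates:
        if name not in metadata.columns:
            raise KeyError(f"covariate not in metadata: {name}")
        col = metadata[name]
        if pd.api.types.is_numeric_dtype(col):
            cols[name] = col.to_numpy(dtype=float)
        else:
            dummies = pd.get_dummies(col.astype("category"), drop_first=True)
            for lvl in dummies.columns:
                cols[f"{name}[{lvl}]"] = dummies[lvl].to_numpy(dtype=float)
    return pd.DataFrame(cols, index=metadata.index)


def residualize(
    m: AccessibilityMatrix,
    covariates: Sequence[str],
    protected: Sequence[str] = ("diagnosis", "group"),
) -> AccessibilityMatrix:
    """Replace each peak column with OLS residuals on intercept + covariates.

    The diagnosis/group label is never allowed among the covariates — the
    disease signal must survive correction.  Idempotent to numerical
    tolerance.  A rank-deficient design raises an error listing the
    offending columns.
    """
    for p in protected:
        if p in covariates:
            raise ValueError(f"refusing to residualize out {p!r}")
    X = _design_matrix(m.metadata, covariates).to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        names = _design_matrix(m.metadata, covariates).columns
        collinear = []
        keep: list[int] = []
        for j in range(X.shape[1]):
            if np.linalg.matrix_rank(X[:, keep + [j]]) > len(keep):
                keep.append(j)
            else:
                collinear.append(names[j])
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")
    Y = m.values.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return AccessibilityMatrix(
        pd.DataFrame(resid, index=m.values.index, columns=m.values.columns),
        m.metadata,
    )


# ---------------------------------------------------------------------------
# Peak -> gene links (enhancer-promoter table, consumed not computed)
# ---------------------------------------------------------------------------

def read_links(path: str | Path) -> pd.DataFrame:
    """Read a peak->gene link table (TSV: peak_id, gene_id, score)."""
    df = pd.read_csv(path, sep="\t")
    required = {"peak_id", "gene_id", "score"}
    if not required.issubset(df.columns):
        raise ValueError(f"link table needs columns {sorted(required)}")
    if (df["score"] < 0).any():
        raise ValueError("link scores must be >= 0")
    return df


def map_peaks_to_genes(
    peaks: "PeakSet", links: pd.DataFrame
) -> dict[str, set[str]]:
    """Map every peak to its set of linked genes (empty set when unlinked).

    Link rows naming an unknown peak are dropped with a warning; duplicate
    (peak, gene) rows collapse.
    """
    from .peaks import PeakSet  # noqa: F401  (type only)

    known = set(peaks.ids)
    unknown = ~links["peak_id"].isin(known)
    if unknown.any():
        warnings.warn(
            f"dropping {int(unknown.sum())} link rows with unknown peak_id",
            stacklevel=2,
        )
        links = links[~unknown]
    mapping: dict[str, set[str]] = {pid: set() for pid in peaks.ids}
    for pid, gid in links[["peak_id", "gene_id"]].drop_duplicates().itertuples(
        index=False
    ):
        mapping[pid].add(gid)
    return mapping


# ---------------------------------------------------------------------------
# TSV round-trip I/O
# ---------------------------------------------------------------------------

def write_matrix(m: AccessibilityMatrix, values_path, metadata_path) -> None:
    m.values.to_csv(values_path, sep="\t", index_label="sample_id")
    m.metadata.to_csv(metadata_path, sep="\t", index_label="sample_id")


def read_matrix(values_path, metadata_path) -> AccessibilityMatrix:
    vals = pd.read_csv(values_path, sep="\t", index_col="sample_id")
    meta = pd.read_csv(metadata_path, sep="\t", index_col="sample_id")
    return AccessibilityMatrix(vals, meta.loc[vals.index])
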