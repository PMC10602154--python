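"""Peak universe: ordered genomic intervals (open chromatin regions).

Coordinates are 0-based half-open (BED convention) throughout the package;
any 1-based interchange (e.g. variant positions) is converted at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

_BED_COLS = ["chrom", "start", "end", "peak_id"]


def _natural_chrom_key(chrom: pd.Series) -> pd.Series:
    """Sort chromosomes numerically where possible (chr2 before chr10)."""

    def key(c: str) -> tuple:
        c = str(c)
        stripped = c[3:] if c.lower().startswith("chr") else c
        if stripped.isdigit():
            return (0, int(stripped), c)
        return (1, 0, c)

    return chrom.map(key)


@dataclass(frozen=True)
class PeakSet:
    """Ordered, validated set of genomic intervals with unique stable IDs.

    The coordinate backbone of every matrix in the pipeline: the column order
    of an accessibility matrix always matches ``PeakSet`` order.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        df = self.table
        missing = [c for c in _BED_COLS if c not in df.columns]
        if missing:
            raise ValueError(f"PeakSet table missing columns {missing}")
        if (df["start"] >= df["end"]).any():
            bad = df.loc[df["start"] >= df["end"], "peak_id"].iloc[0]
            raise ValueError(f"interval with start >= end: {bad}")
        if df["peak_id"].duplicated().any():
            dup = df.loc[df["peak_id"].duplicated(), "peak_id"].iloc[0]
            raise ValueError(f"duplicate peak_id: {dup}")
        if df.duplicated(subset=["chrom", "start", "end"]).any():
            d = df[df.duplicated(subset=["chrom", "start", "end"])].iloc[0]
            raise ValueError(
                f"duplicated interval {d.chrom}:{d.start}-{d.end}"
            )
        key = _natural_chrom_key(df["chrom"])
        order = df.assign(_k=key).sort_values(["_k", "start", "end"]).index
        if not (order == df.index).all():
            object.__setattr__(
                self,
                "table",
                df.loc[order].reset_index(drop=True),
            )
        else:
            object.__setattr__(self, "table", df.reset_index(drop=True))

    @classmethod
    def from_arrays(
        cls,
        chrom: Sequence[str],
        start: Sequence[int],
        end: Sequence[int],
        peak_id: Sequence[str] | None = None,
    ) -> "PeakSet":
        df = pd.DataFrame(
            {
                "chrom": list(chrom),
                "start": np.asarray(start, dtype=np.int64),
                "end": np.asarray(end, dtype=np.int64),
            }
        )
        if peak_id is None:
            df["peak_id"] = [
                f"{c}:{s}-{e}" for c, s, e in zip(df.chrom, df.start, df.end)
            ]
        else:
            df["peak_id"] = list(peak_id)
        return cls(df)

    @property
    def ids(self) -> pd.Index:
        return pd.Index(self.table["peak_id"])

    def __len__(self) -> int:
        return len(self.table)

    def lengths(self) -> pd.Series:
        t = self.table
        return pd.Series(
            (t["end"] - t["start"]).to_numpy(),
            index=t["peak_id"],
            name="length",
        )

    def subset(self, ids: Iterable[str]) -> "PeakSet":
        ids = set(ids)
        unknown = ids - set(self.table["peak_id"])
        if unknown:
            raise KeyError(f"unknown peak ids: {sorted(unknown)[:5]}")
        return PeakSet(
            self.table[self.table["peak_id"].isin(ids)].reset_index(drop=True)
        )

    def by_chromosome(self) -> dict[str, pd.DataFrame]:
        return {
            str(c): g.reset_index(drop=True)
            for c, g in self.table.groupby("chrom", sort=False)
        }


def read_peaks(path: str | Path) -> PeakSet:
    """Read a 3+ column BED file (0-based half-open) into a PeakSet.

    Column 4, when present, supplies the peak ID; otherwise IDs are
    synthesized as ``chrom:start-end``.  Input that is unsorted after parsing
    is repaired silently; a record with start >= end is a parse error
    reported with its line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"line {lineno}: fewer than 3 BED columns")
            chrom, start_s, end_s = parts[0], parts[1], parts[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-integer coordinate") from exc
            if start >= end:
                raise ValueError(
                    f"line {lineno}: start >= end ({chrom}:{start}-{end})"
                )
            name = parts[3] if len(parts) >= 4 and parts[3] != "." else None
            rows.append((chrom, start, end, name))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "peak_id"])
    synth = df["peak_id"].isna()
    df.loc[synth, "peak_id"] = [
        f"{c}:{s}-{e}"
        for c, s, e in zip(df.chrom[synth], df.start[synth], df.end[synth])
    ]
    return PeakSet(df)


def write_bed(
    peaks: PeakSet,
    path: str | Path,
    subset: Iterable[str] | None = None,
    header_when_empty: bool = False,
) -> None:
    """Write peaks (optionally a subset) as sorted 4-column BED."""
    ps = peaks if subset is None else peaks.subset(subset)
    with open(path, "w") as fh:
        if len(ps) == 0 and header_when_empty:
            fh.write("# chrom\tstart\tend\tname (empty subset)\n")
        for row in ps.table.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.peak_id}\n")
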