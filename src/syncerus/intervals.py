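"""A light container for annotated genomic intervals (0-based half-open).

Backed by a pandas DataFrame with columns ``contig, start, end`` plus any
annotation columns; overlap queries go through :mod:`intervaltree`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .containers import FormatError

CORE_COLUMNS = ["contig", "start", "end"]


class IntervalSet:
    """Sorted intervals with per-interval annotations.

    Parameters
    ----------
    df : DataFrame with at least contig/start/end columns.
    contigs : optional iterable declaring the assembly's contig namespace;
        defaults to the contigs present in the data.
    """

    def __init__(self, df: pd.DataFrame, contigs=None):
        missing = [c for c in CORE_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"interval table missing columns: {missing}")
        df = df.copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] < 0).any():
            raise FormatError("negative interval coordinates")
        if (df["end"] <= df["start"]).any():
            bad = df[df["end"] <= df["start"]].iloc[0]
            raise FormatError(
                f"empty or inverted interval {bad['contig']}:{bad['start']}-{bad['end']}"
            )
        self.df = df.sort_values(["contig", "start", "end"]).reset_index(drop=True)
        self.contigs = set(contigs) if contigs is not None else set(df["contig"])
        self._trees: dict | None = None

    def __len__(self) -> int:
        return len(self.df)

    def tree(self, contig) -> IntervalTree:
        if self._trees is None:
            self._trees = {}
            for c, sub in self.df.groupby("contig", sort=False):
                self._trees[c] = IntervalTree.from_tuples(
                    (int(s), int(e), i)
                    for i, (s, e) in zip(sub.index, zip(sub["start"], sub["end"]))
                )
        return self._trees.get(contig, IntervalTree())

    def overlapping(self, contig, start: int, end: int) -> pd.DataFrame:
        """Rows overlapping [start, end) by at least one bp."""
        hits = sorted(iv.data for iv in self.tree(contig).overlap(start, end))
        return self.df.loc[hits]

    def coverage_of(self, contig, start: int, end: int) -> int:
        """Number of bases of [start, end) covered by the (unioned) set."""
        ivs = [(max(int(iv.begin), start), min(int(iv.end), end))
               for iv in self.tree(contig).overlap(start, end)]
        if not ivs:
            return 0
        ivs.sort()
        total, cur_s, cur_e = 0, *ivs[0]
        for s, e in ivs[1:]:
            if s > cur_e:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        return total + cur_e - cur_s


def merge_intervals(df: pd.DataFrame, max_gap: int = 0) -> pd.DataFrame:
    """Union of intervals, additionally joining neighbours < ``max_gap`` bp apart.

    With ``max_gap=0`` this is a plain union of overlapping/adjacent-touching
    intervals; a strictly positive gap smaller than ``max_gap`` is bridged,
    a gap of exactly ``max_gap`` is not.
    """
    if (np.asarray(df["start"]) < 0).any():
        raise FormatError("negative interval coordinates")
    out = []
    for contig, sub in df.sort_values(["contig", "start", "end"]).groupby(
        "contig", sort=True
    ):
        starts = sub["start"].to_numpy(np.int64)
        ends = sub["end"].to_numpy(np.int64)
        cur_s, cur_e = int(starts[0]), int(ends[0])
        for s, e in zip(starts[1:], ends[1:]):
            if s - cur_e < max_gap or s <= cur_e:
                cur_e = max(cur_e, int(e))
            else:
                out.append((contig, cur_s, cur_e))
                cur_s, cur_e = int(s), int(e)
        out.append((contig, cur_s, cur_e))
    return pd.DataFrame(out, columns=CORE_COLUMNS)


def read_bed(path, names=("contig", "start", "end", "name")) -> pd.DataFrame:
    """Read a BED-like TSV (no header) into an interval DataFrame."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = list(names)[: df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path, extra_cols=()) -> None:
    cols = CORE_COLUMNS + [c for c in extra_cols if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)
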