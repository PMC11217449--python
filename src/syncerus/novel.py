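"""Species-specific ("novel") sequence classification and enrichment.

Input intervals are stretches of the assembly not found in any other genome
of an alignment graph.  The pipeline merges intervals less than 5 bp apart,
annotates each region by length (short < 10 bp, intermediate 10-60 bp, large
> 60 bp), position (telomeric when < 10 kb from the end of a scaffold larger
than 5 Mb; gap-flanking when < 1 kb from an N-gap), and type (novel when
> 95% of bases are found in no other genome, divergent haplotype otherwise),
then keeps large, interior regions with at least 50% novel bases.  Retained
regions are validated by per-sample mean read depth, genes fully contained
in them are collected, and gene-set enrichment uses a binomial test against
the genes outside novel regions with Benjamini-Hochberg correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests

from .containers import FormatError, ParameterError
from .intervals import IntervalSet, merge_intervals

log = logging.getLogger(__name__)

TELOMERE_BP = 10_000
TELOMERE_MIN_SCAFFOLD = 5_000_000
GAP_FLANK_BP = 1_000
NOVEL_PCT = 95.0
FILTER_MIN_NOVEL_PCT = 50.0
SHORT_BP = 10
INTERMEDIATE_BP = 60


@dataclass
class AssemblyLayout:
    """Scaffold lengths plus N-gap and repeat-mask interval sets."""

    scaffold_lengths: dict
    gaps: IntervalSet
    repeat_mask: IntervalSet

    def __post_init__(self) -> None:
        for name, iset in (("gaps", self.gaps), ("repeat_mask", self.repeat_mask)):
            for _, row in iset.df.iterrows():
                L = self.scaffold_lengths.get(row["contig"])
                if L is None or row["end"] > L:
                    raise FormatError(
                        f"{name} interval {row['contig']}:{row['start']}-{row['end']} "
                        "outside scaffold bounds"
                    )


def merge_novel_intervals(intervals: pd.DataFrame, max_gap: int = 5) -> pd.DataFrame:
    """Merge graph-derived intervals separated by fewer than ``max_gap`` bp."""
    return merge_intervals(intervals, max_gap=max_gap)


REGION_COLUMNS = [
    "contig", "start", "end", "length", "length_class",
    "telomeric", "gap_flanking", "type_class", "pct_novel", "pct_masked",
]


def classify_regions(
    regions: pd.DataFrame,
    layout: AssemblyLayout,
    novelty: IntervalSet,
) -> pd.DataFrame:
    """Annotate merged regions by length, position and sequence type.

    ``novelty`` is the per-base novelty track as intervals: a base inside it
    is found in no other genome.  ``pct_novel`` and ``pct_masked`` are
    percentages in [0, 100].
    """
    rows = []
    for _, r in regions.iterrows():
        contig, start, end = r["contig"], int(r["start"]), int(r["end"])
        L = layout.scaffold_lengths.get(contig)
        if L is None:
            raise FormatError(f"region on unknown scaffold {contig!r}")
        if end > L:
            raise FormatError(
                f"region {contig}:{start}-{end} beyond scaffold end ({L})"
            )
        length = end - start
        if length < SHORT_BP:
            length_class = "short"
        elif length <= INTERMEDIATE_BP:
            length_class = "intermediate"
        else:
            length_class = "large"
        telomeric = L > TELOMERE_MIN_SCAFFOLD and (
            start < TELOMERE_BP or (L - end) < TELOMERE_BP
        )
        gap_flanking = False
        for iv in layout.gaps.tree(contig).overlap(
            max(0, start - GAP_FLANK_BP), end + GAP_FLANK_BP
        ):
            gap_flanking = True
            break
        pct_novel = 100.0 * novelty.coverage_of(contig, start, end) / length
        pct_masked = 100.0 * layout.repeat_mask.coverage_of(contig, start, end) / length
        type_class = "novel" if pct_novel > NOVEL_PCT else "haplotype"
        rows.append((contig, start, end, length, length_class,
                     telomeric, gap_flanking, type_class, pct_novel, pct_masked))
    return pd.DataFrame(rows, columns=REGION_COLUMNS)


def filter_regions(regions: pd.DataFrame, keep_flagged: bool = False) -> pd.DataFrame:
    """Retain large, mostly-novel, interior regions.

    A region is kept iff it is large (> 60 bp), has >= 50% novel bases, and is
    neither telomeric nor gap-flanking.  ``keep_flagged=True`` inverts the
    positional condition (keeps only telomeric/gap-flanking regions instead).
    """
    interior = ~(regions["telomeric"] | regions["gap_flanking"])
    positional = ~interior if keep_flagged else interior
    keep = (
        (regions["length_class"] == "large")
        & (regions["pct_novel"] >= FILTER_MIN_NOVEL_PCT)
        & positional
    )
    log.info("filter_regions: %d in, %d retained", len(regions), int(keep.sum()))
    return regions[keep].reset_index(drop=True)


@dataclass
class DepthSummary:
    depth: pd.DataFrame       # regions x samples mean depth
    n_low_depth: int          # cross-sample mean < 1
    n_zero_reads: int


def region_mean_depth(regions: pd.DataFrame, reads_by_sample: dict) -> DepthSummary:
    """Mean read depth per region per sample from aligned-read intervals.

    Depth over a region is total overlapping read-bases divided by region
    length.  Reads are interval DataFrames per sample; multiple overlapping
    reads stack (a pileup, not a union).
    """
    if ((regions["end"] - regions["start"]) <= 0).any():
        raise ParameterError("zero-length region in depth computation")
    trees = {
        sample: IntervalSet(df) for sample, df in reads_by_sample.items()
    }
    out = np.zeros((len(regions), len(trees)))
    samples = list(trees)
    for i, (_, r) in enumerate(regions.iterrows()):
        length = int(r["end"]) - int(r["start"])
        for k, sample in enumerate(samples):
            bases = 0
            for iv in trees[sample].tree(r["contig"]).overlap(int(r["start"]), int(r["end"])):
                bases += min(int(iv.end), int(r["end"])) - max(int(iv.begin), int(r["start"]))
            out[i, k] = bases / length
    depth = pd.DataFrame(out, columns=samples)
    mean_across = depth.mean(axis=1) if samples else pd.Series(np.zeros(len(regions)))
    return DepthSummary(
        depth=depth,
        n_low_depth=int((mean_across < 1.0).sum()),
        n_zero_reads=int((depth.sum(axis=1) == 0).sum()),
    )


def contained_features(
    regions: pd.DataFrame, features: IntervalSet
) -> tuple[set, set]:
    """(overlapping, fully contained) gene sets for the retained regions.

    A gene overlaps when it shares >= 1 bp with any region; it is fully
    contained when its entire span lies within a single region.
    """
    unknown = sorted(set(regions["contig"]) - features.contigs)
    if unknown:
        raise ParameterError(f"region contigs unknown to feature set: {unknown}")
    name_col = "name" if "name" in features.df.columns else "gene_id"
    overlapping: set = set()
    contained: set = set()
    for _, r in regions.iterrows():
        start, end = int(r["start"]), int(r["end"])
        hits = features.overlapping(r["contig"], start, end)
        for _, g in hits.iterrows():
            overlapping.add(g[name_col])
            if g["start"] >= start and g["end"] <= end:
                contained.add(g[name_col])
    return overlapping, contained


ENRICH_COLUMNS = [
    "term", "kind", "fg_count", "bg_count", "fg_size", "bg_size",
    "p", "fdr", "significant", "bg_smoothed",
]


def term_enrichment(
    foreground: set,
    background: set,
    gene_terms: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Binomial term enrichment of foreground genes against a background.

    Only genes with at least one annotated term participate.  Per term, the
    p-value is the two-sided binomial test of the foreground count given the
    foreground size and the background term frequency; terms absent from the
    background use an add-one-smoothed frequency and are flagged.  FDR is
    Benjamini-Hochberg across all tested terms.
    """
    foreground, background = set(foreground), set(background)
    if foreground & background:
        raise ParameterError("foreground and background gene sets overlap")
    annotated = gene_terms.groupby("gene_id")["term_id"].apply(set)
    fg = [g for g in sorted(foreground) if g in annotated.index]
    bg = [g for g in sorted(background) if g in annotated.index]
    if not fg or not bg:
        raise ParameterError("no annotated genes in foreground or background")
    fg_size, bg_size = len(fg), len(bg)

    terms: dict[str, list] = {}
    kinds = dict(zip(gene_terms["term_id"], gene_terms.get("term_kind", "")))
    for gene_set, bucket in ((fg, 0), (bg, 1)):
        for g in gene_set:
            for t in annotated[g]:
                terms.setdefault(t, [0, 0])[bucket] += 1

    rows = []
    for t in sorted(terms):
        k_fg, k_bg = terms[t]
        smoothed = k_bg == 0
        freq = (k_bg + 1) / (bg_size + 1) if smoothed else k_bg / bg_size
        p = binomtest(k_fg, fg_size, min(freq, 1.0), alternative="two-sided").pvalue
        rows.append((t, kinds.get(t, ""), k_fg, k_bg, fg_size, bg_size, p, smoothed))
    df = pd.DataFrame(rows, columns=["term", "kind", "fg_count", "bg_count",
                                     "fg_size", "bg_size", "p", "bg_smoothed"])
    _, fdr, _, _ = multipletests(df["p"].to_numpy(), method="fdr_bh")
    df["fdr"] = fdr
    df["significant"] = df["fdr"] < alpha
    return df[ENRICH_COLUMNS].sort_values(["p", "term"]).reset_index(drop=True)
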