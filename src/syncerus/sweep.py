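"""EHH, iES and XP-EHH sweep scanning with windowed peak calling.

Extended haplotype homozygosity at distance x from a core site is the
probability that two randomly drawn haplotypes are identical over the whole
interval from the core to x:

    EHH(x) = sum_g C(n_g, 2) / C(n, 2)

where the n_g are the sizes of the distinct haplotype groups over that
interval.  iES is the trapezoidal integral of the site-EHH curve over
genetic distance on both sides of the core (1 cM/Mb by default), and the
cross-population score at a site is raw = ln(iES_A / iES_B), standardized to
zero mean and unit variance genome-wide.  Peaks are called on 1000-SNP
sliding window means of the standardized score: a region enters at
|smoothed| > 4 and extends outward until the smoothed score falls below 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import HaplotypeMatrix, ParameterError
from .intervals import IntervalSet, merge_intervals
from .popgen import _moving_sum

log = logging.getLogger(__name__)

CM_PER_BP_DEFAULT = 1e-6  # 1 cM/Mb


class UndefinedProfileError(ValueError):
    """EHH profile undefined (fewer than two carrier haplotypes)."""


@dataclass
class EhhProfile:
    core: int
    allele: int | None
    direction: str
    site_indices: np.ndarray
    positions_bp: np.ndarray
    cm: np.ndarray
    ehh: np.ndarray

    @property
    def core_cm(self) -> float:
        return float(self.cm[0])


def _pair_fraction(gid: np.ndarray) -> float:
    n = len(gid)
    counts = np.bincount(gid)
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def _walk(
    H: np.ndarray,
    rows: np.ndarray,
    core: int,
    direction: str,
    gid0: np.ndarray,
    cm: np.ndarray,
    truncation: float,
    max_extend_cm: float,
):
    """Walk outward from the core refining haplotype groups.

    Returns (site indices, ehh values) starting at the core itself.  The walk
    stops before appending the first value below ``truncation`` or beyond
    ``max_extend_cm`` of genetic distance.
    """
    m = H.shape[1]
    step = -1 if direction == "left" else 1
    idx = [core]
    ehh = [_pair_fraction(gid0)]
    gid = gid0
    j = core + step
    while 0 <= j < m and abs(cm[j] - cm[core]) <= max_extend_cm:
        key = gid.astype(np.int64) * 2 + H[rows, j]
        _, gid = np.unique(key, return_inverse=True)
        val = _pair_fraction(gid)
        if val < truncation:
            break
        idx.append(j)
        ehh.append(val)
        if val == 0.0:
            break
        j += step
    return np.array(idx), np.array(ehh)


def _default_cm(positions_bp: np.ndarray, cm_per_bp: float) -> np.ndarray:
    return positions_bp.astype(np.float64) * cm_per_bp


def ehh_profile(
    haps: HaplotypeMatrix,
    core: int,
    allele: int,
    direction: str,
    truncation: float = 0.05,
    max_extend_cm: float = 2.0,
    cm: np.ndarray | None = None,
    cm_per_bp: float = CM_PER_BP_DEFAULT,
) -> EhhProfile:
    """Allele-conditional EHH profile from a core site outward.

    Only haplotypes carrying ``allele`` at the core participate; EHH at the
    core is exactly 1 and the curve is non-increasing with distance.
    """
    if direction not in ("left", "right"):
        raise ParameterError(f"direction must be left/right, got {direction!r}")
    H = haps.haplotypes
    pos = haps.sites["pos"].to_numpy()
    if cm is None:
        cm = _default_cm(pos, cm_per_bp)
    rows = np.flatnonzero(H[:, core] == allele)
    if len(rows) < 2:
        raise UndefinedProfileError(
            f"site {core}: {len(rows)} haplotypes carry allele {allele}"
        )
    gid0 = np.zeros(len(rows), dtype=np.int64)
    idx, ehh = _walk(H, rows, core, direction, gid0, cm, truncation, max_extend_cm)
    return EhhProfile(
        core=core, allele=allele, direction=direction,
        site_indices=idx, positions_bp=pos[idx], cm=cm[idx], ehh=ehh,
    )


def site_ehh_curves(
    haps: HaplotypeMatrix,
    core: int,
    truncation: float = 0.05,
    max_extend_cm: float = 2.0,
    cm: np.ndarray | None = None,
    cm_per_bp: float = CM_PER_BP_DEFAULT,
) -> tuple[EhhProfile, EhhProfile]:
    """Whole-sample (site) EHH curves left and right of the core.

    All haplotypes participate; the initial partition is given by the core
    alleles, so the curve starts below 1 at the core.  This is the quantity
    integrated by iES for the cross-population statistic.
    """
    H = haps.haplotypes
    pos = haps.sites["pos"].to_numpy()
    if cm is None:
        cm = _default_cm(pos, cm_per_bp)
    rows = np.arange(H.shape[0])
    if len(rows) < 2:
        raise UndefinedProfileError("need at least two haplotypes")
    gid0 = H[:, core].astype(np.int64)
    out = []
    for direction in ("left", "right"):
        idx, ehh = _walk(H, rows, core, direction, gid0, cm, truncation, max_extend_cm)
        out.append(
            EhhProfile(core=core, allele=None, direction=direction,
                       site_indices=idx, positions_bp=pos[idx], cm=cm[idx], ehh=ehh)
        )
    return out[0], out[1]


def integrate_ies(left: EhhProfile, right: EhhProfile) -> float:
    """Trapezoidal integral of EHH against |genetic distance|, both sides."""
    total = 0.0
    for prof in (left, right):
        if len(prof.ehh) == 0:
            raise ParameterError("empty EHH profile")
        x = np.abs(prof.cm - prof.core_cm)
        total += float(np.trapezoid(prof.ehh, x))
    return total


@dataclass
class ScanResult:
    """Per-site cross-population scores over the usable sites."""

    table: pd.DataFrame  # contig, pos, ies_a, ies_b, raw, std
    n_skipped: int = 0
    contig_lengths: dict = field(default_factory=dict)


def xpehh_scan(
    haps_a: HaplotypeMatrix,
    haps_b: HaplotypeMatrix,
    truncation: float = 0.05,
    max_extend_cm: float = 2.0,
    cm_per_bp: float = CM_PER_BP_DEFAULT,
) -> ScanResult:
    """Cross-population EHH scan: raw = ln(iES_A/iES_B), standardized.

    Sites monomorphic in either population, or with a vanishing iES, are
    skipped and logged.  Swapping the populations negates the raw scores.
    """
    if not haps_a.sites[["contig", "pos"]].equals(haps_b.sites[["contig", "pos"]]):
        raise ParameterError("the two populations must share one site table")
    m = haps_a.n_sites
    pos = haps_a.sites["pos"].to_numpy()
    contig = haps_a.sites["contig"].to_numpy()
    cm = _default_cm(pos, cm_per_bp)

    rows = []
    skipped = 0
    for j in range(m):
        ok = True
        ies = []
        for hm in (haps_a, haps_b):
            col = hm.haplotypes[:, j]
            if col.min() == col.max():  # monomorphic core
                ok = False
                break
            l, r = site_ehh_curves(hm, j, truncation, max_extend_cm, cm=cm)
            v = integrate_ies(l, r)
            if v <= 0.0:
                ok = False
                break
            ies.append(v)
        if not ok:
            skipped += 1
            continue
        rows.append((contig[j], pos[j], ies[0], ies[1], np.log(ies[0] / ies[1])))
    if not rows:
        raise ParameterError("no usable sites in XP-EHH scan")
    table = pd.DataFrame(rows, columns=["contig", "pos", "ies_a", "ies_b", "raw"])
    raw = table["raw"].to_numpy()
    sd = raw.std(ddof=0)
    table["std"] = (raw - raw.mean()) / sd if sd > 0 else 0.0
    log.info("xpehh_scan: %d usable sites, %d skipped", len(table), skipped)
    return ScanResult(table=table, n_skipped=skipped,
                      contig_lengths=dict(haps_a.contig_lengths))


# ---------------------------------------------------------------------------
# Peak calling
# ---------------------------------------------------------------------------

PEAK_COLUMNS = ["contig", "start", "end", "max_abs_smoothed", "n_snps"]


def smooth_scores(scores: np.ndarray, window_snps: int) -> np.ndarray:
    """Centered sliding window means (step 1 SNP); length m - w + 1."""
    return _moving_sum(np.asarray(scores, dtype=np.float64), window_snps) / window_snps


def call_sweep_peaks(
    scan: ScanResult,
    window_snps: int = 1000,
    enter: float = 4.0,
    exit: float = 2.0,
) -> pd.DataFrame:
    """Windowed peak caller on the standardized score track.

    Per contig with at least ``window_snps`` scored sites, the smoothed value
    of each sliding window is the mean standardized score of its SNPs.  A peak
    is a maximal run of windows with |smoothed| >= ``exit`` containing at
    least one window with |smoothed| > ``enter``; its boundaries are the bp of
    the outermost SNPs of the boundary windows.  Peaks whose spans overlap
    after expansion are merged.
    """
    if exit > enter:
        raise ParameterError("exit threshold must not exceed entry threshold")
    peaks = []
    for contig, sub in scan.table.groupby("contig", sort=False):
        pos = sub["pos"].to_numpy()
        s = sub["std"].to_numpy()
        m = len(s)
        if m < window_snps:
            continue
        w = np.abs(smooth_scores(s, window_snps))
        hold = w >= exit
        spans = []
        for a, b in _runs(hold):
            if (w[a:b] > enter).any():
                first_snp, last_snp = a, b - 1 + window_snps - 1
                spans.append(
                    (int(pos[first_snp]), int(pos[last_snp]) + 1,
                     float(w[a:b].max()), last_snp - first_snp + 1)
                )
        # merge bp-overlapping spans (adjacent window runs share SNPs)
        spans.sort()
        merged = []
        for st, en, mx, ns in spans:
            if merged and st < merged[-1][1]:
                pst, pen, pmx, _ = merged[-1]
                en = max(en, pen)
                n_span = int(np.searchsorted(pos, en) - np.searchsorted(pos, pst))
                merged[-1] = (pst, en, max(mx, pmx), n_span)
            else:
                merged.append((st, en, mx, ns))
        peaks.extend((contig, *t) for t in merged)
    return pd.DataFrame(peaks, columns=PEAK_COLUMNS)


def top_smoothed_location(scan: ScanResult, window_snps: int = 1000) -> tuple:
    """(contig, bp) of the center of the window maximizing |smoothed score|."""
    best = (None, None, -np.inf)
    for contig, sub in scan.table.groupby("contig", sort=False):
        s = sub["std"].to_numpy()
        if len(s) < window_snps:
            continue
        w = np.abs(smooth_scores(s, window_snps))
        j = int(np.argmax(w))
        if w[j] > best[2]:
            center = int(sub["pos"].to_numpy()[j + window_snps // 2])
            best = (contig, center, float(w[j]))
    if best[0] is None:
        raise ParameterError("no contig has enough scored sites for the window")
    return best[0], best[1]


def _runs(mask: np.ndarray):
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    return zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1))


# ---------------------------------------------------------------------------
# Peak / feature overlap
# ---------------------------------------------------------------------------

def overlap_loci(
    peaks: pd.DataFrame,
    features: IntervalSet,
    second: IntervalSet | None = None,
) -> pd.DataFrame:
    """Annotate peaks with overlapping features (>= 1 bp).

    Returns the peak table with a ``features`` column (list of feature names)
    and, when ``second`` is given, a boolean ``in_second`` column plus a
    ``second_genes`` attribute-style summary: the distinct feature names of
    peaks that also intersect a ``second`` interval.
    """
    unknown = sorted(set(peaks["contig"]) - features.contigs)
    if unknown:
        raise ParameterError(f"peak contigs unknown to feature set: {unknown}")
    if second is not None:
        unknown = sorted(set(peaks["contig"]) - second.contigs)
        if unknown:
            raise ParameterError(f"peak contigs unknown to second set: {unknown}")

    name_col = "name" if "name" in features.df.columns else None
    out = peaks.copy().reset_index(drop=True)
    feats, in_second = [], []
    for _, row in out.iterrows():
        hits = features.overlapping(row["contig"], int(row["start"]), int(row["end"]))
        feats.append(sorted(hits[name_col]) if name_col else list(hits.index))
        if second is not None:
            hit2 = second.overlapping(row["contig"], int(row["start"]), int(row["end"]))
            in_second.append(len(hit2) > 0)
    out["features"] = feats
    if second is not None:
        out["in_second"] = in_second
        out.attrs["second_genes"] = sorted(
            {g for f, s in zip(feats, in_second) if s for g in f}
        )
    return out
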