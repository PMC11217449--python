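"""Weir-Cockerham FST, runs of homozygosity, FROH and PCA.

The FST estimator is the Weir & Cockerham (1984) variance-components form
with r = 2 populations.  Per site, with sample sizes n_1, n_2 (called
individuals), alternate-allele frequencies p_1, p_2 and observed
heterozygote frequencies h_1, h_2:

    n_bar = (n_1 + n_2) / 2
    n_c   = 2 n_bar - (n_1^2 + n_2^2) / (2 n_bar)
    p_bar = (n_1 p_1 + n_2 p_2) / (2 n_bar)
    s^2   = (n_1 (p_1 - p_bar)^2 + n_2 (p_2 - p_bar)^2) / n_bar
    h_bar = (n_1 h_1 + n_2 h_2) / (2 n_bar)

    a = n_bar / n_c * (s^2 - (p_bar q_bar - s^2/2 - h_bar/4) / (n_bar - 1))
    b = n_bar / (n_bar - 1) * (p_bar q_bar - s^2/2 - (2 n_bar - 1)/(4 n_bar) h_bar)
    c = h_bar / 2

and the multi-site estimate is the ratio of sums sum(a) / sum(a + b + c),
never a mean of per-site ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, ParameterError, PopulationGroup

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# FST
# ---------------------------------------------------------------------------

@dataclass
class FstResult:
    pop_a: str
    pop_b: str
    fst_weighted: float
    n_sites_used: int
    sum_a: float
    sum_abc: float


def _pop_site_stats(dosage: np.ndarray):
    """Per-site (n called, alt frequency, het frequency) for one population."""
    called = dosage != MISSING
    n = called.sum(axis=0).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, dosage, 0).sum(axis=0) / (2.0 * n)
        h = ((dosage == 1).sum(axis=0)) / n
    return n, p, h


def wc_fst_components(n1, p1, h1, n2, p2, h2):
    """Weir-Cockerham per-site variance components a, b, c for r = 2."""
    n1 = np.asarray(n1, dtype=np.float64)
    n2 = np.asarray(n2, dtype=np.float64)
    nbar = (n1 + n2) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = 2.0 * nbar - (n1 ** 2 + n2 ** 2) / (2.0 * nbar)
        pbar = (n1 * p1 + n2 * p2) / (2.0 * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
        hbar = (n1 * h1 + n2 * h2) / (2.0 * nbar)
        qterm = pbar * (1.0 - pbar) - s2 / 2.0
        a = nbar / nc * (s2 - (qterm - hbar / 4.0) / (nbar - 1.0))
        b = nbar / (nbar - 1.0) * (qterm - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
        c = hbar / 2.0
    return a, b, c


def wc_fst_pair(gm: GenotypeMatrix, pop_a, pop_b, name_a="A", name_b="B") -> FstResult:
    """Weighted Weir-Cockerham FST between two sample sets.

    ``pop_a`` / ``pop_b`` are sample-id iterables.  Sites need at least two
    called individuals in each population to be used; sites with a + b + c = 0
    (monomorphic overall) are excluded from both sums.
    """
    pop_a, pop_b = list(pop_a), list(pop_b)
    if not pop_a or not pop_b:
        raise ParameterError(f"empty population in FST pair {name_a}/{name_b}")
    da = gm.take_samples(pop_a).dosage
    db = gm.take_samples(pop_b).dosage
    n1, p1, h1 = _pop_site_stats(da)
    n2, p2, h2 = _pop_site_stats(db)
    usable = (n1 >= 2) & (n2 >= 2)
    if not usable.any():
        raise ParameterError(
            f"no usable sites for FST pair {name_a}/{name_b} after missingness"
        )
    a, b, c = wc_fst_components(n1, p1, h1, n2, p2, h2)
    abc = a + b + c
    use = usable & np.isfinite(abc) & (abc != 0.0)
    sum_a = float(a[use].sum())
    sum_abc = float(abc[use].sum())
    log.debug("wc_fst_pair %s/%s: %d of %d sites used",
              name_a, name_b, int(use.sum()), gm.n_sites)
    return FstResult(
        pop_a=name_a, pop_b=name_b,
        fst_weighted=sum_a / sum_abc,
        n_sites_used=int(use.sum()),
        sum_a=sum_a, sum_abc=sum_abc,
    )


def fst_matrix(gm: GenotypeMatrix, groups: list[PopulationGroup]) -> pd.DataFrame:
    """Symmetric matrix of pairwise weighted FST between groups."""
    if len(groups) < 2:
        raise ParameterError("fst_matrix needs at least two groups")
    names = [g.name for g in groups]
    mat = np.zeros((len(groups), len(groups)))
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            try:
                res = wc_fst_pair(gm, groups[i].samples, groups[j].samples,
                                  names[i], names[j])
            except ParameterError as exc:
                raise ParameterError(
                    f"FST failed for pair ({names[i]}, {names[j]}): {exc}"
                ) from exc
            mat[i, j] = mat[j, i] = res.fst_weighted
    return pd.DataFrame(mat, index=names, columns=names)


# ---------------------------------------------------------------------------
# Runs of homozygosity
# ---------------------------------------------------------------------------

ROH_COLUMNS = ["sample_id", "contig", "start", "end", "n_snps", "n_het_inside"]


def _moving_sum(x: np.ndarray, w: int) -> np.ndarray:
    c = np.concatenate([[0], np.cumsum(x)])
    return c[w:] - c[:-w]


def detect_roh(
    gm: GenotypeMatrix,
    window_snps: int = 50,
    max_het_per_window: int = 1,
    min_snps: int = 100,
    min_length_bp: int = 1_000_000,
    max_gap_bp: int = 100_000,
    min_density_bp_per_snp: int = 50_000,
) -> pd.DataFrame:
    """Sliding-window ROH caller.

    A window of ``window_snps`` consecutive sites passes when it contains at
    most ``max_het_per_window`` heterozygotes; a SNP votes homozygous when at
    least one window covering it passes.  Maximal runs of voting SNPs are
    split at inter-SNP gaps above ``max_gap_bp`` and reported as segments when
    they satisfy ``min_snps``, ``min_length_bp`` and the SNP-density ceiling
    ``min_density_bp_per_snp`` (bp per SNP).  Coordinates are 0-based
    half-open, spanning first to last SNP of the run.
    """
    segments = []
    contigs = gm.sites["contig"].to_numpy()
    pos_all = gm.sites["pos"].to_numpy()
    for contig in pd.unique(contigs):
        cmask = contigs == contig
        pos = pos_all[cmask]
        m = len(pos)
        if m < window_snps:
            continue
        dose = gm.dosage[:, cmask]
        for si, sample in enumerate(gm.samples):
            het = (dose[si] == 1).astype(np.int64)
            win_het = _moving_sum(het, window_snps)
            ok = win_het <= max_het_per_window
            # SNP k is covered by window starts max(0, k-w+1) .. min(k, m-w)
            vote = _moving_sum(
                np.concatenate([np.zeros(window_snps - 1, bool), ok,
                                np.zeros(window_snps - 1, bool)]).astype(np.int64),
                window_snps,
            ) > 0
            runs = _runs_of_true(vote)
            for r0, r1 in runs:
                for s0, s1 in _split_on_gaps(pos, r0, r1, max_gap_bp):
                    n_snps = s1 - s0
                    start, end = int(pos[s0]), int(pos[s1 - 1]) + 1
                    length = end - start
                    if (n_snps >= min_snps and length >= min_length_bp
                            and length / n_snps <= min_density_bp_per_snp):
                        segments.append(
                            (sample, contig, start, end, n_snps,
                             int(het[s0:s1].sum()))
                        )
    return pd.DataFrame(segments, columns=ROH_COLUMNS)


def _runs_of_true(mask: np.ndarray):
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts, ends))


def _split_on_gaps(pos: np.ndarray, r0: int, r1: int, max_gap_bp: int):
    """Split the half-open SNP-index run [r0, r1) at large physical gaps."""
    if r1 - r0 <= 1:
        yield r0, r1
        return
    gaps = np.flatnonzero(np.diff(pos[r0:r1]) > max_gap_bp) + r0 + 1
    bounds = [r0, *gaps, r1]
    for a, b in zip(bounds[:-1], bounds[1:]):
        yield a, b


def compute_froh(
    roh: pd.DataFrame, genome_bp: int, samples: list[str] | None = None
) -> pd.Series:
    """Per-sample fraction of the eligible genome covered by ROH segments."""
    if genome_bp <= 0:
        raise ParameterError(f"genome_bp must be positive, got {genome_bp}")
    lengths = (roh["end"] - roh["start"]).groupby(roh["sample_id"]).sum()
    if samples is not None:
        lengths = lengths.reindex(samples, fill_value=0)
    froh = lengths / genome_bp
    froh.name = "froh"
    return froh


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    scores: pd.DataFrame            # samples x components
    explained_variance: np.ndarray  # per-component variance
    explained_ratio: np.ndarray


def pca(gm: GenotypeMatrix, n_components: int = 10) -> PcaResult:
    """Genotype PCA with mean imputation and sqrt(p(1-p)) scaling.

    Missing dosages are imputed with the per-site mean; sites are centered
    and divided by sqrt(p(1-p)) where p is the alternate-allele frequency.
    Monomorphic sites are dropped.  Scores are U * S from the SVD of the
    standardized matrix, so per-component scores sum to ~0.
    """
    from .filtering import _imputed_dosage

    d = _imputed_dosage(gm)
    p = d.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    d = d[:, poly]
    p = p[poly]
    if d.shape[1] == 0:
        raise ParameterError("no polymorphic sites for PCA")
    z = (d - 2.0 * p) / np.sqrt(p * (1.0 - p))
    k = min(n_components, min(z.shape) - 1 if min(z.shape) > 1 else 1, z.shape[1])
    if k < n_components:
        log.warning("pca: reducing components from %d to %d", n_components, k)
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    scores = u[:, :k] * s[:k]
    var = (s ** 2) / (gm.n_samples - 1)
    cols = [f"PC{i + 1}" for i in range(k)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=gm.samples, columns=cols),
        explained_variance=var[:k],
        explained_ratio=var[:k] / var.sum(),
    )
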