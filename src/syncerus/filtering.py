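"""Genotype filtering, LD pruning, IBS distances and representative subsampling.

The filter chain mirrors the study design: per-genotype GQ masking first,
then site-level call-rate and minor-allele-frequency filters, then removal
of high-missingness samples.  The MAF filter is strict (maf > threshold).
Applying the chain twice is a no-op.
"""

from __future__ import annotations

import logging

import numpy as np
from skbio.stats.distance import DistanceMatrix
from skbio.stats.ordination import pcoa

from .containers import MISSING, GenotypeMatrix, ParameterError, PopulationGroup

log = logging.getLogger(__name__)


def _check_fraction(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ParameterError(f"{name} must be in [0, 1], got {value}")


def apply_site_filters(
    gm: GenotypeMatrix,
    min_gq: int | None = 30,
    min_call_rate: float = 0.9,
    min_maf: float = 0.05,
) -> GenotypeMatrix:
    """Mask low-GQ genotypes, then keep sites by call rate and MAF.

    Genotypes with GQ < ``min_gq`` are set missing *before* site statistics
    are computed.  A site is kept iff call_rate >= ``min_call_rate`` and
    maf > ``min_maf`` (strict).  Pass ``min_maf=0`` to keep all polymorphic
    and monomorphic sites alike, or ``min_gq=None`` to skip GQ masking.
    """
    _check_fraction("min_call_rate", min_call_rate)
    _check_fraction("min_maf", min_maf)
    if min_gq is not None and min_gq < 0:
        raise ParameterError(f"min_gq must be >= 0, got {min_gq}")

    if min_gq is not None and gm.gq is not None:
        mask = np.isfinite(gm.gq) & (gm.gq < min_gq)
        if mask.any():
            dosage = gm.dosage.copy()
            dosage[mask] = MISSING
            gm = GenotypeMatrix(
                samples=list(gm.samples),
                sites=gm.sites.reset_index(drop=True),
                dosage=dosage,
                gq=gm.gq,
                contig_lengths=dict(gm.contig_lengths),
            )
            log.info("apply_site_filters: masked %d genotypes with GQ < %s",
                     int(mask.sum()), min_gq)

    keep = (gm.sites["call_rate"].to_numpy() >= min_call_rate) & (
        gm.sites["maf"].to_numpy() > min_maf
    )
    out = gm.take_sites(keep)
    log.info("apply_site_filters: %d sites in, %d kept", gm.n_sites, out.n_sites)
    return out


def apply_sample_filter(gm: GenotypeMatrix, max_missing: float = 0.15) -> GenotypeMatrix:
    """Drop samples whose missing fraction exceeds ``max_missing``.

    Site statistics are recomputed on the surviving samples.
    """
    _check_fraction("max_missing", max_missing)
    rates = gm.sample_missing_rate()
    keep = rates <= max_missing
    if not keep.any():
        log.warning("apply_sample_filter: all %d samples removed", gm.n_samples)
    out = gm.take_samples(keep)
    log.info("apply_sample_filter: %d samples in, %d kept", gm.n_samples, out.n_samples)
    return out


def filter_chain(
    gm: GenotypeMatrix,
    min_gq: int | None = 30,
    min_call_rate: float = 0.9,
    min_maf: float = 0.05,
    max_missing: float = 0.15,
) -> GenotypeMatrix:
    """GQ mask -> site filters -> sample filter, in the study's order."""
    gm = apply_site_filters(gm, min_gq=min_gq, min_call_rate=min_call_rate,
                            min_maf=min_maf)
    return apply_sample_filter(gm, max_missing=max_missing)


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def _imputed_dosage(gm: GenotypeMatrix) -> np.ndarray:
    """Dosage as float with per-site mean imputation of missing calls."""
    d = gm.dosage.astype(np.float64)
    miss = gm.dosage == MISSING
    if miss.any():
        called = ~miss
        n = called.sum(axis=0)
        mean = np.where(n > 0, np.where(called, d, 0.0).sum(axis=0) / np.maximum(n, 1), 0.0)
        d = np.where(miss, mean[None, :], d)
    return d


def ld_prune(
    gm: GenotypeMatrix,
    window_snps: int = 5000,
    step_snps: int = 100,
    r2_max: float = 0.3,
) -> np.ndarray:
    """Greedy within-window LD pruning on composite dosage correlation.

    Windows of ``window_snps`` sites slide by ``step_snps``; within a window,
    whenever a retained pair has squared dosage correlation above ``r2_max``
    the later site is dropped.  Returns the sorted indices of retained sites.
    Pruning is contig-aware: pairs on different contigs are never compared.
    """
    if not (window_snps >= step_snps >= 1):
        raise ParameterError("need window_snps >= step_snps >= 1")
    _check_fraction("r2_max", r2_max)
    m = gm.n_sites
    if m <= 1:
        return np.arange(m)

    d = _imputed_dosage(gm)
    contigs = gm.sites["contig"].to_numpy()
    keep = np.ones(m, dtype=bool)
    for start in range(0, m, step_snps):
        stop = min(start + window_snps, m)
        idx = np.flatnonzero(keep[start:stop]) + start
        if len(idx) < 2:
            continue
        block = d[:, idx]
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(block, rowvar=False)
        r2 = np.nan_to_num(corr, nan=0.0) ** 2
        alive = np.ones(len(idx), dtype=bool)
        for a in range(len(idx)):
            if not alive[a]:
                continue
            for b in range(a + 1, len(idx)):
                if alive[b] and contigs[idx[a]] == contigs[idx[b]] and r2[a, b] > r2_max:
                    alive[b] = False
        keep[idx[~alive]] = False
        if stop == m:
            break
    return np.flatnonzero(keep)


# ---------------------------------------------------------------------------
# IBS distances and representative selection
# ---------------------------------------------------------------------------

def ibs_matrix(gm: GenotypeMatrix) -> np.ndarray:
    """Identity-by-state dissimilarity matrix in [0, 1].

    For a co-called site the shared-allele fraction is 1 for identical
    genotypes, 0.5 when one allele is shared and 0 for opposite homozygotes;
    the distance is one minus its mean.  Pairs with no co-called site get NaN.
    """
    if gm.n_samples < 2:
        raise ParameterError("ibs_matrix needs at least two samples")
    d = gm.dosage.astype(np.float64)
    called = gm.called().astype(np.float64)
    d0 = np.where(gm.called(), d, 0.0)
    # sum over co-called sites of |di - dj| via expansion: requires pair loop
    n = gm.n_samples
    out = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(d0[i][None, :] - d0[i + 1:, :])
        co = called[i][None, :] * called[i + 1:, :]
        num = (diff * co).sum(axis=1)
        den = co.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = np.where(den > 0, num / (2.0 * den), np.nan)
        out[i, i + 1:] = dist
        out[i + 1:, i] = dist
    return out


def _classical_mds(dist: np.ndarray, dims: int) -> np.ndarray:
    res = pcoa(DistanceMatrix(dist), number_of_dimensions=dims)
    coords = res.samples.to_numpy()[:, :dims]
    if coords.shape[1] < dims:  # degenerate geometry, pad with zeros
        pad = np.zeros((coords.shape[0], dims - coords.shape[1]))
        coords = np.hstack([coords, pad])
    return coords


def _k_medoids(coords: np.ndarray, k: int, rng: np.random.Generator,
               restarts: int = 100) -> np.ndarray:
    """Small PAM-style k-medoids with random restarts; returns medoid indices."""
    n = len(coords)
    dist = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    best_cost, best = np.inf, None
    for _ in range(restarts):
        medoids = rng.choice(n, size=k, replace=False)
        for _ in range(50):
            assign = np.argmin(dist[:, medoids], axis=1)
            new = medoids.copy()
            for c in range(k):
                members = np.flatnonzero(assign == c)
                if len(members):
                    within = dist[np.ix_(members, members)].sum(axis=1)
                    new[c] = members[np.argmin(within)]
            if np.array_equal(np.sort(new), np.sort(medoids)):
                break
            medoids = new
        cost = dist[np.arange(n), medoids[np.argmin(dist[:, medoids], axis=1)]].sum()
        if cost < best_cost - 1e-12:
            best_cost, best = cost, np.sort(medoids)
    return best


def select_representatives(
    gm: GenotypeMatrix,
    groups: list[PopulationGroup],
    target: int = 15,
    mds_dims: int = 2,
    min_call_rate: float = 0.99,
    min_maf: float = 0.3,
    max_markers: int = 10_000,
    seed: int = 0,
    restarts: int = 100,
) -> list[str]:
    """Per-group representative subsampling for even-sized analyses.

    Groups larger than ``target`` are reduced to exactly ``target`` samples:
    IBS distances on up to ``max_markers`` highly polymorphic, well-called
    markers are embedded by classical MDS and the ``target`` k-medoids of the
    embedding are returned, so the subset tracks the full group's centroid and
    dispersion.  Smaller groups are returned whole.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    qual = (gm.sites["call_rate"].to_numpy() >= min_call_rate) & (
        gm.sites["maf"].to_numpy() > min_maf
    )
    idx = np.flatnonzero(qual)
    if len(idx) < 10:
        raise ParameterError(
            f"only {len(idx)} markers pass call_rate >= {min_call_rate} and "
            f"maf > {min_maf}; need at least 10"
        )
    if len(idx) > max_markers:
        idx = np.sort(rng.choice(idx, size=max_markers, replace=False))
    marker_gm = gm.take_sites(idx)

    chosen: list[str] = []
    for grp in groups:
        if len(grp.samples) <= target:
            chosen.extend(grp.samples)
            continue
        sub = marker_gm.take_samples(grp.samples)
        dist = ibs_matrix(sub)
        if np.isnan(dist).any():
            raise ParameterError(
                f"group {grp.name!r}: undefined IBS distance (no co-called markers)"
            )
        coords = _classical_mds(dist, mds_dims)
        medoids = _k_medoids(coords, target, rng, restarts=restarts)
        chosen.extend(sub.samples[i] for i in medoids)
        log.info("select_representatives: group %s %d -> %d",
                 grp.name, len(grp.samples), target)
    return chosen
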