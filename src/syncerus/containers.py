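"""Core in-memory containers shared by the whole pipeline.

Genotypes are held as an allele-dosage matrix (samples x sites, values in
{0, 1, 2} counting copies of the alternate allele, ``MISSING`` = -1), with a
per-site table of contig/position/alleles and recomputed call rate and minor
allele frequency.  Phased data are held as a 0/1 haplotype matrix with two
rows per sample.  All coordinates are 0-based half-open internally; the
1-based convention applies only at VCF boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing diploid dosage.  Half-calls are collapsed onto it.
MISSING: int = -1

SITE_COLUMNS = ["contig", "pos", "ref", "alt", "call_rate", "maf"]


class FormatError(ValueError):
    """Malformed or contradictory input data (unsorted VCF, bad header...)."""


class ParameterError(ValueError):
    """A threshold or option outside its documented range."""


def make_site_table(contig, pos, ref, alt) -> pd.DataFrame:
    """Assemble a site table; call_rate/maf are filled in by the matrix."""
    df = pd.DataFrame(
        {
            "contig": np.asarray(contig, dtype=object),
            "pos": np.asarray(pos, dtype=np.int64),
            "ref": np.asarray(ref, dtype=object),
            "alt": np.asarray(alt, dtype=object),
        }
    )
    df["call_rate"] = np.nan
    df["maf"] = np.nan
    return df


def _check_sorted(sites: pd.DataFrame) -> None:
    contigs = sites["contig"].to_numpy()
    pos = sites["pos"].to_numpy()
    seen: dict[object, int] = {}
    last_contig = None
    for i in range(len(sites)):
        c = contigs[i]
        if c != last_contig:
            if c in seen:
                raise FormatError(
                    f"records for contig {c!r} are not contiguous "
                    f"(record {i}, {c}:{pos[i] + 1})"
                )
            seen[c] = i
            last_contig = c
        elif pos[i] <= pos[i - 1]:
            raise FormatError(
                f"unsorted or duplicate record at {c}:{pos[i] + 1} (record {i})"
            )


@dataclass
class GenotypeMatrix:
    """Diploid dosage matrix plus site and contig metadata.

    Attributes
    ----------
    samples : list of str
        Ordered sample identifiers (rows of ``dosage``).
    sites : pandas.DataFrame
        One row per site with columns ``contig, pos, ref, alt, call_rate, maf``,
        sorted by (contig, pos) and strictly increasing within a contig.
    dosage : ndarray of int8, shape (n_samples, n_sites)
        Alternate-allele counts; ``MISSING`` for no-calls.
    gq : ndarray of float32 or None
        Per-genotype Phred-scaled genotype qualities, same shape as ``dosage``,
        NaN where absent.
    contig_lengths : dict
        Length in bp of every contig the matrix may reference.
    """

    samples: list[str]
    sites: pd.DataFrame
    dosage: np.ndarray
    gq: np.ndarray | None = None
    contig_lengths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.samples), len(self.sites)):
            raise FormatError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        if len(self.sites):
            _check_sorted(self.sites)
        self.recompute_site_stats()

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def called(self) -> np.ndarray:
        """Boolean mask of non-missing genotypes."""
        return self.dosage != MISSING

    # -- statistics -----------------------------------------------------
    def recompute_site_stats(self) -> None:
        """Refresh per-site call_rate and minor allele frequency in place."""
        if self.n_sites == 0:
            return
        called = self.called()
        n_called = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            call_rate = n_called / max(self.n_samples, 1)
            alt = np.where(called, self.dosage, 0).sum(axis=0)
            p = np.where(n_called > 0, alt / (2.0 * np.maximum(n_called, 1)), np.nan)
        maf = np.minimum(p, 1.0 - p)
        self.sites = self.sites.copy()
        self.sites["call_rate"] = call_rate
        self.sites["maf"] = maf

    def sample_missing_rate(self) -> np.ndarray:
        """Fraction of sites missing per sample."""
        if self.n_sites == 0:
            return np.zeros(self.n_samples)
        return (~self.called()).sum(axis=1) / self.n_sites

    # -- subsetting -----------------------------------------------------
    def take_sites(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=self.sites.iloc[index].reset_index(drop=True),
            dosage=self.dosage[:, index],
            gq=None if self.gq is None else self.gq[:, index],
            contig_lengths=dict(self.contig_lengths),
        )

    def take_samples(self, which) -> "GenotypeMatrix":
        """Subset samples by boolean mask, integer index or id list."""
        which = list(which)
        if which and isinstance(which[0], str):
            lookup = {s: i for i, s in enumerate(self.samples)}
            idx = np.array([lookup[s] for s in which], dtype=int)
        else:
            idx = np.asarray(which)
            if idx.dtype == bool:
                idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            sites=self.sites.reset_index(drop=True),
            dosage=self.dosage[idx],
            gq=None if self.gq is None else self.gq[idx],
            contig_lengths=dict(self.contig_lengths),
        )


@dataclass
class HaplotypeMatrix:
    """Phased 0/1 haplotypes; rows ``2i`` and ``2i+1`` belong to sample ``i``."""

    haplotypes: np.ndarray
    sites: pd.DataFrame
    samples: list[str] | None = None
    contig_lengths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[0] % 2:
            raise FormatError("haplotype matrix needs an even number of rows")
        if self.haplotypes.shape[1] != len(self.sites):
            raise FormatError("haplotype columns do not match site table")
        if self.samples is None:
            self.samples = [f"S{i}" for i in range(self.haplotypes.shape[0] // 2)]

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def to_dosage(self) -> GenotypeMatrix:
        """Collapse haplotype pairs back onto a diploid dosage matrix."""
        dose = self.haplotypes[0::2].astype(np.int8) + self.haplotypes[1::2]
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=self.sites.reset_index(drop=True),
            dosage=dose,
            contig_lengths=dict(self.contig_lengths),
        )


@dataclass
class PopulationGroup:
    """A named set of samples with a geographic centroid."""

    name: str
    samples: list[str]
    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat <= 90.0 and -180.0 <= self.lon <= 180.0):
            raise ParameterError(
                f"group {self.name!r}: centroid ({self.lat}, {self.lon}) "
                "outside coordinate bounds"
            )


METADATA_COLUMNS = ["sample_id", "group", "subspecies", "lat", "lon"]


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Check a sample-metadata table (one row per sample, coords in bounds)."""
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"metadata missing columns: {missing}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"duplicate metadata record for sample {dup!r}")
    lat = meta["lat"].astype(float)
    lon = meta["lon"].astype(float)
    if (lat.abs() > 90).any() or (lon.abs() > 180).any():
        bad = meta.loc[(lat.abs() > 90) | (lon.abs() > 180), "sample_id"].iloc[0]
        raise ParameterError(f"sample {bad!r} has out-of-bounds coordinates")
    return meta


def build_groups(meta: pd.DataFrame) -> list[PopulationGroup]:
    """Population groups from metadata; centroid = mean of member coordinates."""
    validate_metadata(meta)
    groups = []
    for name, sub in meta.groupby("group", sort=True):
        groups.append(
            PopulationGroup(
                name=str(name),
                samples=list(sub["sample_id"]),
                lat=float(sub["lat"].astype(float).mean()),
                lon=float(sub["lon"].astype(float).mean()),
            )
        )
    return groups
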