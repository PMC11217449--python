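"""VCF and metadata I/O.

Reading goes through :mod:`cyvcf2`, writing through :mod:`pysam`.  Only
biallelic SNPs on contigs of at least ``min_contig_length`` bp survive
:func:`read_vcf`; everything else is tallied and logged.  Positions are
converted to 0-based half-open on the way in and back to 1-based on the way
out.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from cyvcf2 import VCF
import pysam

from .containers import (
    MISSING,
    FormatError,
    GenotypeMatrix,
    HaplotypeMatrix,
    make_site_table,
    validate_metadata,
)

log = logging.getLogger(__name__)

_BASES = frozenset("ACGT")


def _contig_lengths(vcf: VCF, path: str) -> dict:
    names = list(vcf.seqnames)
    try:
        lens = list(vcf.seqlens)
    except AttributeError as exc:  # header without contig lines
        raise FormatError(f"{path}: no contig lengths in header") from exc
    if len(names) != len(lens):
        raise FormatError(f"{path}: contradictory contig header")
    return dict(zip(names, (int(x) for x in lens)))


def _scan(path: str, min_contig_length: int, load_gq: bool):
    """Shared record scan: yields qualifying biallelic-SNP records."""
    vcf = VCF(str(path), gts012=False)
    lengths = _contig_lengths(vcf, str(path))
    samples = list(vcf.samples)
    keep_contig = {c for c, L in lengths.items() if L >= min_contig_length}

    tallies = {"total": 0, "multiallelic": 0, "indel": 0, "small_contig": 0, "kept": 0}
    contigs, pos, ref, alt, dosages, gqs = [], [], [], [], [], []
    last = (None, -1)
    for v in vcf:
        tallies["total"] += 1
        if v.CHROM == last[0] and v.POS <= last[1]:
            raise FormatError(
                f"{path}: unsorted record at {v.CHROM}:{v.POS} "
                f"(record {tallies['total']})"
            )
        if v.CHROM == last[0] or last[0] is None or True:
            last = (v.CHROM, v.POS)
        if len(v.ALT) != 1:
            tallies["multiallelic"] += 1
            continue
        if len(v.REF) != 1 or len(v.ALT[0]) != 1 or v.ALT[0] not in _BASES:
            tallies["indel"] += 1
            continue
        if v.CHROM not in keep_contig:
            tallies["small_contig"] += 1
            continue
        tallies["kept"] += 1
        contigs.append(v.CHROM)
        pos.append(v.POS - 1)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        g = np.array([gt[:2] for gt in v.genotypes], dtype=np.int16)
        dose = g.sum(axis=1).astype(np.int8)
        dose[(g < 0).any(axis=1)] = MISSING  # half-calls count as missing
        dosages.append(dose)
        if load_gq:
            q = np.asarray(v.gt_quals, dtype=np.float32).copy()
            q[q < 0] = np.nan
            gqs.append(q)
    vcf.close()
    log.info(
        "read_vcf %s: %d records, kept %d (dropped %d multiallelic, %d "
        "indel/non-SNP, %d on contigs < %d bp)",
        path, tallies["total"], tallies["kept"], tallies["multiallelic"],
        tallies["indel"], tallies["small_contig"], min_contig_length,
    )
    return samples, lengths, contigs, pos, ref, alt, dosages, gqs


def read_vcf(path, min_contig_length: int = 10_000, load_gq: bool = True) -> GenotypeMatrix:
    """Read a (possibly bgzipped) VCF into a :class:`GenotypeMatrix`.

    Only biallelic SNP records on contigs >= ``min_contig_length`` are kept.
    """
    samples, lengths, contigs, pos, ref, alt, dosages, gqs = _scan(
        str(path), min_contig_length, load_gq
    )
    sites = make_site_table(contigs, pos, ref, alt)
    n = len(samples)
    dosage = (
        np.stack(dosages, axis=1) if dosages else np.zeros((n, 0), dtype=np.int8)
    )
    gq = None
    if gqs and not all(np.isnan(q).all() for q in gqs):
        gq = np.stack(gqs, axis=1)
    return GenotypeMatrix(
        samples=samples, sites=sites, dosage=dosage, gq=gq, contig_lengths=lengths
    )


def read_vcf_haplotypes(path, min_contig_length: int = 10_000) -> HaplotypeMatrix:
    """Read a phased VCF into a :class:`HaplotypeMatrix`.

    Every genotype must be phased and fully called; anything else is a
    format error, since sweep statistics are undefined on unphased data.
    """
    vcf = VCF(str(path), gts012=False)
    lengths = _contig_lengths(vcf, str(path))
    samples = list(vcf.samples)
    contigs, pos, ref, alt, haps = [], [], [], [], []
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            continue
        if v.CHROM not in lengths or lengths[v.CHROM] < min_contig_length:
            continue
        col = np.empty(2 * len(samples), dtype=np.int16)
        for i, gt in enumerate(v.genotypes):
            a, b, phased = gt[0], gt[1], gt[2]
            if a < 0 or b < 0 or (not phased and a != b):
                raise FormatError(
                    f"{path}: unphased or missing genotype at {v.CHROM}:{v.POS} "
                    f"sample {samples[i]}"
                )
            col[2 * i] = a
            col[2 * i + 1] = b
        contigs.append(v.CHROM)
        pos.append(v.POS - 1)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        haps.append(col.astype(np.uint8))
    vcf.close()
    sites = make_site_table(contigs, pos, ref, alt)
    hmat = (
        np.stack(haps, axis=1)
        if haps
        else np.zeros((2 * len(samples), 0), dtype=np.uint8)
    )
    return HaplotypeMatrix(
        haplotypes=hmat, sites=sites, samples=samples, contig_lengths=lengths
    )


def _vcf_header(samples, contig_lengths, with_gq: bool) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contig_lengths.items():
        header.contigs.add(str(name), length=int(length))
    header.formats.add("GT", 1, "String", "Genotype")
    if with_gq:
        header.formats.add("GQ", 1, "Integer", "Genotype quality")
    for s in samples:
        header.add_sample(str(s))
    return header


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a genotype matrix as an uncompressed VCF 4.2 file."""
    with_gq = gm.gq is not None
    header = _vcf_header(gm.samples, gm.contig_lengths, with_gq)
    out = pysam.VariantFile(str(path), "w", header=header)
    sites = gm.sites
    for j in range(gm.n_sites):
        rec = out.new_record(
            contig=str(sites["contig"].iat[j]),
            start=int(sites["pos"].iat[j]),
            alleles=(str(sites["ref"].iat[j]), str(sites["alt"].iat[j])),
        )
        for i, s in enumerate(gm.samples):
            d = int(gm.dosage[i, j])
            rec.samples[s]["GT"] = (
                (None, None) if d == MISSING else ((0, 0), (0, 1), (1, 1))[d]
            )
            if with_gq and np.isfinite(gm.gq[i, j]):
                rec.samples[s]["GQ"] = int(gm.gq[i, j])
        out.write(rec)
    out.close()


def write_vcf_haplotypes(hm: HaplotypeMatrix, path) -> None:
    """Write phased haplotypes as a VCF with ``|``-separated genotypes."""
    header = _vcf_header(hm.samples, hm.contig_lengths, with_gq=False)
    out = pysam.VariantFile(str(path), "w", header=header)
    sites = hm.sites
    for j in range(hm.n_sites):
        rec = out.new_record(
            contig=str(sites["contig"].iat[j]),
            start=int(sites["pos"].iat[j]),
            alleles=(str(sites["ref"].iat[j]), str(sites["alt"].iat[j])),
        )
        for i, s in enumerate(hm.samples):
            rec.samples[s]["GT"] = (
                int(hm.haplotypes[2 * i, j]),
                int(hm.haplotypes[2 * i + 1, j]),
            )
            rec.samples[s].phased = True
        out.write(rec)
    out.close()


def read_metadata(path) -> pd.DataFrame:
    """Read a sample-metadata TSV (sample_id, group, subspecies, lat, lon)."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    return validate_metadata(meta)


def write_metadata(meta: pd.DataFrame, path) -> None:
    validate_metadata(meta).to_csv(path, sep="\t", index=False)
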