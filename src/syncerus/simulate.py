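"""Synthetic-truth generators for every pipeline stage.

Each generator is a pure function of its seed/config and emulates one aspect
of a continental population-genomic study: spatially structured diploid
genotypes (Balding-Nichols drift along a chain of demes), pedigrees with
known kinship, injected runs of homozygosity of known total fraction, phased
haplotypes with a hard sweep in one population, and a toy assembly with
analytically known novel-region classifications.

The Balding-Nichols step draws a deme's allele frequency from a Beta
distribution with mean equal to its neighbour's frequency and variance
F * p * (1 - p), so the expected Weir-Cockerham FST between demes one step
apart is F and differentiation accumulates with chain distance — the
isolation-by-distance structure of a continuous range, in miniature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    MISSING,
    GenotypeMatrix,
    HaplotypeMatrix,
    ParameterError,
    make_site_table,
)
from .intervals import IntervalSet
from .novel import AssemblyLayout


def _site_table_on_contig(contig: str, n_sites: int, length: int,
                          rng: np.random.Generator) -> pd.DataFrame:
    pos = np.sort(rng.choice(length, size=n_sites, replace=False))
    ref = np.full(n_sites, "A", dtype=object)
    alt = np.full(n_sites, "G", dtype=object)
    return make_site_table([contig] * n_sites, pos, ref, alt)


# ---------------------------------------------------------------------------
# Structured genotypes (stepping-stone Balding-Nichols chain)
# ---------------------------------------------------------------------------

@dataclass
class StructureConfig:
    n_demes: int = 6
    n_per_deme: int = 10
    n_sites: int = 500
    step_f: float = 0.015
    anc_range: tuple = (0.1, 0.9)
    deme_spacing_deg: float = 3.0   # demes on the equator, spaced in longitude
    contig: str = "1"
    contig_length: int = 50_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.step_f < 0.5):
            raise ParameterError(f"step_f must be in (0, 0.5), got {self.step_f}")
        lo, hi = self.anc_range
        if not (0.0 < lo < hi < 1.0):
            raise ParameterError(f"bad ancestral frequency range {self.anc_range}")
        if self.n_demes < 1 or self.n_per_deme < 1 or self.n_sites < 1:
            raise ParameterError("n_demes, n_per_deme and n_sites must be positive")


def _bn_step(p: np.ndarray, F: float, rng: np.random.Generator) -> np.ndarray:
    lam = (1.0 - F) / F
    return rng.beta(np.maximum(p * lam, 1e-9), np.maximum((1.0 - p) * lam, 1e-9))


def sim_structured_genotypes(cfg: StructureConfig):
    """Genotypes from a chain of demes with per-step Balding-Nichols drift.

    Returns (GenotypeMatrix, metadata DataFrame, per-deme frequency array of
    shape (n_demes, n_sites)).
    """
    rng = np.random.default_rng(cfg.seed)
    p_anc = rng.uniform(*cfg.anc_range, size=cfg.n_sites)
    freqs = np.empty((cfg.n_demes, cfg.n_sites))
    # serial chain with per-step Beta variance 2*step_f*p(1-p): the drift
    # between adjacent demes splits evenly between them, so their expected
    # Weir-Cockerham FST is step_f (the classic two-population model with
    # each deme drifting step_f from the shared ancestor), differentiation
    # accumulates linearly with chain distance, and the FST-vs-distance
    # relation passes through the origin
    prev = p_anc
    for d in range(cfg.n_demes):
        prev = _bn_step(prev, 2.0 * cfg.step_f, rng)
        freqs[d] = prev

    sites = _site_table_on_contig(cfg.contig, cfg.n_sites, cfg.contig_length, rng)
    samples, groups, lons, dose_rows = [], [], [], []
    for d in range(cfg.n_demes):
        g = rng.binomial(2, freqs[d], size=(cfg.n_per_deme, cfg.n_sites))
        dose_rows.append(g.astype(np.int8))
        for i in range(cfg.n_per_deme):
            samples.append(f"deme{d}_s{i}")
            groups.append(f"deme{d}")
            lons.append(cfg.deme_spacing_deg * d)
    gm = GenotypeMatrix(
        samples=samples,
        sites=sites,
        dosage=np.vstack(dose_rows),
        contig_lengths={cfg.contig: cfg.contig_length},
    )
    meta = pd.DataFrame(
        {
            "sample_id": samples,
            "group": groups,
            "subspecies": ["sim"] * len(samples),
            "lat": 0.0,
            "lon": lons,
        }
    )
    return gm, meta, freqs


# ---------------------------------------------------------------------------
# Pedigrees with known kinship
# ---------------------------------------------------------------------------

EXPECTED_PHI = {
    "duplicate": 0.5,
    "parent_offspring": 0.25,
    "full_sib": 0.25,
    "half_sib": 0.125,
    "first_cousin": 0.0625,
    "unrelated": 0.0,
}


def sim_pedigree(
    n_sites: int = 50_000,
    freq_range: tuple = (0.1, 0.9),
    n_unrelated: int = 4,
    seed: int = 0,
    contig: str = "1",
    contig_length: int = 100_000_000,
):
    """Founder/offspring genotypes with a truth table of pedigree kinship.

    Builds one exemplar pair of each relationship class (duplicate,
    parent-offspring, full sibs, half sibs, first cousins) plus
    ``n_unrelated`` extra founders, all segregating the same Hardy-Weinberg
    founder frequencies with independent Mendelian transmission per site.

    Returns (GenotypeMatrix, truth DataFrame with sample_i/sample_j/
    relationship/expected_phi rows for the constructed pairs).
    """
    rng = np.random.default_rng(seed)
    p = rng.uniform(*freq_range, size=n_sites)

    def founder():
        return rng.random((2, n_sites)) < p  # two haplotypes

    def child(pa, pb):
        ha = np.where(rng.random(n_sites) < 0.5, pa[0], pa[1])
        hb = np.where(rng.random(n_sites) < 0.5, pb[0], pb[1])
        return np.stack([ha, hb])

    people: dict[str, np.ndarray] = {}
    truth = []

    def add(name, hap):
        people[name] = hap

    # duplicate pair
    f = founder(); add("dup_a", f); add("dup_b", f.copy())
    truth.append(("dup_a", "dup_b", "duplicate", 0.5))
    # parent-offspring
    pa, pb = founder(), founder()
    add("po_parent", pa); kid = child(pa, pb); add("po_child", kid)
    truth.append(("po_parent", "po_child", "parent_offspring", 0.25))
    # full sibs
    sa, sb = founder(), founder()
    add("fs_1", child(sa, sb)); add("fs_2", child(sa, sb))
    truth.append(("fs_1", "fs_2", "full_sib", 0.25))
    # half sibs (shared father, different mothers)
    dad, m1, m2 = founder(), founder(), founder()
    add("hs_1", child(dad, m1)); add("hs_2", child(dad, m2))
    truth.append(("hs_1", "hs_2", "half_sib", 0.125))
    # first cousins: sibling parents
    g1, g2 = founder(), founder()
    par1, par2 = child(g1, g2), child(g1, g2)
    add("fc_1", child(par1, founder())); add("fc_2", child(par2, founder()))
    truth.append(("fc_1", "fc_2", "first_cousin", 0.0625))
    # extra unrelated founders
    for i in range(n_unrelated):
        add(f"unrel_{i}", founder())
    for i in range(n_unrelated):
        for j in range(i + 1, n_unrelated):
            truth.append((f"unrel_{i}", f"unrel_{j}", "unrelated", 0.0))

    samples = list(people)
    dosage = np.stack([people[s].sum(axis=0).astype(np.int8) for s in samples])
    sites = _site_table_on_contig(contig, n_sites, contig_length, rng)
    gm = GenotypeMatrix(samples=samples, sites=sites, dosage=dosage,
                        contig_lengths={contig: contig_length})
    truth_df = pd.DataFrame(
        truth, columns=["sample_i", "sample_j", "relationship", "expected_phi"]
    )
    return gm, truth_df


# ---------------------------------------------------------------------------
# ROH injection
# ---------------------------------------------------------------------------

def inject_roh(
    gm: GenotypeMatrix,
    fraction: float,
    min_tract_bp: int = 1_000_000,
    seed: int = 0,
    samples: list[str] | None = None,
):
    """Overwrite tracts totalling ``fraction`` of the genome with homozygosity.

    Within each tract one of the sample's two alleles is copied over the
    other (heterozygotes become a random homozygote, homozygotes stay), which
    is what autozygosity does.  Tracts are non-overlapping and at least
    ``min_tract_bp`` long.  Returns (new GenotypeMatrix, truth BED DataFrame
    with sample_id/contig/start/end).
    """
    if not (0.0 <= fraction <= 1.0):
        raise ParameterError(f"fraction must be in [0,1], got {fraction}")
    rng = np.random.default_rng(seed)
    dosage = gm.dosage.copy()
    targets = samples if samples is not None else list(gm.samples)
    idx = {s: i for i, s in enumerate(gm.samples)}
    contigs = gm.sites["contig"].to_numpy()
    pos = gm.sites["pos"].to_numpy()
    truth = []
    for s in targets:
        si = idx[s]
        for contig, L in gm.contig_lengths.items():
            target = fraction * L
            if target <= 0:
                continue
            if fraction >= 1.0:
                tracts = [(0, L)]
            else:
                if target < min_tract_bp:
                    raise ParameterError(
                        f"fraction {fraction} infeasible: target {target:.0f} bp "
                        f"< min_tract_bp {min_tract_bp} on contig {contig}"
                    )
                # equal tract lengths, each >= min_tract_bp, summing to target
                k = max(1, int(target // (1.5 * min_tract_bp)))
                base = int(target / k)
                lengths = [base] * (k - 1) + [int(target) - base * (k - 1)]
                free = L - sum(lengths)
                if free < 0:
                    raise ParameterError("fraction infeasible given min_tract_bp")
                gaps = rng.dirichlet(np.ones(len(lengths) + 1)) * free
                tracts, cursor = [], 0.0
                for g, ln in zip(gaps, lengths):
                    cursor += g
                    tracts.append((int(cursor), int(cursor) + ln))
                    cursor += ln
            cmask = contigs == contig
            for start, end in tracts:
                smask = cmask & (pos >= start) & (pos < end)
                cols = np.flatnonzero(smask)
                het = cols[dosage[si, cols] == 1]
                dosage[si, het] = 2 * (rng.random(len(het)) < 0.5)
                truth.append((s, contig, start, end))
    out = GenotypeMatrix(
        samples=list(gm.samples), sites=gm.sites.reset_index(drop=True),
        dosage=dosage, gq=gm.gq, contig_lengths=dict(gm.contig_lengths),
    )
    return out, pd.DataFrame(truth, columns=["sample_id", "contig", "start", "end"])


def sim_panmictic(
    n_samples: int = 4,
    n_sites: int = 10_000,
    contig: str = "1",
    contig_length: int = 20_000_000,
    freq_range: tuple = (0.2, 0.8),
    seed: int = 0,
    evenly_spaced: bool = True,
) -> GenotypeMatrix:
    """One Hardy-Weinberg population; the substrate for ROH injection."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(*freq_range, size=n_sites)
    if evenly_spaced:
        step = contig_length // (n_sites + 1)
        pos = np.arange(1, n_sites + 1) * step
        sites = make_site_table([contig] * n_sites, pos,
                                ["A"] * n_sites, ["G"] * n_sites)
    else:
        sites = _site_table_on_contig(contig, n_sites, contig_length, rng)
    dosage = rng.binomial(2, p, size=(n_samples, n_sites)).astype(np.int8)
    return GenotypeMatrix(
        samples=[f"S{i}" for i in range(n_samples)], sites=sites, dosage=dosage,
        contig_lengths={contig: contig_length},
    )


# ---------------------------------------------------------------------------
# Sweep haplotypes
# ---------------------------------------------------------------------------

@dataclass
class SweepConfig:
    n_haplotypes: int = 50        # per population
    n_sites: int = 1500
    contig: str = "1"
    contig_length: int = 3_000_000
    core_pos: int = 1_500_000
    beta: float = 0.4             # carrier fraction in the swept population
    sweep_tract_bp: int = 400_000
    n_founders: int = 20
    switch_rate_per_bp: float = 1e-4
    mutation_rate: float = 0.002  # per site per haplotype
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.beta <= 1.0):
            raise ParameterError(f"beta must be in [0,1], got {self.beta}")
        if not (0 <= self.core_pos < self.contig_length):
            raise ParameterError("core position outside contig")


def _mosaic_pop(n_hap, founders, pos, switch_rate, mu, rng):
    n_founders, m = founders.shape
    H = np.empty((n_hap, m), dtype=np.uint8)
    gaps = np.diff(pos)
    p_switch = 1.0 - np.exp(-switch_rate * gaps)
    cols = np.arange(m)
    for h in range(n_hap):
        switches = rng.random(m - 1) < p_switch
        seg = np.concatenate([[0], np.cumsum(switches)])
        draws = rng.integers(n_founders, size=seg[-1] + 1)
        H[h] = founders[draws[seg], cols]
    flips = rng.random(H.shape) < mu
    H ^= flips.astype(np.uint8)
    return H


def sim_sweep_pair(cfg: SweepConfig):
    """Two phased populations, one carrying a hard sweep at a known core.

    Both populations are copying mosaics of shared founder haplotypes with
    switch and mutation noise.  In population A, a fraction ``beta`` of
    haplotypes carry founder 0's sequence across a tract around the core
    whose half-length is exponential with mean ``sweep_tract_bp / 2`` per
    side (identity eroding with distance).  With ``beta = 0`` the populations
    are exchangeable.

    Returns (haps_a, haps_b, truth dict with core_bp, core_index, beta,
    carrier row indices).
    """
    rng = np.random.default_rng(cfg.seed)
    step = cfg.contig_length // (cfg.n_sites + 1)
    pos = np.arange(1, cfg.n_sites + 1) * step
    founder_freq = rng.uniform(0.2, 0.8, size=cfg.n_sites)
    founders = (rng.random((cfg.n_founders, cfg.n_sites)) < founder_freq).astype(np.uint8)

    A = _mosaic_pop(cfg.n_haplotypes, founders, pos, cfg.switch_rate_per_bp,
                    cfg.mutation_rate, rng)
    B = _mosaic_pop(cfg.n_haplotypes, founders, pos, cfg.switch_rate_per_bp,
                    cfg.mutation_rate, rng)

    core_index = int(np.argmin(np.abs(pos - cfg.core_pos)))
    core_bp = int(pos[core_index])
    n_carriers = int(round(cfg.beta * cfg.n_haplotypes))
    carriers = rng.choice(cfg.n_haplotypes, size=n_carriers, replace=False)
    for h in carriers:
        left = rng.exponential(cfg.sweep_tract_bp / 2.0)
        right = rng.exponential(cfg.sweep_tract_bp / 2.0)
        tract = (pos >= core_bp - left) & (pos <= core_bp + right)
        A[h, tract] = founders[0, tract]

    sites = make_site_table([cfg.contig] * cfg.n_sites, pos,
                            ["A"] * cfg.n_sites, ["G"] * cfg.n_sites)
    lengths = {cfg.contig: cfg.contig_length}
    haps_a = HaplotypeMatrix(
        haplotypes=A, sites=sites.copy(),
        samples=[f"A{i}" for i in range(cfg.n_haplotypes // 2)]
        if cfg.n_haplotypes % 2 == 0 else None,
        contig_lengths=lengths,
    )
    haps_b = HaplotypeMatrix(
        haplotypes=B, sites=sites.copy(),
        samples=[f"B{i}" for i in range(cfg.n_haplotypes // 2)]
        if cfg.n_haplotypes % 2 == 0 else None,
        contig_lengths=lengths,
    )
    truth = {
        "core_bp": core_bp,
        "core_index": core_index,
        "beta": cfg.beta,
        "carriers": np.sort(carriers),
    }
    return haps_a, haps_b, truth


# ---------------------------------------------------------------------------
# Toy assembly fixture for the novel-region pipeline
# ---------------------------------------------------------------------------

@dataclass
class ToyAssemblyFixture:
    layout: AssemblyLayout
    raw_intervals: pd.DataFrame       # pre-merge presence-absence intervals
    novelty: IntervalSet              # per-base novelty track
    genes: pd.DataFrame               # contig/start/end/name
    gene_terms: pd.DataFrame          # gene_id/term_id/term_kind
    reads_by_sample: dict
    truth_regions: pd.DataFrame       # expected post-merge classification
    truth_retained: list              # expected retained (contig,start,end)
    truth_contained_genes: set
    truth_overlapping_genes: set
    truth_top_term: str
    truth_depth: dict                 # n_low_depth / n_zero_reads


def make_toy_assembly_fixture(seed: int = 0) -> ToyAssemblyFixture:
    """A small assembly whose novel-region truth is known by construction.

    Three scaffolds (one above the 5 Mb telomere-eligibility threshold),
    planted N-gaps and repeat mask, presence intervals covering every
    length/position/type combination, genes inside and straddling retained
    regions, and a term table loading one GO term onto the contained genes.
    All expectations are derived analytically while building, never by
    running the classifier.
    """
    # deterministic by construction; seed kept for interface uniformity
    del seed
    scaffolds = {"scaf1": 6_000_000, "scaf2": 2_000_000, "scaf3": 300_000}
    gaps = pd.DataFrame(
        [("scaf1", 2_000_000, 2_000_500), ("scaf2", 1_000_000, 1_000_200)],
        columns=["contig", "start", "end"],
    )
    mask = pd.DataFrame(
        [("scaf1", 3_300_000, 3_300_100)], columns=["contig", "start", "end"]
    )

    # (contig, start, end, pct_novel_target, note)
    planted = [
        ("scaf1", 3_000_000, 3_000_005, 100.0, "short interior novel"),
        ("scaf1", 3_100_000, 3_100_040, 100.0, "intermediate interior novel"),
        ("scaf1", 3_200_000, 3_200_060, 100.0, "length-60 boundary intermediate"),
        ("scaf1", 3_300_000, 3_300_200, 100.0, "large interior novel -> retained"),
        ("scaf1", 5_000, 5_200, 100.0, "large telomeric -> dropped"),
        ("scaf1", 2_000_700, 2_000_900, 100.0, "large gap-flanking -> dropped"),
        ("scaf1", 3_400_000, 3_400_500, 94.0, "large interior haplotype -> retained"),
        ("scaf1", 3_500_000, 3_500_300, 40.0, "large interior low-novelty -> dropped"),
        ("scaf2", 8_000, 8_150, 100.0, "large near-end of small scaffold -> retained"),
    ]
    # merge-rule probes: gap of 3 bp (merges into one 197 bp region) and a
    # gap of exactly 5 bp (stays two large regions)
    raw_extra = [
        ("scaf1", 3_600_000, 3_600_100), ("scaf1", 3_600_103, 3_600_200),
        ("scaf1", 3_700_000, 3_700_080), ("scaf1", 3_700_085, 3_700_165),
    ]
    raw = pd.DataFrame(
        [(c, s, e) for c, s, e, *_ in planted] + raw_extra,
        columns=["contig", "start", "end"],
    )

    # novelty track: full coverage except the two partial regions
    novelty_rows = []
    for c, s, e, pct, _ in planted:
        novel_bases = int(round((e - s) * pct / 100.0))
        novelty_rows.append((c, s, s + novel_bases))
    for c, s, e in raw_extra:
        novelty_rows.append((c, s, e))
    novelty = IntervalSet(
        pd.DataFrame(novelty_rows, columns=["contig", "start", "end"]),
        contigs=scaffolds,
    )

    # analytic truth for the post-merge classification
    def expect(c, s, e, pct):
        L = scaffolds[c]
        length = e - s
        lc = "short" if length < 10 else ("intermediate" if length <= 60 else "large")
        telo = L > 5_000_000 and (s < 10_000 or L - e < 10_000)
        gapf = any(
            gc == c and s - 1_000 < ge and gs < e + 1_000
            for gc, gs, ge in gaps.itertuples(index=False)
        )
        tc = "novel" if pct > 95.0 else "haplotype"
        return (c, s, e, length, lc, telo, gapf, tc, pct)

    truth_rows = [expect(c, s, e, pct) for c, s, e, pct, _ in planted]
    merged_a = ("scaf1", 3_600_000, 3_600_200)  # 3 bp gap bridged
    truth_rows.append(expect(*merged_a, 100.0 * 197 / 200))  # bridged bases not novel
    truth_rows.append(expect("scaf1", 3_700_000, 3_700_080, 100.0))
    truth_rows.append(expect("scaf1", 3_700_085, 3_700_165, 100.0))
    truth_regions = pd.DataFrame(
        truth_rows,
        columns=["contig", "start", "end", "length", "length_class",
                 "telomeric", "gap_flanking", "type_class", "pct_novel"],
    ).sort_values(["contig", "start"]).reset_index(drop=True)

    truth_retained = sorted(
        (r.contig, r.start, r.end)
        for r in truth_regions.itertuples()
        if r.length_class == "large" and r.pct_novel >= 50.0
        and not r.telomeric and not r.gap_flanking
    )

    # genes: inside retained regions, straddling one, and background
    genes_rows = [
        ("scaf1", 3_300_050, 3_300_150, "g_contained_1"),
        ("scaf1", 3_400_100, 3_400_300, "g_contained_2"),
        ("scaf1", 3_600_020, 3_600_180, "g_contained_3"),
        ("scaf2", 8_020, 8_120, "g_contained_4"),
        ("scaf1", 3_300_100, 3_300_400, "g_straddle"),
    ]
    for i in range(12):
        genes_rows.append(("scaf1", 4_000_000 + 10_000 * i,
                           4_000_500 + 10_000 * i, f"g_bg_{i}"))
    genes = pd.DataFrame(genes_rows, columns=["contig", "start", "end", "name"])
    truth_contained = {"g_contained_1", "g_contained_2", "g_contained_3",
                       "g_contained_4"}
    truth_overlap = truth_contained | {"g_straddle"}

    # terms: GO:TEST01 loads onto 3 of 4 contained genes but only 1 of 12
    # background genes -> the designed minimum-p term; KEGG:TEST99 is a
    # common background pathway (not enriched)
    term_rows = [
        ("g_contained_1", "GO:TEST01", "GO"),
        ("g_contained_2", "GO:TEST01", "GO"),
        ("g_contained_3", "GO:TEST01", "GO"),
        ("g_contained_4", "GO:TEST02", "GO"),
        ("g_contained_4", "KEGG:TEST99", "KEGG"),
        ("g_bg_0", "GO:TEST01", "GO"),
        ("g_straddle", "GO:TEST02", "GO"),
    ]
    for i in range(6):
        term_rows.append((f"g_bg_{i}", "KEGG:TEST99", "KEGG"))
    for i in range(6, 12):
        term_rows.append((f"g_bg_{i}", "GO:TEST03", "GO"))
    gene_terms = pd.DataFrame(term_rows, columns=["gene_id", "term_id", "term_kind"])

    # reads: two samples; every retained region covered twice except the
    # scaf2 region, which has no reads at all
    reads = []
    for c, s, e in truth_retained:
        if c == "scaf2":
            continue
        reads.append((c, max(0, s - 50), e + 50))
    reads_by_sample = {
        "wgs1": pd.DataFrame(reads, columns=["contig", "start", "end"]),
        "wgs2": pd.DataFrame(reads, columns=["contig", "start", "end"]),
    }
    truth_depth = {"n_low_depth": 1, "n_zero_reads": 1}

    layout = AssemblyLayout(
        scaffold_lengths=scaffolds,
        gaps=IntervalSet(gaps, contigs=scaffolds),
        repeat_mask=IntervalSet(mask, contigs=scaffolds),
    )
    return ToyAssemblyFixture(
        layout=layout,
        raw_intervals=raw,
        novelty=novelty,
        genes=genes,
        gene_terms=gene_terms,
        reads_by_sample=reads_by_sample,
        truth_regions=truth_regions,
        truth_retained=truth_retained,
        truth_contained_genes=truth_contained,
        truth_overlapping_genes=truth_overlap,
        truth_top_term="GO:TEST01",
        truth_depth=truth_depth,
    )
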