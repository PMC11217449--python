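"""Runs of homozygosity and FROH on genotypes with injected tracts.

Injects homozygous tracts covering 30% of a 20 Mb contig, detects them with
the sliding-window ROH caller and reports FROH (fraction of the genome in
runs of homozygosity, a genomic inbreeding measure).
"""

import syncerus as sy

gm = sy.sim_panmictic(n_samples=3, n_sites=10_000, contig_length=20_000_000,
                      seed=3)
gm_roh, truth = sy.inject_roh(gm, fraction=0.3, seed=4)

segments = sy.detect_roh(gm_roh)
froh = sy.compute_froh(segments, genome_bp=20_000_000, samples=gm_roh.samples)

print(f"{len(segments)} ROH segments detected "
      f"({len(truth)} tracts injected)")
print("\nper-sample FROH (truth = 0.30):")
print(froh.round(3).to_string())
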