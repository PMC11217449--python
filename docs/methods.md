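# Methods

This note documents the statistical models the package implements, the
synthetic-data generators used to test them, the default parameters and the
reasoning behind the genuinely open design choices.

## Genotype filtering

Filters are applied in a fixed order: per-genotype GQ masking (GQ < 30 →
missing), then site filters (call rate ≥ 0.9, minor allele frequency
strictly > 0.05), then removal of samples with > 15% missingness; site
statistics are recomputed after each stage, so the chain is idempotent.
Half-calls are treated as missing. Missingness is computed after GQ
masking; the alternative order is available by passing `min_gq=None` and
masking separately. All coordinates are 0-based half-open internally and
1-based only at VCF boundaries.

LD pruning computes composite (dosage) correlation in sliding windows
defined in SNP counts (5000-SNP windows stepping by 100, r² > 0.3), with
the earlier site winning ties — the convention of the standard pruning
tools. Mean imputation stands in for missing dosages in the correlation,
as in those tools.

Representative downsampling reduces every group larger than the target
(default 15) to exactly the target: IBS dissimilarities on up to 10,000
markers with call rate ≥ 0.99 and MAF > 0.3 are embedded by classical MDS
(two dimensions, via principal coordinates analysis) and the k-medoids of
the embedding are returned. The published pipeline delegates this step to
an external package documented only by its option values; k-medoids over
the MDS embedding is this package's own deterministic construction of "a
subset whose structure reflects the total set", with restarts (default
100) driven by the seed. It is a declared substitute, not a
reconstruction of that tool's internals.

## Kinship

The KING-robust estimator is used exactly as defined:
φ = (N_Aa,Aa − 2·N_AA,aa) / (N_Aa(i) + N_Aa(j)), counts restricted to sites
co-called in both samples. It is robust to population structure because it
never uses sample-level allele frequencies. Pruning keeps pairs with
φ < 0.0625 (strictly below the third-degree lower bound, so "fourth degree
or greater" is kept), removing greedily the sample with the most
over-cutoff partners; ties break toward lower call rate, then the
lexically larger id. Greedy max-degree removal is deterministic and
near-optimal; an exact maximum independent set would be NP-hard for no
practical gain. Kinship is computed on well-called biallelic sites before
MAF filtering, the usual practice for relatedness tools.

## F_ST, ROH, PCA

F_ST uses the Weir & Cockerham (1984) two-population variance components.
Per usable site (≥ 2 called individuals in each population) the
among-population (a), among-individual (b) and within-individual (c)
components are computed from sample sizes, allele frequencies and observed
heterozygote frequencies, and combined across sites as Σa / Σ(a+b+c) — the
ratio of sums, which is consistent, unlike the mean of per-site ratios.
Sites with a+b+c = 0 (monomorphic) drop out of both sums, so adding
monomorphic sites never changes the estimate.

The ROH caller is a PLINK-style sliding window scan: 50-SNP windows pass
with at most one heterozygote; a SNP votes homozygous when any covering
window passes; maximal runs of voting SNPs are split at > 100 kb gaps and
reported when they have ≥ 100 SNPs, span ≥ 1 Mb and average at most
50 kb/SNP. The source study does not state its ROH method, so these
conventional defaults are used and fully exposed; F_ROH comparisons are
meaningful under any fixed parameterization, and the package's tests
validate recovery of injected tract fractions (0.1/0.3/0.6 within ±0.02)
rather than agreement with any particular published F_ROH value.

PCA mean-imputes missing dosages, centers each site and scales by
1/√(p(1−p)); scores are U·S of the SVD, so they are exactly centered.

## Isolation by distance

Centroid distances use the Haversine formula with Earth radius 6371.0 km.
The Mantel statistic is the Pearson correlation of the strict upper
triangles; the null jointly permutes rows and columns of the second
matrix. The sampled p-value is (#extreme + 1)/(n_perm + 1); for matrices
small enough (n! ≤ n_perm) the test switches to exact enumeration over all
relabelings. The default is two-sided with 9999 permutations; a one-sided
alternative is a flag. Pair classes follow the study design (forest-
buffalo pairs, bottleneck-population pairs, their single mutual pair, and
the rest, with the mutual pair taking precedence), and per-class OLS of
F_ST on distance reports a two-sided *t*-test of the intercept. The two
supplementary-data quantities of the source study (Mantel r over the nine
deposited groups and after excluding the two flagged groups) require the
deposited tables; the same code path (`ibd_from_tables`) runs on any
FST-matrix TSV plus metadata TSV, and is exercised end-to-end on the
synthetic stepping-stone replica.

## Sweep scan

EHH at distance x from a core is Σ_g C(n_g,2)/C(n,2) over groups of
haplotypes identical on the whole interval between core and x. Two
variants exist: the allele-conditional profile (carriers of one core
allele; EHH = 1 at the core) and the whole-sample site EHH whose initial
partition is the core alleles — the latter is what iES integrates for the
cross-population statistic. Profiles truncate below EHH = 0.05 and at 2 cM
of extension (conventional; both configurable), and the genetic map is a
constant 1 cM/Mb unless a map is supplied. iES is the trapezoidal integral
over genetic distance, both directions summed; XP-EHH is ln(iES_A/iES_B),
standardized to zero mean and unit variance over scored sites genome-wide
(no frequency binning). Sites monomorphic in either population are
skipped.

Peak calling smooths the standardized score with a sliding (step 1 SNP)
1000-SNP window mean; a peak is a maximal run of windows with
|smoothed| ≥ 2 containing at least one window with |smoothed| > 4, its
boundaries the outermost SNPs of the boundary windows, with bp-overlapping
runs merged. Sliding windows (rather than disjoint) make the "fell back
below 2" boundary well defined at SNP resolution, and the exit test uses
the smoothed track for consistency with the entry test; both choices are
config-exposed because the convention is not uniquely determined.

## Novel-sequence classification

Presence-absence intervals separated by < 5 bp are merged (a gap of
exactly 5 bp is not). Regions are annotated by length (short < 10 bp,
intermediate 10–60 bp inclusive, large > 60 bp — length exactly 60 is
excluded by the "longer than 60 bp" retention rule), position (telomeric
iff < 10 kb from either end of a scaffold > 5 Mb; gap-flanking iff < 1 kb
from an N-gap), sequence type (novel iff > 95% of bases occur in no other
genome, divergent haplotype otherwise) and repeat-masked percentage.
Retention keeps large regions with ≥ 50% novel bases that are neither
telomeric nor gap-flanking; a flag inverts the positional condition for
inspection of the flagged complement. Novelty percentages are computed
after merging. Depth validation counts regions whose cross-sample mean
read depth is < 1 and regions with no reads at all. Enrichment is a
two-sided binomial test per term of the foreground count against the
background term frequency (genes with at least one annotated term only;
foreground and background disjoint), with add-one smoothing and a flag for
terms absent from the background, and Benjamini–Hochberg correction across
all tested terms.

## Synthetic-data generators

All generators are pure functions of seed and config.

**Stepping-stone genotypes.** Deme frequencies form a serial chain of
Balding–Nichols steps: each deme's frequency is Beta-distributed around
its neighbour's with variance 2F·p(1−p). The factor 2 calibrates the
parameter to the quantity of interest: the drift between adjacent demes
splits evenly between them, so their expected Weir–Cockerham F_ST is F
(equivalently, each of the two demes drifts F from their midpoint — the
classic two-population Balding–Nichols setting), differentiation grows
~linearly with chain distance, and the F_ST-versus-distance relation
passes through the origin, which is what an isolation-by-distance test
needs. Defaults describe the in-silico study condition: 6 demes spaced 3°
along the equator, 10 diploids per deme, a 500-SNP panel (an LD-pruned
sparse panel; with per-step F = 0.015 the pairwise F_ST range ≈
0.015–0.075, comparable to the continental study's span for
non-bottlenecked populations). With many more sites the estimator becomes
so precise that the slight concavity of compounded drift
(1−(1−2F)^k) is statistically detectable as a nonzero intercept; the
500-site panel represents the realistic regime in which estimator noise
dominates that higher-order curvature.

**Pedigrees.** Founders are Hardy–Weinberg draws from uniform(0.1, 0.9)
frequencies; children inherit one allele per parent independently per site
(no linkage — irrelevant for expected kinship, which is a per-site IBD
probability). One exemplar pair of each class is built: duplicate (φ =
0.5), parent–offspring and full sibs (0.25), half sibs (0.125), first
cousins (0.0625), plus unrelated founders (0).

**ROH injection.** Tracts of roughly equal length (≥ 1 Mb) totalling
exactly the requested fraction of each contig are placed uniformly without
overlap (Dirichlet-distributed gaps); within a tract each heterozygote
collapses to a random homozygote, which is what autozygosity does to a
genotype.

**Sweep pair.** Both populations are copying mosaics of 20 shared founder
haplotypes (switch probability 1−exp(−10⁻⁴·bp) between adjacent sites,
per-site mutation 0.002). In the swept population a fraction β = 0.4 of
haplotypes copy founder 0 across a tract around the core whose half-length
is exponential with mean 200 kb per side, so identity erodes with
distance — the haplotype signature of a partial hard sweep, without
simulating a selection trajectory (the tested surface is peak
localization, which needs long shared haplotypes at a known position, not
a realistic allele-frequency path). Default scale: 1500 SNPs evenly
spaced on a 3 Mb contig, 50 haplotypes per population. With β = 0 the
populations are exchangeable and serve as the neutral calibration.

**Toy assembly.** Three scaffolds (6 Mb, 2 Mb, 0.3 Mb), planted N-gaps,
repeat mask, presence intervals covering every length × position × type
combination including both merge-rule boundary cases (3 bp and exactly
5 bp gaps), genes inside and straddling retained regions, and a term table
loading one GO term onto the contained genes. Every expected
classification is derived analytically while the fixture is built, never
by running the classifier, so the fixture is an independent truth table.

## What the tests do and do not show

The generators produce idealized data: unlinked sites given deme
frequencies (except the sweep mosaics), no genotyping error, no
ascertainment bias, exact Hardy–Weinberg founders and a constant genetic
map. Passing recovery tests therefore demonstrates correctness of the
estimators and procedures under their generating models, not robustness
to real-data pathologies (batch effects, mapping bias, phasing error).
The deposited-data quantities of the source study are not recomputed here
because the deposited summary tables are not redistributed with the
package.

## Numerical choices

Undefined quantities are flagged, not silently dropped: IBS distances
with no co-called sites are NaN, kinship pairs with no heterozygotes carry
`defined=False`, Mantel on a constant matrix returns an `undefined`
result, and EHH with fewer than two carriers raises. Monomorphic sites
are excluded from PCA and LD r² treats zero-variance columns as
uncorrelated. Permutation p-values use the +1 convention; exact Mantel
counts the identity permutation. Peak-caller comparisons use ≥/> exactly
as stated, and window sums are cumulative-sum based (exact for the
integer-valued score plateaus used in the oracle tests). Problem sizes in
the test-suite and acceptance script (20k-site two-deme panels, 50k-site
pedigrees, 10k-site ROH contigs, 1500-SNP sweep contigs, 20 replicates
per stochastic claim) are the package's chosen desk-scale study
conditions; all recover their targets within the stated tolerances in
about half a minute.
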