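# Methods

This note records the models, conventions and design choices behind each
stage of the toolkit, what the synthetic-data generator does and does not
emulate, and the numerical decisions a maintainer would want to know.

## Coordinates and formats

All coordinates are 0-based half-open (BED-native) throughout the package;
VCF positions are converted on read and write so no other module ever sees
a 1-based coordinate. Soft-masked (lowercase) FASTA runs are retained as a
parallel mask track rather than hard-masked; scanners currently ignore the
mask. Ambiguity codes other than N are rejected on input with a clear error;
N is treated as a mismatch by all scanners. Interval algebra (merge,
intersect, subtract, total length) is a sorted sweep with half-open
semantics; the test suite checks it against a per-base bitmap oracle.

## Telomere detection

A telomere is a maximal tandem run of the motif (default `CCCTAAA`, ≥ 5 bp
enforced) whose run start (5' end) or run end (3' end, reverse-complement
motif) lies within `terminal_window` of the chromosome terminus. Defaults:
`min_copies = 4`, `terminal_window = 10 kb`. These two thresholds are
exposed as flags because terminal repeat tracts in real assemblies vary from
a few hundred bases to tens of kilobases and published pipelines rarely
state their run criteria. Copy counts are full motif copies; partial edge
copies are not counted. The detector is strand-symmetric: reverse-
complementing a chromosome swaps 5'/3' hits with mirrored coordinates (a
property test).

## Satellite scanning

`scan_satellite` finds non-overlapping, monomer-sized hits at or above an
identity threshold (default 0.90) in both orientations. Identity is
BLAST-style: matches divided by alignment columns of a global alignment
against the monomer, not matches over the shorter sequence. Tiling is
greedy: the best remaining hit (smallest edit distance, leftmost on ties)
is accepted and masked, until the best hit falls below the threshold. Hit
lengths are constrained to ±20% of the monomer length (tunable), so
severely truncated partial copies are excluded by default. Two modes share
this engine: the default seeds candidate regions with exact 16-mers of the
monomer and scans only those; `exact=True` scans whole chromosomes and
serves as the oracle in tests (the two agree on sequences up to ~50 kb).
Alignment is done with edlib (banded semi-global placement plus global
rescoring); because edit-distance-optimal alignments are not unique,
identities from co-optimal alignments can differ in the third decimal —
tests therefore pin edit distances exactly and identities to a small
tolerance.

## Monomer consensus and divergence

The consensus is a column-wise majority vote over a star alignment anchored
on the medoid copy (the copy minimizing total edit distance to a sample of
≤30 others) rather than a full multiple alignment: deterministic, linear in
the number of copies, and adequate for the ≤5% divergent monomers it is
meant for (a simulation test shows exact recovery of the true monomer from
100 copies at 2% substitution). Ties break in fixed base order A<C<G<T;
gap-majority columns are dropped; inputs whose lengths differ by more than
50% are rejected with a suggestion to split length classes first. Variant
counts against the consensus score one per mismatched column plus one per
gap opening, so a 2-bp deletion counts once. Identity strata
(within-chromosome, among-chromosome, between-genome) subsample to ~1800
monomers proportionally by chromosome with a fixed seed, then cap pairs per
stratum (default 20,000) before computing pairwise identities.

## Centromere delineation, arm ratios, repositioning

Satellite hits within `merge_gap` (default 50 kb) merge into candidate
arrays; the array overlapping the densest tandem-repeat window (window
100 kb) becomes the centromere ("array-anchored"). Chromosomes without
satellite hits fall back to the maximal run of windows with tandem density
≥ `min_density` (default 0.5) — "density-inferred". These three documented
parameters replace the manual boundary curation that such studies perform;
chromosomes with neither signal are reported "undetermined" rather than
raising. One centromere per chromosome is enforced (monocentric assumption,
appropriate for the legumes this targets). Arm ratio is long arm / short
arm (≥ 1, infinite and flagged when the centromere touches an end).
Repositioning projects centromere A's midpoint into the partner genome by
linear interpolation between the nearest flanking anchors; the verdict is
"repositioned" when the projection lands more than `threshold` (default
1 Mb — a flag, since synteny non-overlap has no canonical numeric cutoff)
outside centromere B, and any inversion call covering the midpoint or the
projection is attached to the call.

## Inversion detection and breakpoints

Detection looks for maximal runs of reverse-oriented anchors along the
query, bridging up to `max_noise = 2` consecutive forward anchors and
requiring `min_anchors = 5` reverse anchors per run — a run-based,
reproducible replacement for calling "funnel" patterns by eye on dot plots.
Call bounds span the first to last reverse anchor, so recovered bounds are
accurate to one anchor spacing by construction. Breakpoint flanks are
40-kb windows extending **outward** from each inversion edge (the flank
windows used for enrichment), clipped at chromosome ends with the clipping
recorded; a `centered` option places them across the edge instead, since
"flanking the boundary" admits both readings.

## Inversion genotyping

Per accession, `covered_fraction` is breadth: the fraction of bases in the
inversion whose bin depth is at or above `min_depth = 1`, partial bins
weighted by overlap. The coverage call is REF iff breadth strictly exceeds
0.94 (the >94% rule; 0.94 itself is INV). Breadth-at-depth≥1 rather than
mean depth is the default reading of "genomic coverage"; the depth floor is
a flag so a mean-depth-like criterion can be emulated. Independently, a PCA
restricted to inversion-region SNPs (mean-imputed, centered, scaled,
zero-variance sites dropped) is clustered by 1-D two-means on PC1; cluster
labels map to REF/INV by maximal agreement with the coverage calls when
available, otherwise the larger cluster is REF (carriers are the minority
under the default design). Discordant calls keep the coverage call — the
primary signal — with a conflict flag, replacing manual read-level review
with an explicit report rather than a silent tie-break.

## Population statistics

Hard filters implement the removal disjunction QD<2.0 || QUAL<30.0 ||
SOR>3.0 || FS>60.0 || MQ<40.0 plus the rank-sum criteria. Taken literally,
rank-sum thresholds of ≤12.5/≤8.0 would remove essentially every site
(rank-sum annotations are near zero for well-behaved variants); the
defaults therefore follow the GATK convention, removing at ≤ −12.5 and
≤ −8.0, with the literal reading available via `literal_ranksum=True`.
Missing annotations never fire a criterion. MAF filtering is inclusive at
the bound (MAF ≥ 0.03 kept) and missingness exclusive above 0.1, computed
over non-missing alleles with no imputation. Windowed π divides by window
length (VCFtools convention; `per_site=True` divides by variant sites).
F_ST is Weir & Cockerham (1984) — the estimator VCFtools implements —
combined per window as Σa/Σ(a+b+c); windows without polymorphic sites
report None rather than zero. Multiallelic sites are dropped on VCF read.

## Permutation enrichment

Observed occupancy is the unique-base overlap between breakpoint windows
and a repeat class. Each permutation draws, for every breakpoint length,
one interval uniformly among all start positions in unmasked space
(weighted across gaps and chromosomes), fully avoiding the mask; sampled
intervals may overlap each other, since length-matched "equivalent
intervals" carry no joint non-overlap constraint. k counts permutations
with observed strictly greater than permuted, p = (N − k)/N exactly — ties
count against enrichment, so an annotation covering the whole genome yields
p = 1. An add-one smoothed estimator (N − k + 1)/(N + 1) is available by
flag but is not the default. Multiple classes run against a shared
placement set per iteration and are reported without multiplicity
correction (per-class p plus fold = observed/expected mean, the frequency
and magnitude components respectively). Tests verify the sampler's start
distribution by a KS test, the p-value against exhaustive enumeration on a
10-kb toy, and null calibration (mean p within [0.45, 0.55] over 200
random-annotation runs; the residual deviation from 0.5 is the tie mass of
the strict inequality on a discrete occupancy).

## Assembly QC

Error rate is Σ NM / Σ aligned query bases over mapped reads; NM counts
mismatches plus small indels and is used as-is. Aligned query bases mean
matched + mismatched + inserted bases, soft-clips excluded. Alignment
summaries are consumed as a documented TSV (a one-line conversion from
standard alignment output is given in the module docstring) to keep the
module dependency-light. N50 is the largest L such that contigs ≥ L cover
half the assembly, computed by descending cumulative sum.

## The synthetic-data generator

The generator's defaults are the study conditions the pipeline targets:
two groups of 45 and 225 accessions; inversion carrier frequencies 0.69 and
0.24; Balding–Nichols divergence F = 0.74 inside and 0.10 outside the
inversion; 455-bp satellite monomers at 2% per-copy substitution; 7-bp
telomere motif caps (30 copies per end); SD pairs ≥1 kb at ≥90% identity;
Poisson(20) coverage per 500-bp bin with zero-depth voids over 25% of the
inversion in carriers, split between the two breakpoints and growing inward;
read error rate 0.01 and improper-pair fraction 0.05. Chromosomes default to
a few hundred kilobases so the full pipeline runs in seconds; the problem
sizes are a deliberate desk-scale choice, with counts (45/225 accessions,
thousands of SNPs) kept at study scale where they drive the statistics.

Inside-inversion SNPs follow a haplotype-block model by default: each site
carries a non-inverted and an inverted haplotype frequency (diverged at
F = 0.74) and an accession draws both alleles from the vector matching its
binary inversion genotype. This couples inversion-region SNPs to carrier
status — which is what makes inversion-region PCA genotyping work — but it
means realized *between-subspecies* F_ST inside the inversion is capped by
the carrier-frequency difference (about 0.24 under the defaults), not equal
to the haplotype divergence. With `hap_block=False` the generator instead
draws per-group frequencies directly from Balding–Nichols at F = 0.74
inside / 0.10 outside, which is the configuration the F_ST-recovery checks
use. The two modes reflect that a single-locus simulator cannot make the
carrier frequencies and the between-group F_ST hit study-scale values
simultaneously; real subspecies carry genome-wide divergence beyond one
inversion.

What the generator does **not** emulate: linkage disequilibrium beyond the
inversion block, recombination, demographic history, read-level sequence
(no FASTQ), reference bias, mapping artifacts at repeats, heterozygous
inversion carriers (the inversion is a binary carrier state, matching
two-class genotyping), and satellite higher-order repeat structure.
Passing recovery tests therefore demonstrate correctness of the estimators
and detectors under the stated generative model, not robustness to every
artifact of real re-sequencing data.

## Determinism and numerical choices

All generators and the permutation test are deterministic under a fixed
seed (numpy `default_rng`); derived seeds stay below 2^31. PCA uses full
SVD so variance fractions sum to 1; two-means on PC1 uses a fixed
`random_state`. Satellite-scan ties break leftmost; consensus ties break
A<C<G<T; degenerate inputs (empty windows, monomorphic sites, undetermined
centromeres, missing accessions) return typed sentinels (None/NA/flags)
rather than raising, except where the input is structurally invalid.

## Known limitations

- The satellite scanner's greedy stop rule (stop when the globally best
  remaining hit drops below threshold) can, in principle, miss an
  above-threshold hit whose edit distance exceeds that of a rejected
  shorter candidate; this does not occur for tandem arrays of a single
  monomer class, the intended use.
- Anchor projection for repositioning assumes collinearity between the two
  flanking anchors; a projection through a nested rearrangement inherits
  that rearrangement's distortion (the attached inversion call flags this).
- `pca_genotype` assigns REF/INV deterministically but the two-cluster
  assumption fails for populations segregating more than two structural
  haplotypes.
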