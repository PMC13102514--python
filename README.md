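# t2tpop

A comparative-genomics toolkit for telomere-to-telomere (T2T) plant genome
assemblies and the population analyses they enable. It packages, as tested
reusable code, the computations a T2T re-sequencing study runs between the
assembler and the figures:

- **telomere detection** — maximal tandem runs of the canonical plant motif
  (5'-CCCTAAA / 3'-TTTAGGG) at chromosome termini;
- **satellite scanning** — locating copies of a centromeric monomer class
  (e.g. the 455-bp cowpea unit) at a ≥90% alignment-identity threshold, plus
  monomer consensus building, per-copy variant counts, and pairwise-identity
  strata (within-chromosome / among-chromosome / between-genome);
- **centromere delineation** — merging satellite hits into arrays anchored on
  tandem-repeat density, arm ratios, and anchor-projected repositioning calls
  between syntenic chromosomes;
- **inversion detection** — runs of reverse-oriented syntenic anchors (the
  dot-plot "funnel"), with 40-kb breakpoint flank windows;
- **population inversion genotyping** — per accession, breadth of short-read
  coverage over the inversion (REF iff breadth > 94%) reconciled with
  clustering on PC1 of a PCA restricted to inversion-region SNPs;
- **population genetics** — GATK-style hard filters, MAF/missingness
  filtering, 50-kb windowed nucleotide diversity (π) and Weir & Cockerham
  (1984) F_ST, and genotype-matrix PCA;
- **breakpoint enrichment** — a permutation test for repeat occupancy at
  inversion breakpoints with genome-wide centromere/telomere masking,
  p = (N − k)/N over N = 1000 length-matched placements;
- **assembly QC** — NM-tag base-level error rate, improper-pair rate,
  mapping rate and breadth, contig N50.

Because the real inputs of such a study are hundreds of gigabytes of reads,
the package ships a first-class **synthetic-data generator** that emulates
the study design with known ground truth: telomere-capped chromosomes with
mutated satellite arrays and TE/SD annotations, a two-subspecies population
of 45 + 225 accessions segregating for an inversion at carrier frequencies
0.69/0.24, Balding–Nichols allele-frequency divergence (F = 0.74 inside the
inversion, 0.10 outside), coverage voids over the inversion in carriers, and
binomial alignment-error summaries. Every detector is validated by
recovering what the generator planted.

## The statistics at the core

Per-site nucleotide diversity uses allele counts over non-missing calls,
π_site = 2·c_ref·c_alt / (n(n−1)), summed over a window and divided by the
window length (the VCFtools convention). F_ST is the Weir & Cockerham (1984)
two-population estimator: per-site variance components (a, b, c) from sample
sizes, allele frequencies and observed heterozygosity, combined over a
window as Σa / Σ(a+b+c). Group allele frequencies in the simulator follow
the Balding–Nichols model, p_group ~ Beta(p(1−F)/F, (1−p)(1−F)/F), so a
target F is dialed in directly. The breakpoint permutation test reports
P = (N − k)/N, k being the number of permutations whose length-matched
random placement carries strictly less repeat occupancy than observed.

## Worked example

Genotype a simulated 270-accession population for its inversion and recover
the windowed F_ST landscape:

```python
import numpy as np
from t2tpop.synthetic_data import SimConfig, simulate_population, simulate_coverage, GROUP_A, GROUP_B
from t2tpop.inversion import (covered_fraction, genotype_by_coverage,
                              pca_genotype, reconcile, group_carrier_frequencies)
from t2tpop.popgen import window_fst

cfg = SimConfig(seed=1)                      # 45 + 225 accessions, carriers 0.69/0.24
gm, truth = simulate_population(cfg)
profiles = simulate_coverage(truth, cfg)

inv = cfg.inversion
fracs = {a: covered_fraction(p, inv) for a, p in profiles.items()}
cov = {a: genotype_by_coverage(f) for a, f in fracs.items()}     # REF iff breadth > 0.94
pca, _ = pca_genotype(gm, inv, coverage_calls=cov)
genotypes = reconcile(cov, pca, fracs)

truth_calls = {a: "INV" if c else "REF" for a, c in truth.inversion_carriers.items()}
print("per-accession concordance:",
      np.mean([g.final_call == truth_calls[g.accession] for g in genotypes]))
print("recovered carrier frequencies:", group_carrier_frequencies(genotypes, truth.groups))

fst_cfg = SimConfig(seed=2, snp_count=8_000, hap_block=False)    # F = 0.74 in / 0.10 out
gm2, truth2 = simulate_population(fst_cfg)
ga = [s for s in gm2.samples if truth2.groups[s] == GROUP_A]
gb = [s for s in gm2.samples if truth2.groups[s] == GROUP_B]
for w in window_fst(gm2, ga, gb, window=50_000, chrom_length=400_000):
    print(f"{w.chrom}:{w.window.start}-{w.window.end}  n={w.n_sites}  FST={w.value:.3f}")
```

Output:

```
per-accession concordance: 1.0
recovered carrier frequencies: {'unguiculata': 0.6888888888888889, 'sesquipedalis': 0.24444444444444444}
chr1:0-50000  n=986  FST=0.217
chr1:50000-100000  n=1037  FST=0.735
chr1:100000-150000  n=993  FST=0.749
chr1:150000-200000  n=1014  FST=0.218
chr1:200000-250000  n=976  FST=0.096
chr1:250000-300000  n=1012  FST=0.100  ...
```

Every accession's inversion genotype matches the simulated truth, the
recovered carrier frequencies sit at the configured 0.69/0.24 design, and
the 50-kb F_ST windows inside the inversion (which spans 40–160 kb here)
recover the target 0.74 while flanking windows fall to the background 0.10
(edge windows mixing inside and outside sites land in between).

The same pipeline is available from the shell — `t2tpop simulate`,
`telomeres`, `satscan`, `centromere`, `invdetect`, `invgeno`, `popstats`,
`enrich`, `qc` — and `t2tpop demo --seed 0 --out demo/` runs everything end
to end and writes a machine-readable recovery report.

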