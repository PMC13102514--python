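"""Ground-truth synthetic data: genomes, anchor maps, populations, coverage.

Every downstream stage of the pipeline is exercisable on data produced here,
with the generating parameters recorded as truth. The default configuration
mirrors the study design the pipeline targets: a two-subspecies cowpea-like
population of 45 + 225 accessions segregating for a large inversion at
carrier frequencies 0.69 and 0.24, allele-frequency divergence following a
Balding-Nichols beta model (F = 0.74 inside the inversion, 0.10 outside),
telomere-capped chromosomes, a centromeric array of 455-bp satellite
monomers with per-copy substitutions, TE/SD annotation tracks, and coverage
tracks showing voids over the inversion in carrier accessions.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .core_io import (
    AnchorPair,
    AnnotationTrack,
    GenomeSequence,
    GenotypeMatrix,
    Interval,
    VariantRecord,
    revcomp,
)
from .inversion import CoverageProfile
from .qc_metrics import AlignmentRecord

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_genome",
    "apply_inversion",
    "simulate_anchor_map",
    "simulate_population",
    "simulate_coverage",
    "simulate_alignments",
    "simulate_variant_annotations",
    "random_sequence",
    "mutate_sequence",
    "balding_nichols",
]

GROUP_A = "unguiculata"
GROUP_B = "sesquipedalis"


@dataclass
class SimConfig:
    """Declarative description of one synthetic study.

    Defaults are the study conditions the pipeline is meant to recover:
    group sizes 45/225, inversion carrier frequencies 0.69/0.24, target
    F_ST 0.74 inside the inversion and 0.10 outside, 455-bp satellite
    monomers at 2% per-copy divergence, and 7-bp telomere motif caps.
    """

    seed: int = 0
    chromosome_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 400_000, "chr2": 300_000}
    )
    # telomeres
    telomere_motif: str = "CCCTAAA"
    telomere_copies: int = 30
    # centromeric satellite array
    monomer_length: int = 455
    satellite_monomer: str | None = None  # generated from the seed when None
    satellite_copies: int = 120
    satellite_sub_rate: float = 0.02
    satellite_position: float = 0.55  # array start as a fraction of chrom length
    # TE / SD annotations
    te_count_per_chrom: int = 12
    te_length_range: tuple[int, int] = (500, 5_000)
    sd_pairs_per_chrom: int = 2
    sd_length: int = 1_500
    sd_divergence: float = 0.03  # keeps SD pairs >=90% identical
    # inversion (on the first chromosome)
    inversion: Interval | None = Interval("chr1", 40_000, 160_000)
    # population
    group_sizes: tuple[int, int] = (45, 225)
    carrier_freqs: tuple[float, float] = (0.69, 0.24)
    snp_count: int = 6_000
    fst_inside: float = 0.74
    fst_outside: float = 0.10
    hap_block: bool = True  # couple inside-inversion SNPs to the inversion genotype
    # coverage
    mean_depth: float = 20.0
    coverage_bin: int = 500
    void_fraction: float = 0.25
    # alignment summaries
    n_reads: int = 10_000
    read_length: int = 100
    alignment_error_rate: float = 0.01
    improper_pair_fraction: float = 0.05
    mapping_rate: float = 0.995

    def __post_init__(self) -> None:
        for name in (
            "satellite_sub_rate",
            "sd_divergence",
            "fst_inside",
            "fst_outside",
            "void_fraction",
            "alignment_error_rate",
            "improper_pair_fraction",
            "mapping_rate",
        ):
            val = getattr(self, name)
            if not 0 <= val <= 1:
                raise ValueError(f"{name}={val} must lie in [0,1]")
        for cf in self.carrier_freqs:
            if not 0 <= cf <= 1:
                raise ValueError("carrier frequencies must lie in [0,1]")
        if any(n <= 0 for n in self.group_sizes):
            raise ValueError("group sizes must be positive")
        if any(l <= 0 for l in self.chromosome_lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        if self.inversion is not None:
            L = self.chromosome_lengths.get(self.inversion.chrom)
            if L is None or self.inversion.end > L:
                raise ValueError("inversion interval must lie inside its chromosome")

    @property
    def samples(self) -> list[str]:
        nA, nB = self.group_sizes
        return [f"{GROUP_A[:3]}_{i:03d}" for i in range(nA)] + [
            f"{GROUP_B[:3]}_{i:03d}" for i in range(nB)
        ]

    @property
    def groups(self) -> dict[str, str]:
        nA, _ = self.group_sizes
        return {
            s: (GROUP_A if i < nA else GROUP_B)
            for i, s in enumerate(self.samples)
        }


@dataclass
class SimTruth:
    """Ground truth emitted alongside each simulated dataset."""

    telomeres: list[tuple[str, str, Interval]] = field(default_factory=list)
    satellite_arrays: dict[str, Interval] = field(default_factory=dict)
    monomer: str | None = None
    inversion: Interval | None = None
    breakpoints: tuple[int, int] | None = None
    inversion_carriers: dict[str, bool] = field(default_factory=dict)
    groups: dict[str, str] = field(default_factory=dict)
    group_freqs: dict[str, np.ndarray] = field(default_factory=dict)
    site_positions: np.ndarray | None = None
    annotations: dict[str, AnnotationTrack] = field(default_factory=dict)
    sd_pairs: list[tuple[Interval, Interval]] = field(default_factory=list)
    alignment_totals: dict[str, float] = field(default_factory=dict)


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def mutate_sequence(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Independent substitutions at the given per-base rate (no indels)."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    bases = np.array([b"A", b"C", b"G", b"T"])
    for i in hits:
        choices = bases[bases != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# Genome


def simulate_genome(config: SimConfig) -> tuple[GenomeSequence, SimTruth, dict[str, AnnotationTrack]]:
    """Build telomere-capped chromosomes with a centromeric satellite array
    and TE/SD annotations, and record where everything is.

    Chromosome layout: 5' telomere cap | flank | satellite array | flank |
    3' telomere cap (reverse-complement motif). Satellite copies are each
    independently mutated at the configured substitution rate. SD pairs are
    real sequence copies >=1 kb sharing >=90% identity; TE annotations label
    intervals without altering sequence. Deterministic under the seed.
    """
    rng = np.random.default_rng(config.seed)
    monomer = config.satellite_monomer or random_sequence(rng, config.monomer_length)
    tel5 = config.telomere_motif * config.telomere_copies
    tel3 = revcomp(config.telomere_motif) * config.telomere_copies
    truth = SimTruth(monomer=monomer)
    sequences: dict[str, str] = {}
    te_intervals: dict[str, list[Interval]] = {"LTR/Gypsy": [], "LTR/Copia": [], "DNA": []}
    sd_intervals: list[Interval] = []

    for chrom, L in config.chromosome_lengths.items():
        array_len = config.satellite_copies * len(monomer)
        array_start = int(config.satellite_position * L)
        array_end = array_start + array_len
        tel_len = len(tel5)
        if array_start < tel_len + 1000 or array_end > L - tel_len - 1000:
            raise ValueError(
                f"satellite array [{array_start},{array_end}) does not fit inside "
                f"chromosome {chrom} of length {L} with telomere caps"
            )
        array = "".join(
            mutate_sequence(rng, monomer, config.satellite_sub_rate)
            for _ in range(config.satellite_copies)
        )
        flank1 = random_sequence(rng, array_start - tel_len)
        flank2 = random_sequence(rng, L - array_end - tel_len)
        seq = tel5 + flank1 + array + flank2 + tel3
        assert len(seq) == L

        # SD pairs: copy a segment within the flanks at low divergence
        seq_list = [seq]

        def free_spot(rng, lo, hi, length, occupied):
            for _ in range(200):
                s = int(rng.integers(lo, hi - length))
                iv = Interval(chrom, s, s + length)
                if not any(iv.overlaps(o) for o in occupied):
                    return iv
            return None

        occupied = [
            Interval(chrom, 0, tel_len),
            Interval(chrom, L - tel_len, L),
            Interval(chrom, array_start, array_end),
        ]
        for _ in range(config.sd_pairs_per_chrom):
            src = free_spot(rng, tel_len, array_start, config.sd_length, occupied)
            dst = free_spot(rng, array_end, L - tel_len, config.sd_length, occupied)
            if src is None or dst is None:
                continue
            segment = seq_list[0][src.start : src.end]
            copy = mutate_sequence(rng, segment, config.sd_divergence)
            s = seq_list[0]
            seq_list[0] = s[: dst.start] + copy + s[dst.end :]
            sd_intervals.extend([src, dst])
            truth.sd_pairs.append((src, dst))
            occupied.extend([src, dst])

        for _ in range(config.te_count_per_chrom):
            te_len = int(rng.integers(*config.te_length_range))
            iv = free_spot(rng, tel_len, L - tel_len, te_len, occupied)
            if iv is None:
                continue
            label = ("LTR/Gypsy", "LTR/Copia", "DNA")[int(rng.integers(0, 3))]
            te_intervals[label].append(iv)
            occupied.append(iv)

        sequences[chrom] = seq_list[0]
        truth.telomeres.append((chrom, "5prime", Interval(chrom, 0, tel_len)))
        truth.telomeres.append((chrom, "3prime", Interval(chrom, L - tel_len, L)))
        truth.satellite_arrays[chrom] = Interval(chrom, array_start, array_end)

    tracks = {
        label: AnnotationTrack(label, ivs) for label, ivs in te_intervals.items()
    }
    tracks["SD"] = AnnotationTrack("SD", sd_intervals)
    tracks["centromere"] = AnnotationTrack(
        "centromere", list(truth.satellite_arrays.values())
    )
    tracks["telomere"] = AnnotationTrack(
        "telomere", [iv for _, _, iv in truth.telomeres]
    )
    truth.annotations = tracks
    genome = GenomeSequence(sequences)
    return genome, truth, tracks


def apply_inversion(
    genome: GenomeSequence, interval: Interval
) -> tuple[GenomeSequence, SimTruth]:
    """Replace the segment by its reverse complement; record the event."""
    if interval.chrom not in genome:
        raise ValueError(f"chromosome {interval.chrom!r} not in genome")
    seq = genome[interval.chrom]
    if interval.end > len(seq):
        raise ValueError("inversion interval spans beyond the chromosome end")
    inverted = (
        seq[: interval.start]
        + revcomp(seq[interval.start : interval.end])
        + seq[interval.end :]
    )
    sequences = dict(genome.sequences)
    sequences[interval.chrom] = inverted
    truth = SimTruth(inversion=interval, breakpoints=(interval.start, interval.end))
    return GenomeSequence(sequences, mask=genome.mask), truth


# ---------------------------------------------------------------------------
# Anchor maps


def simulate_anchor_map(
    chrom_lengths: dict[str, int],
    inversions: Sequence[Interval] = (),
    anchor_spacing: int = 10_000,
    anchor_length: int = 1_000,
    noise_rate: float = 0.0,
    seed: int = 0,
    target_prefix: str = "",
) -> list[AnchorPair]:
    """Syntenic anchors between a reference genome and a derived genome
    carrying the recorded inversions.

    Anchors are placed every ``anchor_spacing`` bases; anchors inside an
    inversion get reversed orientation and mirrored target coordinates;
    anchors straddling a breakpoint are dropped (synteny breaks there).
    Optional noise anchors receive random target positions and orientation.
    """
    rng = np.random.default_rng(seed)
    anchors: list[AnchorPair] = []
    import warnings as _warnings

    for chrom, L in chrom_lengths.items():
        if anchor_spacing >= L:
            _warnings.warn(
                f"anchor spacing {anchor_spacing} exceeds chromosome {chrom} "
                f"length {L}; no anchors emitted"
            )
            continue
        tchrom = target_prefix + chrom
        invs = [iv for iv in inversions if iv.chrom == chrom]
        pos = anchor_spacing
        while pos + anchor_length <= L:
            q = Interval(chrom, pos, pos + anchor_length)
            inside = next(
                (iv for iv in invs if iv.start <= q.start and q.end <= iv.end), None
            )
            straddles = any(
                q.start < iv.start < q.end or q.start < iv.end < q.end for iv in invs
            )
            if straddles:
                pos += anchor_spacing
                continue
            if noise_rate > 0 and rng.random() < noise_rate:
                t0 = int(rng.integers(0, L - anchor_length))
                anchors.append(
                    AnchorPair(
                        q,
                        Interval(tchrom, t0, t0 + anchor_length),
                        "+" if rng.random() < 0.5 else "-",
                    )
                )
            elif inside is not None:
                # mirror within the inversion
                t_start = inside.start + (inside.end - q.end)
                t_end = inside.start + (inside.end - q.start)
                anchors.append(AnchorPair(q, Interval(tchrom, t_start, t_end), "-"))
            else:
                anchors.append(AnchorPair(q, Interval(tchrom, q.start, q.end), "+"))
            pos += anchor_spacing
    return anchors


# ---------------------------------------------------------------------------
# Population genotypes


def balding_nichols(
    rng: np.random.Generator, ancestral: np.ndarray, fst: float
) -> np.ndarray:
    """Subpopulation allele frequencies: Beta(p(1-F)/F, (1-p)(1-F)/F).

    F = 0 returns the ancestral frequencies unchanged (no drift)."""
    if not 0 <= fst < 1:
        raise ValueError("target F must lie in [0, 1)")
    if fst == 0:
        return ancestral.copy()
    scale = (1 - fst) / fst
    return rng.beta(ancestral * scale, (1 - ancestral) * scale)


def simulate_population(
    config: SimConfig, seed: int | None = None
) -> tuple[GenotypeMatrix, SimTruth]:
    """Simulate diploid genotypes for a two-group population with an
    inversion locus.

    Outside the inversion, group allele frequencies diverge from a shared
    ancestral frequency (Uniform(0.05,0.95)) under a Balding-Nichols model
    at ``fst_outside``. Inside the inversion, with the default haplotype-block
    model, each site carries a pair of haplotype frequencies (non-inverted /
    inverted) diverged at ``fst_inside``, and every accession draws its two
    alleles from the vector matching its inversion genotype — so
    inside-inversion SNPs are correlated with carrier status and PCA over
    them separates carriers. With ``hap_block=False``, inside sites instead
    use plain Balding-Nichols per-group frequencies at ``fst_inside``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    samples = config.samples
    groups = config.groups
    nA, nB = config.group_sizes
    carriers = {}
    for i, s in enumerate(samples):
        cf = config.carrier_freqs[0] if i < nA else config.carrier_freqs[1]
        carriers[s] = bool(rng.random() < cf)

    if config.inversion is not None:
        chrom = config.inversion.chrom
        L = config.chromosome_lengths[chrom]
    else:
        chrom, L = next(iter(config.chromosome_lengths.items()))
    positions = np.sort(
        rng.choice(np.arange(100, L - 100), size=config.snp_count, replace=False)
    )
    inv = config.inversion
    inside = (
        (positions >= inv.start) & (positions < inv.end)
        if inv is not None
        else np.zeros(len(positions), dtype=bool)
    )

    ancestral = rng.uniform(0.05, 0.95, size=config.snp_count)
    freq_A = np.empty(config.snp_count)
    freq_B = np.empty(config.snp_count)
    out = ~inside
    freq_A[out] = balding_nichols(rng, ancestral[out], config.fst_outside)
    freq_B[out] = balding_nichols(rng, ancestral[out], config.fst_outside)

    hap_ref = np.empty(config.snp_count)
    hap_inv = np.empty(config.snp_count)
    if config.hap_block:
        hap_ref[inside] = balding_nichols(rng, ancestral[inside], config.fst_inside)
        hap_inv[inside] = balding_nichols(rng, ancestral[inside], config.fst_inside)
        cA, cB = config.carrier_freqs
        freq_A[inside] = cA * hap_inv[inside] + (1 - cA) * hap_ref[inside]
        freq_B[inside] = cB * hap_inv[inside] + (1 - cB) * hap_ref[inside]
    else:
        freq_A[inside] = balding_nichols(rng, ancestral[inside], config.fst_inside)
        freq_B[inside] = balding_nichols(rng, ancestral[inside], config.fst_inside)

    geno = np.empty((config.snp_count, len(samples)), dtype=np.int8)
    for j, s in enumerate(samples):
        grp_freq = freq_A if groups[s] == GROUP_A else freq_B
        site_freq = grp_freq.copy()
        if config.hap_block and inv is not None:
            site_freq[inside] = hap_inv[inside] if carriers[s] else hap_ref[inside]
        geno[:, j] = rng.binomial(2, site_freq)

    bases = np.array(list("ACGT"))
    records = []
    for i, pos in enumerate(positions):
        ref, alt = rng.choice(4, size=2, replace=False)
        records.append(
            VariantRecord(
                chrom=chrom,
                pos=int(pos),
                ref=bases[ref],
                alt=bases[alt],
                qual=float(rng.uniform(100, 2000)),
                info={},
                genotypes=geno[i],
            )
        )
    truth = SimTruth(
        inversion=inv,
        breakpoints=(inv.start, inv.end) if inv is not None else None,
        inversion_carriers=carriers,
        groups=dict(groups),
        group_freqs={GROUP_A: freq_A, GROUP_B: freq_B},
        site_positions=positions,
    )
    return GenotypeMatrix(samples, records), truth


# ---------------------------------------------------------------------------
# Coverage


def simulate_coverage(
    truth: SimTruth,
    config: SimConfig,
    seed: int | None = None,
    region: Interval | None = None,
) -> dict[str, CoverageProfile]:
    """Binned read-depth profiles per accession over the inversion region.

    Baseline depth is Poisson(mean_depth) per bin. Accessions carrying the
    inversion get zero-depth voids over ``void_fraction`` of the inversion,
    split between the two breakpoints and growing inward (reads from the
    inverted haplotype fail to map across the breakpoints on the reference).
    Non-carriers keep their Poisson baseline, so essentially all their bins
    stay above zero.
    """
    if truth.inversion is None:
        raise ValueError("coverage simulation requires inversion truth")
    inv = truth.inversion
    if region is None:
        pad = max(len(inv) // 5, 1_000)
        region = Interval(inv.chrom, max(0, inv.start - pad), inv.end + pad)
    if config.coverage_bin > len(region):
        raise ValueError("coverage bin size exceeds the profiled region")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    n_bins = (len(region) + config.coverage_bin - 1) // config.coverage_bin
    bin_starts = region.start + config.coverage_bin * np.arange(n_bins)
    inv_bins = np.flatnonzero(
        (bin_starts >= inv.start) & (bin_starts + config.coverage_bin <= inv.end)
    )
    n_void = int(round(config.void_fraction * len(inv_bins)))
    profiles = {}
    for acc, carrier in truth.inversion_carriers.items():
        depths = rng.poisson(config.mean_depth, size=n_bins).astype(float)
        if carrier and n_void > 0:
            left = inv_bins[: (n_void + 1) // 2]
            right = inv_bins[len(inv_bins) - n_void // 2 :]
            depths[left] = 0.0
            depths[right] = 0.0
        profiles[acc] = CoverageProfile(
            accession=acc,
            chrom=region.chrom,
            start=int(region.start),
            bin_size=config.coverage_bin,
            depths=depths,
            reference="simulated-reference",
        )
    return profiles


# ---------------------------------------------------------------------------
# Alignment summaries


def simulate_alignments(
    config: SimConfig,
    seed: int | None = None,
    genome: GenomeSequence | None = None,
) -> tuple[list[AlignmentRecord], SimTruth]:
    """Read-alignment summaries: NM ~ Binomial(read length, error rate),
    improper-pair flags at the stated fraction, optional random placements."""
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    n = config.n_reads
    nm = rng.binomial(config.read_length, config.alignment_error_rate, size=n)
    mapped = rng.random(n) < config.mapping_rate
    improper = rng.random(n) < config.improper_pair_fraction
    chroms, lengths = None, None
    if genome is not None:
        chroms = list(genome.sequences)
        lengths = np.array([genome.chrom_length(c) for c in chroms])
        probs = lengths / lengths.sum()
    records = []
    for i in range(n):
        loc = None
        if genome is not None and mapped[i]:
            ci = rng.choice(len(chroms), p=probs)
            start = int(rng.integers(0, lengths[ci] - config.read_length))
            loc = Interval(chroms[ci], start, start + config.read_length)
        records.append(
            AlignmentRecord(
                read_id=f"read{i}",
                mapped=bool(mapped[i]),
                aligned_bases=config.read_length if mapped[i] else 0,
                nm=int(nm[i]) if mapped[i] else 0,
                paired=True,
                proper_pair=not improper[i],
                location=loc,
            )
        )
    truth = SimTruth(
        alignment_totals={
            "total_nm": float(nm[mapped].sum()),
            "total_bases": float(mapped.sum() * config.read_length),
            "improper_fraction": float(improper.mean()),
            "mapped_fraction": float(mapped.mean()),
        }
    )
    return records, truth


# ---------------------------------------------------------------------------
# Variant-annotation records for filter testing


def simulate_variant_annotations(
    n: int, seed: int = 0, fail_fraction: float = 0.5
) -> list[VariantRecord]:
    """Random sites with hard-filter annotations straddling the GATK
    thresholds, for exercising the filter disjunction."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        info = {
            "QD": float(rng.uniform(0, 8)),          # threshold 2.0
            "SOR": float(rng.uniform(0, 6)),         # threshold 3.0
            "FS": float(rng.uniform(0, 120)),        # threshold 60.0
            "MQ": float(rng.uniform(20, 60)),        # threshold 40.0
            "MQRankSum": float(rng.uniform(-25, 5)),  # threshold -12.5
            "ReadPosRankSum": float(rng.uniform(-16, 4)),  # threshold -8.0
        }
        # occasionally drop annotations to exercise the missing-value rule
        for key in list(info):
            if rng.random() < 0.1:
                del info[key]
        if rng.random() > fail_fraction:
            # force a clearly passing record
            info = {
                "QD": 25.0, "SOR": 1.0, "FS": 5.0, "MQ": 60.0,
                "MQRankSum": 0.0, "ReadPosRankSum": 0.0,
            }
        records.append(
            VariantRecord(
                chrom="chr1",
                pos=100 * i,
                ref="A",
                alt="T",
                qual=float(rng.uniform(10, 100)),
                info=info,
                genotypes=np.zeros(2, dtype=np.int8),
            )
        )
    return records
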