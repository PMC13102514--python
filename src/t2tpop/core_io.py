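"""Readers/writers for the standard formats the pipeline touches, plus interval algebra.

All coordinates are internally 0-based half-open (BED-native). Formats using
1-based inclusive positions (VCF) are converted on read and write so the rest
of the package never sees a 1-based coordinate.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

VALID_BASES = frozenset("ACGTN")

__all__ = [
    "Interval",
    "GenomeSequence",
    "AnnotationTrack",
    "AnchorPair",
    "VariantRecord",
    "GenotypeMatrix",
    "FastaParseError",
    "BedParseError",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_anchor_table",
    "write_anchor_table",
    "read_bedgraph",
    "write_bedgraph",
    "read_vcf",
    "write_vcf",
    "merge_intervals",
    "intersect_intervals",
    "subtract_intervals",
    "total_length",
    "revcomp",
]


class FastaParseError(ValueError):
    pass


class BedParseError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class Interval:
    """A genomic interval, 0-based half-open, optionally stranded."""

    chrom: str
    start: int
    end: int
    strand: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def revcomp(seq: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet."""
    return str(Seq(seq).reverse_complement())


class GenomeSequence:
    """Named chromosomes of uppercase nucleotide text over {A,C,G,T,N}.

    Lowercase (soft-masked) input bases are uppercased; the masked runs are
    retained as a parallel track of intervals so scanners can honor or ignore
    them. Ambiguity codes other than N are rejected.
    """

    def __init__(
        self,
        sequences: Mapping[str, str],
        mask: Mapping[str, Sequence[Interval]] | None = None,
    ) -> None:
        self.sequences: dict[str, str] = {}
        self.mask: dict[str, list[Interval]] = {}
        for name, seq in sequences.items():
            if name in self.sequences:
                raise FastaParseError(f"duplicate chromosome id {name!r}")
            if len(seq) == 0:
                raise FastaParseError(f"chromosome {name!r} has zero length")
            upper = seq.upper()
            bad = set(upper) - VALID_BASES
            if bad:
                raise FastaParseError(
                    f"chromosome {name!r} contains non-ACGTN characters: "
                    f"{sorted(bad)!r} (ambiguity codes other than N are not supported)"
                )
            self.sequences[name] = upper
            if mask is not None and name in mask:
                self.mask[name] = sorted(mask[name], key=lambda iv: iv.start)
            else:
                self.mask[name] = _lowercase_runs(name, seq)

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def __iter__(self) -> Iterator[str]:
        return iter(self.sequences)

    def chrom_length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def fetch(self, interval: Interval) -> str:
        seq = self.sequences[interval.chrom]
        if interval.end > len(seq):
            raise ValueError(
                f"interval {interval} beyond chromosome end ({len(seq)})"
            )
        return seq[interval.start : interval.end]


def _lowercase_runs(chrom: str, seq: str) -> list[Interval]:
    runs: list[Interval] = []
    start = None
    for i, ch in enumerate(seq):
        if ch.islower():
            if start is None:
                start = i
        elif start is not None:
            runs.append(Interval(chrom, start, i))
            start = None
    if start is not None:
        runs.append(Interval(chrom, start, len(seq)))
    return runs


@dataclass
class AnnotationTrack:
    """A class-labeled set of intervals (e.g. LTR/Gypsy, SD, centromere)."""

    label: str
    intervals: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("annotation class label must be nonempty")
        self.intervals = sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start))

    def __len__(self) -> int:
        return len(self.intervals)

    def on_chrom(self, chrom: str) -> list[Interval]:
        return [iv for iv in self.intervals if iv.chrom == chrom]


@dataclass(frozen=True)
class AnchorPair:
    """A syntenic anchor: matched query and target blocks with orientation."""

    query: Interval
    target: Interval
    orientation: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.orientation not in ("+", "-"):
            raise ValueError(f"orientation must be +/-, got {self.orientation!r}")


@dataclass
class VariantRecord:
    """A biallelic SNP site with optional hard-filter annotations and genotypes.

    ``pos`` is 0-based (converted from the VCF's 1-based POS on read).
    Genotype codes are alt-allele dosages {0,1,2} with -1 for missing.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float | None = None
    info: dict[str, float] = field(default_factory=dict)
    genotypes: np.ndarray | None = None  # int8 codes per accession


@dataclass
class GenotypeMatrix:
    """Population genotypes: accessions x sites, with per-site metadata."""

    samples: list[str]
    records: list[VariantRecord]

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.genotypes is None or len(rec.genotypes) != len(self.samples):
                raise ValueError(
                    f"site {rec.chrom}:{rec.pos} genotype vector does not match "
                    f"sample count {len(self.samples)}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.records)

    def matrix(self) -> np.ndarray:
        """Dense (n_sites, n_samples) int8 dosage matrix, -1 = missing."""
        if not self.records:
            return np.zeros((0, len(self.samples)), dtype=np.int8)
        return np.vstack([rec.genotypes for rec in self.records]).astype(np.int8)

    def subset_sites(self, keep: Sequence[bool] | Sequence[int]) -> "GenotypeMatrix":
        arr = np.asarray(keep)
        if arr.dtype == bool:
            recs = [r for r, k in zip(self.records, arr) if k]
        else:
            recs = [self.records[i] for i in arr]
        return GenotypeMatrix(self.samples, recs)

    def sites_in(self, interval: Interval) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.samples,
            [
                r
                for r in self.records
                if r.chrom == interval.chrom and interval.start <= r.pos < interval.end
            ],
        )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> GenomeSequence:
    """Read a FASTA file into a :class:`GenomeSequence`.

    Soft-masked (lowercase) runs become the genome's mask track. Duplicate
    headers and non-ACGTN characters raise :class:`FastaParseError`.
    """
    sequences: dict[str, str] = {}
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # Biopython raises assorted ValueErrors
        raise FastaParseError(f"malformed FASTA {path}: {exc}") from exc
    if not records:
        raise FastaParseError(f"no FASTA records found in {path}")
    for rec in records:
        if rec.id in sequences:
            raise FastaParseError(f"duplicate FASTA header {rec.id!r} in {path}")
        sequences[rec.id] = str(rec.seq)
    return GenomeSequence(sequences)


def write_fasta(genome: GenomeSequence, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED / bedgraph


def read_bed(path, label: str | None = None) -> AnnotationTrack:
    """Read BED3/BED4 into an :class:`AnnotationTrack` (0-based half-open).

    The 4th column, when present, becomes the interval's class label; the
    track label defaults to the most common name column value (or ``label``).
    """
    intervals: list[Interval] = []
    names: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise BedParseError(
                    f"{path}:{lineno}: start {start} >= end {end} (empty interval)"
                )
            if start < 0:
                raise BedParseError(f"{path}:{lineno}: negative start {start}")
            strand = None
            if len(fields) >= 6 and fields[5] in ("+", "-"):
                strand = fields[5]
            intervals.append(Interval(chrom, start, end, strand))
            if len(fields) >= 4 and fields[3]:
                names.append(fields[3])
    if label is None:
        if names:
            label = max(set(names), key=names.count)
        else:
            label = "region"
    return AnnotationTrack(label, intervals)


def write_bed(track: AnnotationTrack, path, scores: Sequence[float] | None = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(track.intervals):
            row = [iv.chrom, str(iv.start), str(iv.end), track.label]
            if scores is not None:
                row.append(f"{scores[i]:.4f}")
            if iv.strand is not None:
                while len(row) < 5:
                    row.append(".")
                row.append(iv.strand)
            fh.write("\t".join(row) + "\n")


def read_bedgraph(path) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Read a bedgraph into per-chromosome (starts, ends, values) arrays."""
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedParseError(f"{path}:{lineno}: expected 4 columns")
            per_chrom.setdefault(fields[0], []).append(
                (int(fields[1]), int(fields[2]), float(fields[3]))
            )
    out = {}
    for chrom, rows in per_chrom.items():
        rows.sort()
        s, e, v = zip(*rows)
        out[chrom] = (np.array(s), np.array(e), np.array(v))
    return out


def write_bedgraph(path, chrom: str, starts, ends, values) -> None:
    with open(path, "w") as fh:
        for s, e, v in zip(starts, ends, values):
            fh.write(f"{chrom}\t{int(s)}\t{int(e)}\t{v:g}\n")


# ---------------------------------------------------------------------------
# Anchor tables


def read_anchor_table(path, genomes: Mapping[str, GenomeSequence] | None = None) -> list[AnchorPair]:
    """Read a 6/7-column syntenic anchor table.

    Columns: query chrom, query start, query end, target chrom, target start,
    target end, [orientation]. When orientation is absent it is inferred from
    the sign of consecutive target-coordinate differences along the query.
    """
    rows: list[tuple[str, int, int, str, int, int, str | None]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise BedParseError(
                    f"{path}:{lineno}: expected >=6 tab-separated columns"
                )
            orient = f[6] if len(f) >= 7 and f[6] in ("+", "-") else None
            rows.append((f[0], int(f[1]), int(f[2]), f[3], int(f[4]), int(f[5]), orient))
    if genomes is not None:
        qnames = {r[0] for r in rows}
        tnames = {r[3] for r in rows}
        for role, names in (("query", qnames), ("target", tnames)):
            genome = genomes.get(role)
            if genome is not None:
                unknown = names - set(genome.sequences)
                if unknown:
                    warnings.warn(
                        f"{role} chromosomes {sorted(unknown)} not present in "
                        "the bound genome; records kept"
                    )
    rows.sort(key=lambda r: (r[0], r[1]))
    return _assign_orientations(rows)


def _assign_orientations(rows) -> list[AnchorPair]:
    anchors: list[AnchorPair] = []
    # orientation inferred per query chromosome from target coordinate trend
    by_chrom: dict[str, list] = {}
    for r in rows:
        by_chrom.setdefault(r[0], []).append(r)
    for chrom_rows in by_chrom.values():
        mids = [(r[4] + r[5]) / 2 for r in chrom_rows]
        n = len(chrom_rows)
        for i, r in enumerate(chrom_rows):
            orient = r[6]
            if orient is None:
                if n == 1:
                    orient = "+"
                elif i < n - 1:
                    orient = "+" if mids[i + 1] >= mids[i] else "-"
                else:
                    orient = "+" if mids[i] >= mids[i - 1] else "-"
            anchors.append(
                AnchorPair(
                    Interval(r[0], r[1], r[2]),
                    Interval(r[3], r[4], r[5]),
                    orient,
                )
            )
    anchors.sort(key=lambda a: (a.query.chrom, a.query.start))
    return anchors


def write_anchor_table(anchors: Iterable[AnchorPair], path) -> None:
    with open(path, "w") as fh:
        for a in anchors:
            fh.write(
                f"{a.query.chrom}\t{a.query.start}\t{a.query.end}\t"
                f"{a.target.chrom}\t{a.target.start}\t{a.target.end}\t{a.orientation}\n"
            )


# ---------------------------------------------------------------------------
# VCF (read via cyvcf2; minimal v4.2 text writer)

_INFO_KEYS = ("QD", "SOR", "FS", "MQ", "MQRankSum", "ReadPosRankSum")


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix` (biallelic SNPs only).

    POS is converted to the internal 0-based convention. Multiallelic records
    are dropped (consistent with a high-confidence SNP set). INFO keys used by
    the hard filters are retained; GT fields become {0,1,2,-1} dosages.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records: list[VariantRecord] = []
    for v in vcf:
        if len(v.ALT) != 1:
            continue
        info = {}
        for key in _INFO_KEYS:
            val = v.INFO.get(key)
            if val is not None:
                try:
                    info[key] = float(val)
                except (TypeError, ValueError):
                    warnings.warn(
                        f"non-numeric INFO/{key} at {v.CHROM}:{v.POS}; treated as missing"
                    )
        gt = np.asarray(v.gt_types, dtype=np.int8)
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        codes = np.full(len(gt), -1, dtype=np.int8)
        codes[gt == 0] = 0
        codes[gt == 1] = 1
        codes[gt == 3] = 2
        records.append(
            VariantRecord(
                chrom=v.CHROM,
                pos=v.POS - 1,
                ref=v.REF,
                alt=v.ALT[0],
                qual=v.QUAL,
                info=info,
                genotypes=codes,
            )
        )
    return GenotypeMatrix(samples, records)


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(gm: GenotypeMatrix, path, contig_lengths: Mapping[str, int] | None = None) -> None:
    """Write a minimal VCF v4.2 with GT fields and hard-filter INFO keys."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contig_lengths:
            for chrom, length in contig_lengths.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        for key in _INFO_KEYS:
            fh.write(
                f'##INFO=<ID={key},Number=1,Type=Float,Description="{key}">\n'
            )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for rec in gm.records:
            info = (
                ";".join(f"{k}={v:g}" for k, v in rec.info.items())
                if rec.info
                else "."
            )
            qual = f"{rec.qual:g}" if rec.qual is not None else "."
            gts = "\t".join(_GT_STRINGS[int(g)] for g in rec.genotypes)
            fh.write(
                f"{rec.chrom}\t{rec.pos + 1}\t.\t{rec.ref}\t{rec.alt}\t{qual}\t"
                f".\t{info}\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Interval algebra (sorted sweep; half-open semantics throughout)


def _group_by_chrom(intervals: Iterable[Interval]) -> dict[str, list[Interval]]:
    out: dict[str, list[Interval]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append(iv)
    for ivs in out.values():
        ivs.sort(key=lambda iv: (iv.start, iv.end))
    return out


def merge_intervals(intervals: Iterable[Interval], gap: int = 0) -> list[Interval]:
    """Merge overlapping or book-ended intervals; intervals within ``gap``
    bases of each other are also merged."""
    result: list[Interval] = []
    for chrom, ivs in sorted(_group_by_chrom(intervals).items()):
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end + gap:
                cur_end = max(cur_end, iv.end)
            else:
                result.append(Interval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        result.append(Interval(chrom, cur_start, cur_end))
    return result


def intersect_intervals(
    a: Iterable[Interval], b: Iterable[Interval]
) -> list[Interval]:
    """Pairwise intersection of two interval sets (each side merged first)."""
    am = _group_by_chrom(merge_intervals(a))
    bm = _group_by_chrom(merge_intervals(b))
    result: list[Interval] = []
    for chrom in sorted(set(am) & set(bm)):
        xs, ys = am[chrom], bm[chrom]
        i = j = 0
        while i < len(xs) and j < len(ys):
            lo = max(xs[i].start, ys[j].start)
            hi = min(xs[i].end, ys[j].end)
            if lo < hi:
                result.append(Interval(chrom, lo, hi))
            if xs[i].end <= ys[j].end:
                i += 1
            else:
                j += 1
    return result


def subtract_intervals(
    a: Iterable[Interval], b: Iterable[Interval]
) -> list[Interval]:
    """Bases of ``a`` not covered by ``b``."""
    am = _group_by_chrom(merge_intervals(a))
    bm = _group_by_chrom(merge_intervals(b))
    result: list[Interval] = []
    for chrom in sorted(am):
        cuts = bm.get(chrom, [])
        for iv in am[chrom]:
            pos = iv.start
            for cut in cuts:
                if cut.end <= pos:
                    continue
                if cut.start >= iv.end:
                    break
                if cut.start > pos:
                    result.append(Interval(chrom, pos, cut.start))
                pos = max(pos, cut.end)
                if pos >= iv.end:
                    break
            if pos < iv.end:
                result.append(Interval(chrom, pos, iv.end))
    return result


def total_length(intervals: Iterable[Interval]) -> int:
    """Total bases covered, counting each base once."""
    return sum(len(iv) for iv in merge_intervals(intervals))
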