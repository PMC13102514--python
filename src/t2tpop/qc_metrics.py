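"""Alignment-based assembly accuracy metrics and contiguity statistics.

Alignment summaries are consumed as a documented TSV rather than BAM:
one row per read with columns

    read_id  mapped(0/1)  aligned_bases  nm  paired(0/1)  proper(0/1)  [chrom  start  end]

A one-liner to produce this table from standard alignment output:

    samtools view aln.bam | awk '{nm=0; for(i=12;i<=NF;i++) if($i~/^NM:i:/){split($i,a,":"); nm=a[3]}
        mapped=and($2,4)?0:1; paired=and($2,1)?1:0; proper=and($2,2)?1:0;
        print $1"\t"mapped"\t"length($10)"\t"nm"\t"paired"\t"proper"\t"$3"\t"$4-1"\t"$4-1+length($10)}'

"aligned query bases" means matched + mismatched + inserted query bases
(soft-clips excluded). The NM tag counts mismatches plus small indels and is
used as-is for the base-level error rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core_io import GenomeSequence, Interval, merge_intervals, total_length

__all__ = [
    "AlignmentRecord",
    "QCReport",
    "read_alignment_tsv",
    "write_alignment_tsv",
    "error_rate",
    "improper_pair_rate",
    "mapping_and_breadth",
    "n50",
    "qc_report",
]


@dataclass(frozen=True)
class AlignmentRecord:
    """A summarized read alignment carrying the edit-distance (NM) tag."""

    read_id: str
    mapped: bool
    aligned_bases: int
    nm: int
    paired: bool = False
    proper_pair: bool = True
    location: Interval | None = None

    def __post_init__(self) -> None:
        if self.nm < 0 or self.aligned_bases < 0:
            raise ValueError("NM and aligned_bases must be non-negative")


@dataclass
class QCReport:
    error_rate: float
    improper_pair_rate: float | None
    mapping_rate: float
    breadth: float | None
    n50: int | None
    n_records: int

    def as_dict(self) -> dict:
        return {
            "error_rate": self.error_rate,
            "improper_pair_rate": self.improper_pair_rate,
            "mapping_rate": self.mapping_rate,
            "breadth": self.breadth,
            "n50": self.n50,
            "n_records": self.n_records,
        }


def read_alignment_tsv(path) -> list[AlignmentRecord]:
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            loc = None
            if len(f) >= 9 and f[6] != ".":
                loc = Interval(f[6], int(f[7]), int(f[8]))
            records.append(
                AlignmentRecord(
                    read_id=f[0],
                    mapped=bool(int(f[1])),
                    aligned_bases=int(f[2]),
                    nm=int(f[3]),
                    paired=bool(int(f[4])) if len(f) > 4 else False,
                    proper_pair=bool(int(f[5])) if len(f) > 5 else True,
                    location=loc,
                )
            )
    return records


def write_alignment_tsv(records: Iterable[AlignmentRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("#read_id\tmapped\taligned_bases\tnm\tpaired\tproper\tchrom\tstart\tend\n")
        for r in records:
            loc = (
                f"{r.location.chrom}\t{r.location.start}\t{r.location.end}"
                if r.location is not None
                else ".\t.\t."
            )
            fh.write(
                f"{r.read_id}\t{int(r.mapped)}\t{r.aligned_bases}\t{r.nm}\t"
                f"{int(r.paired)}\t{int(r.proper_pair)}\t{loc}\n"
            )


def error_rate(records: Sequence[AlignmentRecord]) -> float:
    """Base-level error rate: sum of NM over mapped reads / sum of aligned query bases."""
    mapped = [r for r in records if r.mapped]
    if not mapped:
        raise ValueError("no mapped records")
    total_bases = sum(r.aligned_bases for r in mapped)
    if total_bases == 0:
        raise ValueError("zero aligned bases across mapped records")
    return sum(r.nm for r in mapped) / total_bases


def improper_pair_rate(records: Sequence[AlignmentRecord]) -> float | None:
    """Fraction of evaluated read pairs flagged improper (discordant
    orientation or insert size); None when no paired records exist."""
    paired = [r for r in records if r.paired]
    if not paired:
        return None
    return sum(not r.proper_pair for r in paired) / len(paired)


def mapping_and_breadth(
    records: Sequence[AlignmentRecord],
    genome: GenomeSequence,
    min_depth: int = 1,
) -> tuple[float, float]:
    """Mapping rate (mapped/total reads) and breadth of coverage (fraction of
    genome bases with depth >= min_depth)."""
    if not records:
        return 0.0, 0.0
    mapping_rate = sum(r.mapped for r in records) / len(records)
    if min_depth <= 1:
        placed = [r.location for r in records if r.mapped and r.location is not None]
        covered = total_length(placed) if placed else 0
    else:
        covered = 0
        for chrom in genome:
            depth = np.zeros(genome.chrom_length(chrom) + 1, dtype=np.int32)
            for r in records:
                if r.mapped and r.location is not None and r.location.chrom == chrom:
                    depth[r.location.start] += 1
                    depth[r.location.end] -= 1
            covered += int(np.count_nonzero(np.cumsum(depth[:-1]) >= min_depth))
    return mapping_rate, covered / genome.total_length


def n50(lengths: Sequence[int]) -> int:
    """Largest L such that contigs of length >= L cover at least half the total."""
    if len(lengths) == 0:
        raise ValueError("n50 of an empty length set is undefined")
    arr = np.sort(np.asarray(lengths))[::-1]
    if np.any(arr <= 0):
        raise ValueError("contig lengths must be positive")
    half = arr.sum() / 2
    csum = np.cumsum(arr)
    return int(arr[np.searchsorted(csum, half)])


def qc_report(
    records: Sequence[AlignmentRecord],
    genome: GenomeSequence | None = None,
    contig_lengths: Sequence[int] | None = None,
    min_depth: int = 1,
) -> QCReport:
    mapping = sum(r.mapped for r in records) / len(records) if records else 0.0
    breadth = None
    if genome is not None:
        mapping, breadth = mapping_and_breadth(records, genome, min_depth)
    return QCReport(
        error_rate=error_rate(records),
        improper_pair_rate=improper_pair_rate(records),
        mapping_rate=mapping,
        breadth=breadth,
        n50=n50(contig_lengths) if contig_lengths is not None else None,
        n_records=len(records),
    )
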