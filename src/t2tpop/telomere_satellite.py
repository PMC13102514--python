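"""Telomere detection, satellite-monomer scanning, consensus and divergence.

Telomeres are maximal tandem runs of the canonical plant motif (5'-CCCTAAA /
3'-TTTAGGG) at chromosome termini. Satellite arrays (e.g. the 455-bp cowpea
centromeric monomer class) are located by scanning for monomer-sized hits at
an alignment-identity threshold (>=90% by default) in both orientations.
Monomer diversity is summarized by a majority-vote consensus over a star
alignment, per-copy variant counts against that consensus, and pairwise
identity statistics stratified within/among chromosomes and between genomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import edlib
import numpy as np
import pandas as pd

from .core_io import GenomeSequence, Interval, revcomp

__all__ = [
    "TelomereHit",
    "SatelliteHit",
    "MonomerRecord",
    "find_telomeres",
    "scan_satellite",
    "extract_monomers",
    "build_consensus",
    "count_variants",
    "pairwise_identity",
    "similarity_classes",
]

VALID = frozenset("ACGTN")


@dataclass(frozen=True)
class TelomereHit:
    chrom: str
    end_label: str  # "5prime" | "3prime"
    interval: Interval
    copies: int
    motif: str


@dataclass(frozen=True)
class SatelliteHit:
    chrom: str
    interval: Interval
    monomer_id: str
    identity: float
    orientation: str


@dataclass(frozen=True)
class MonomerRecord:
    """One satellite monomer copy with its provenance."""

    genome: str
    chrom: str
    interval: Interval
    sequence: str


# ---------------------------------------------------------------------------
# Telomeres


def _tandem_runs(seq: str, motif: str) -> list[tuple[int, int]]:
    """Maximal tandem runs of ``motif``: (start, full copy count)."""
    m = len(motif)
    runs = []
    i = 0
    n = len(seq)
    while i <= n - m:
        if seq.startswith(motif, i):
            k = 1
            while seq.startswith(motif, i + k * m):
                k += 1
            runs.append((i, k))
            i += k * m
        else:
            i += 1
    return runs


def find_telomeres(
    genome: GenomeSequence,
    motif: str = "CCCTAAA",
    min_copies: int = 4,
    terminal_window: int = 10_000,
) -> list[TelomereHit]:
    """Report the longest tandem motif run at each chromosome end.

    A 5' hit is a run of ``motif`` starting within ``terminal_window`` of the
    chromosome start; a 3' hit is a run of the reverse-complement motif
    ending within ``terminal_window`` of the chromosome end. Runs shorter
    than ``min_copies`` full copies are ignored; at most one hit per end
    (longest run, ties broken toward the terminus). Copy counts are full
    copies; partial edge copies are not counted.
    """
    if len(motif) < 5:
        raise ValueError("telomere motif must be at least 5 bp")
    if terminal_window < len(motif) * min_copies:
        raise ValueError("terminal window smaller than the minimum run length")
    hits: list[TelomereHit] = []
    rc = revcomp(motif)
    m = len(motif)
    for chrom in genome:
        seq = genome[chrom]
        L = len(seq)
        # 5' end: scan enough sequence that a run starting inside the window
        # can be followed to its full extent
        head = seq[: min(L, terminal_window + m * min_copies * 50)]
        cands = [
            (start, k)
            for start, k in _tandem_runs(head, motif)
            if k >= min_copies and start < terminal_window
        ]
        if cands:
            start, k = max(cands, key=lambda c: (c[1], -c[0]))
            hits.append(
                TelomereHit(
                    chrom, "5prime", Interval(chrom, start, start + k * m), k, motif
                )
            )
        # 3' end: runs of the reverse-complement motif ending near the end
        tail_len = min(L, terminal_window + m * min_copies * 50)
        tail = seq[L - tail_len :]
        offset = L - tail_len
        cands3 = [
            (offset + start, k)
            for start, k in _tandem_runs(tail, rc)
            if k >= min_copies and L - (offset + start + k * m) < terminal_window
        ]
        if cands3:
            start, k = max(cands3, key=lambda c: (c[1], c[0]))
            hits.append(
                TelomereHit(
                    chrom, "3prime", Interval(chrom, start, start + k * m), k, motif
                )
            )
    return hits


# ---------------------------------------------------------------------------
# Satellite scanning


def _alignment_identity(query: str, target: str) -> float:
    """BLAST-style identity of a global alignment: matches / alignment columns."""
    res = edlib.align(query, target, mode="NW", task="path")
    nice = edlib.getNiceAlignment(res, query, target)
    matched = nice["matched_aligned"]
    return matched.count("|") / len(matched)


def _iterative_scan(
    seq: str,
    monomer: str,
    min_identity: float,
    length_tol: float,
    offset: int,
    chrom: str,
    monomer_id: str,
) -> list[SatelliteHit]:
    """Greedy non-overlapping tiling: repeatedly take the best remaining hit
    (smallest edit distance, leftmost on ties), mask it, and stop once the
    best hit falls below the identity threshold."""
    m = len(monomer)
    max_k = max(1, int(np.ceil(m * (1 - min_identity) * 2)))
    lo_len, hi_len = int(m * (1 - length_tol)), int(np.ceil(m * (1 + length_tol)))
    work = seq
    queries = {"+": monomer, "-": revcomp(monomer)}
    hits: list[SatelliteHit] = []
    max_iter = 3 * (len(seq) // m + 2)
    for _ in range(max_iter):
        best = None  # (edit_distance, start, end, orientation)
        for orient, q in queries.items():
            res = edlib.align(q, work, mode="HW", task="locations", k=max_k)
            ed = res["editDistance"]
            if ed < 0:
                continue
            s, e = min(res["locations"])  # leftmost optimal location
            if best is None or (ed, s) < (best[0], best[1]):
                best = (ed, s, e + 1, orient)
        if best is None:
            break
        ed, s, e, orient = best
        span = work[s:e]
        ident = _alignment_identity(queries[orient], span)
        if ident < min_identity:
            break
        if lo_len <= len(span) <= hi_len:
            hits.append(
                SatelliteHit(
                    chrom,
                    Interval(chrom, offset + s, offset + e),
                    monomer_id,
                    ident,
                    orient,
                )
            )
        work = work[:s] + "N" * (e - s) + work[e:]
    hits.sort(key=lambda h: h.interval.start)
    return hits


def _seed_regions(seq: str, monomer: str, k: int = 16, step: int = 4) -> list[tuple[int, int]]:
    """Candidate array regions from exact k-mer seed matches (both strands)."""
    kmers = set()
    for strand in (monomer, revcomp(monomer)):
        for i in range(0, len(strand) - k + 1, step):
            kmers.add(strand[i : i + k])
    positions: list[int] = []
    for kmer in kmers:
        start = seq.find(kmer)
        while start != -1:
            positions.append(start)
            start = seq.find(kmer, start + 1)
    if not positions:
        return []
    positions.sort()
    m = len(monomer)
    regions = []
    reg_start = positions[0]
    prev = positions[0]
    for p in positions[1:]:
        if p - prev > 2 * m:
            regions.append((max(0, reg_start - m), min(len(seq), prev + 2 * m)))
            reg_start = p
        prev = p
    regions.append((max(0, reg_start - m), min(len(seq), prev + 2 * m)))
    return regions


def scan_satellite(
    genome: GenomeSequence,
    monomer: str,
    min_identity: float = 0.90,
    exact: bool = False,
    length_tol: float = 0.20,
    monomer_id: str = "monomer",
) -> list[SatelliteHit]:
    """Locate non-overlapping monomer-sized satellite hits at or above an
    identity threshold, in both orientations.

    The default mode seeds candidate regions with exact k-mer matches and
    scans only those; ``exact=True`` scans whole chromosomes exhaustively
    (the oracle mode — identical hit sets on sequences up to ~50 kb, just
    slower). Identity is matches / alignment columns of a global alignment
    against the monomer.
    """
    monomer = monomer.upper()
    if len(monomer) < 50:
        raise ValueError("satellite monomer must be at least 50 bp")
    bad = set(monomer) - VALID
    if bad:
        raise ValueError(f"monomer contains non-ACGTN characters: {sorted(bad)!r}")
    hits: list[SatelliteHit] = []
    for chrom in genome:
        seq = genome[chrom]
        if exact:
            hits.extend(
                _iterative_scan(
                    seq, monomer, min_identity, length_tol, 0, chrom, monomer_id
                )
            )
        else:
            for lo, hi in _seed_regions(seq, monomer):
                hits.extend(
                    _iterative_scan(
                        seq[lo:hi],
                        monomer,
                        min_identity,
                        length_tol,
                        lo,
                        chrom,
                        monomer_id,
                    )
                )
    hits.sort(key=lambda h: (h.chrom, h.interval.start))
    return hits


def extract_monomers(
    genome: GenomeSequence, hits: Sequence[SatelliteHit], genome_id: str
) -> list[MonomerRecord]:
    """Pull monomer copy sequences (oriented to the monomer strand) out of a
    genome at satellite-hit coordinates."""
    out = []
    for h in hits:
        seq = genome.fetch(h.interval)
        if h.orientation == "-":
            seq = revcomp(seq)
        out.append(MonomerRecord(genome_id, h.chrom, h.interval, seq))
    return out


# ---------------------------------------------------------------------------
# Consensus and divergence

_BASE_ORDER = {"A": 0, "C": 1, "G": 2, "T": 3}


def build_consensus(monomers: Sequence[str]) -> str:
    """Column-wise majority consensus over a star alignment of the monomers.

    The medoid (copy minimizing total edit distance to a sample of the
    others) anchors the alignment; every monomer is globally aligned to it
    and its bases are projected onto medoid columns. Insertions relative to
    the medoid are ignored (they would be gap-majority columns). Majority
    ties are broken in fixed base order A<C<G<T; columns where gaps hold the
    strict majority are dropped.
    """
    seqs = [m.upper() for m in monomers]
    if len(seqs) < 2:
        raise ValueError("consensus requires at least 2 monomers")
    lens = [len(s) for s in seqs]
    if (max(lens) - min(lens)) / min(lens) > 0.5:
        raise ValueError(
            "monomer lengths differ by more than 50%; split into length classes "
            "before building a consensus"
        )
    sample = seqs if len(seqs) <= 30 else seqs[:: max(1, len(seqs) // 30)][:30]
    totals = [
        sum(edlib.align(s, t, mode="NW")["editDistance"] for t in sample)
        for s in seqs
    ]
    medoid = seqs[int(np.argmin(totals))]
    counts = np.zeros((len(medoid), 5), dtype=np.int64)  # A C G T gap
    for s in seqs:
        res = edlib.align(s, medoid, mode="NW", task="path")
        nice = edlib.getNiceAlignment(res, s, medoid)
        pos = 0
        for qc, tc in zip(nice["query_aligned"], nice["target_aligned"]):
            if tc == "-":
                continue  # insertion relative to the medoid
            idx = _BASE_ORDER.get(qc, 4)
            counts[pos, idx] += 1
            pos += 1
    consensus = []
    for row in counts:
        if row[4] > row[:4].sum():
            continue  # gap-majority column dropped
        consensus.append("ACGT"[int(np.argmax(row[:4]))])
    return "".join(consensus)


def count_variants(monomer: str, consensus: str) -> int:
    """Variant bases of a monomer relative to the consensus: mismatched
    aligned columns plus one variant per gap opening (a 2-bp deletion counts
    once)."""
    if not monomer or not consensus:
        raise ValueError("count_variants requires nonempty sequences")
    res = edlib.align(monomer.upper(), consensus.upper(), mode="NW", task="path")
    nice = edlib.getNiceAlignment(res, monomer.upper(), consensus.upper())
    q, t = nice["query_aligned"], nice["target_aligned"]
    variants = 0
    in_gap = False
    for qc, tc in zip(q, t):
        if qc == "-" or tc == "-":
            if not in_gap:
                variants += 1
                in_gap = True
        else:
            in_gap = False
            if qc != tc:
                variants += 1
    return variants


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment columns."""
    if not a or not b:
        raise ValueError("pairwise_identity requires nonempty sequences")
    return _alignment_identity(a.upper(), b.upper())


def similarity_classes(
    monomers: Sequence[MonomerRecord],
    cap: int = 1_800,
    max_pairs_per_stratum: int = 20_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Pairwise-identity summaries within-chromosome, among-chromosome (same
    genome) and between-genome.

    Monomers are first subsampled to ~``cap`` proportionally by chromosome
    (fixed seed); pairs within each stratum are then sampled up to
    ``max_pairs_per_stratum``. Strata with fewer than 2 monomers (no pairs)
    are omitted with a warning.
    """
    rng = np.random.default_rng(seed)
    if len(monomers) > cap:
        by_chrom: dict[tuple[str, str], list[MonomerRecord]] = {}
        for m in monomers:
            by_chrom.setdefault((m.genome, m.chrom), []).append(m)
        chosen: list[MonomerRecord] = []
        for key in sorted(by_chrom):
            grp = by_chrom[key]
            take = max(1, int(round(cap * len(grp) / len(monomers))))
            idx = rng.choice(len(grp), size=min(take, len(grp)), replace=False)
            chosen.extend(grp[i] for i in sorted(idx))
        monomers = chosen
    n = len(monomers)

    def stratum_of(i: int, j: int) -> str:
        a, b = monomers[i], monomers[j]
        if a.genome != b.genome:
            return "between-genome"
        if a.chrom != b.chrom:
            return "among-chromosome"
        return "within-chromosome"

    pairs: dict[str, list[tuple[int, int]]] = {
        "within-chromosome": [],
        "among-chromosome": [],
        "between-genome": [],
    }
    for i in range(n):
        for j in range(i + 1, n):
            pairs[stratum_of(i, j)].append((i, j))
    rows = []
    for stratum, plist in pairs.items():
        if not plist:
            warnings.warn(f"stratum {stratum!r} has <2 monomers; omitted")
            continue
        if len(plist) > max_pairs_per_stratum:
            idx = rng.choice(len(plist), size=max_pairs_per_stratum, replace=False)
            plist = [plist[i] for i in idx]
        idents = np.array(
            [
                pairwise_identity(monomers[i].sequence, monomers[j].sequence)
                for i, j in plist
            ]
        )
        rows.append(
            {
                "stratum": stratum,
                "n_monomers": n,
                "n_pairs": len(plist),
                "mean_identity": idents.mean(),
                "q25": np.quantile(idents, 0.25),
                "median": np.quantile(idents, 0.5),
                "q75": np.quantile(idents, 0.75),
            }
        )
    return pd.DataFrame(rows)
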