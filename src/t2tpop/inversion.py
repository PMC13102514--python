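"""Inversion detection from syntenic anchors and population-scale genotyping.

Detection looks for runs of reverse-oriented anchors in an anchor map (the
dot-plot "funnel" pattern), tolerating a little orientation noise. Genotyping
combines two signals per accession: breadth of short-read coverage over the
inversion on the reference assembly (carriers show voids, so breadth falls
below the >94% reference threshold) and clustering on PC1 of a PCA restricted
to SNPs inside the inversion. Discordant calls keep the coverage call and are
flagged for review.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .core_io import AnchorPair, GenotypeMatrix, Interval

__all__ = [
    "InversionCall",
    "Breakpoints",
    "CoverageProfile",
    "InversionGenotype",
    "detect_inversions",
    "define_breakpoints",
    "covered_fraction",
    "genotype_by_coverage",
    "pca_genotype",
    "reconcile",
    "group_carrier_frequencies",
]

REF, INV, NA = "REF", "INV", "NA"


@dataclass
class InversionCall:
    """An inversion inferred from a reverse-oriented anchor run."""

    id: str
    query: Interval
    target: Interval
    n_anchors: int
    orientation_consistency: float
    anchors: list[AnchorPair] = field(default_factory=list, repr=False)


@dataclass
class Breakpoints:
    """Fixed-width windows flanking the two inversion edges (outward by
    default), clipped at chromosome ends."""

    left: Interval | None
    right: Interval | None
    left_clipped: bool = False
    right_clipped: bool = False

    def intervals(self) -> list[Interval]:
        return [iv for iv in (self.left, self.right) if iv is not None]


@dataclass
class CoverageProfile:
    """Binned read depth for one accession over a region of a reference."""

    accession: str
    chrom: str
    start: int
    bin_size: int
    depths: np.ndarray
    reference: str = ""

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin size must be positive")
        self.depths = np.asarray(self.depths, dtype=float)
        if np.any(self.depths < 0):
            raise ValueError("depths must be non-negative")

    @property
    def end(self) -> int:
        return self.start + self.bin_size * len(self.depths)


@dataclass
class InversionGenotype:
    accession: str
    covered_fraction: float | None
    coverage_call: str
    pca_call: str
    final_call: str
    conflict: bool


def detect_inversions(
    anchors: Sequence[AnchorPair],
    min_anchors: int = 5,
    max_noise: int = 2,
) -> list[InversionCall]:
    """Find maximal runs of reverse-oriented anchors along the query.

    A run may bridge stretches of up to ``max_noise`` consecutive
    forward-oriented anchors; longer forward stretches split runs. Runs with
    fewer than ``min_anchors`` reverse anchors are discarded. Call bounds span
    the first to last reverse anchor of the run on both genomes.
    """
    srt = sorted(anchors, key=lambda a: (a.query.chrom, a.query.start))
    if list(srt) != list(anchors):
        warnings.warn("anchors were not sorted by query coordinate; sorted internally")
    calls: list[InversionCall] = []
    by_chrom: dict[str, list[AnchorPair]] = {}
    for a in srt:
        by_chrom.setdefault(a.query.chrom, []).append(a)
    counter = 0
    for chrom in sorted(by_chrom):
        chrom_anchors = by_chrom[chrom]
        run: list[AnchorPair] = []  # anchors from first to current reverse anchor
        pending = 0  # consecutive forward anchors since last reverse anchor

        def close(run: list[AnchorPair]) -> None:
            nonlocal counter
            minus = [a for a in run if a.orientation == "-"]
            if len(minus) < min_anchors:
                return
            counter += 1
            q_start = min(a.query.start for a in minus)
            q_end = max(a.query.end for a in minus)
            t_start = min(a.target.start for a in minus)
            t_end = max(a.target.end for a in minus)
            calls.append(
                InversionCall(
                    id=f"inv{counter}",
                    query=Interval(chrom, q_start, q_end),
                    target=Interval(minus[0].target.chrom, t_start, t_end),
                    n_anchors=len(minus),
                    orientation_consistency=len(minus) / len(run),
                    anchors=list(run),
                )
            )

        for a in chrom_anchors:
            if a.orientation == "-":
                run.append(a)
                pending = 0
            else:
                if run:
                    pending += 1
                    if pending > max_noise:
                        # trim bridged forward anchors off the tail
                        while run and run[-1].orientation == "+":
                            run.pop()
                        close(run)
                        run, pending = [], 0
                    else:
                        run.append(a)
        while run and run[-1].orientation == "+":
            run.pop()
        if run:
            close(run)
    return calls


def define_breakpoints(
    call: InversionCall | Interval,
    chrom_length: int,
    flank: int = 40_000,
    centered: bool = False,
) -> Breakpoints:
    """Breakpoint windows of ``flank`` bases at each inversion edge.

    By default each window extends outward from the edge; ``centered`` places
    it symmetrically across the edge instead. Windows are clipped at
    chromosome ends and the clipping is recorded.
    """
    if flank <= 0:
        raise ValueError("breakpoint flank must be positive")
    region = call.query if isinstance(call, InversionCall) else call
    if region.end > chrom_length:
        raise ValueError("inversion extends beyond chromosome end")
    if centered:
        l_lo, l_hi = region.start - flank // 2, region.start + flank // 2
        r_lo, r_hi = region.end - flank // 2, region.end + flank // 2
    else:
        l_lo, l_hi = region.start - flank, region.start
        r_lo, r_hi = region.end, region.end + flank
    left_clip = l_lo < 0
    right_clip = r_hi > chrom_length
    l_lo = max(0, l_lo)
    r_hi = min(chrom_length, r_hi)
    left = Interval(region.chrom, l_lo, l_hi) if l_lo < l_hi else None
    right = Interval(region.chrom, r_lo, r_hi) if r_lo < r_hi else None
    return Breakpoints(left, right, left_clip, right_clip)


def covered_fraction(
    profile: CoverageProfile,
    interval: Interval,
    min_depth: float = 1,
) -> float:
    """Fraction of bases in ``interval`` whose bin depth >= ``min_depth``,
    with partial bins weighted by their overlap."""
    if interval.chrom != profile.chrom:
        raise ValueError("interval chromosome does not match profile")
    if interval.start < profile.start or interval.end > profile.end:
        raise ValueError("interval extends outside the coverage profile")
    first = (interval.start - profile.start) // profile.bin_size
    last = (interval.end - 1 - profile.start) // profile.bin_size
    covered = 0.0
    for b in range(first, last + 1):
        b_start = profile.start + b * profile.bin_size
        b_end = b_start + profile.bin_size
        overlap = min(b_end, interval.end) - max(b_start, interval.start)
        if profile.depths[b] >= min_depth:
            covered += overlap
    return covered / len(interval)


def genotype_by_coverage(fraction: float, threshold: float = 0.94) -> str:
    """Reference genotype iff breadth strictly exceeds the threshold (the
    >94% rule); anything at or below it is called inverted."""
    if not 0 <= fraction <= 1:
        raise ValueError("covered fraction must lie in [0,1]")
    return REF if fraction > threshold else INV


def pca_genotype(
    gm: GenotypeMatrix,
    inversion: Interval | None = None,
    coverage_calls: Mapping[str, str] | None = None,
    random_state: int = 0,
) -> tuple[dict[str, str], np.ndarray]:
    """Genotype the inversion by clustering accessions on PC1 of a PCA over
    inversion-region SNPs.

    Genotypes are mean-imputed, centered and scaled by site standard
    deviation (zero-variance sites dropped). Accessions are split by 1-D
    two-means on PC1; the cluster labeling that best agrees with the coverage
    calls (when supplied) is kept, otherwise the larger cluster is labeled
    REF. Returns the per-accession calls and the per-PC variance fractions.
    """
    sub = gm.sites_in(inversion) if inversion is not None else gm
    X = sub.matrix().astype(float).T  # accessions x sites
    n, p = X.shape
    if n < 2 or p == 0:
        return {s: NA for s in gm.samples}, np.array([])
    # mean-impute missing, then drop monomorphic sites
    for j in range(p):
        col = X[:, j]
        miss = col < 0
        if miss.all():
            col[:] = 0.0
        elif miss.any():
            col[miss] = col[~miss].mean()
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.any():
        return {s: NA for s in gm.samples}, np.array([])
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    # full spectrum so variance fractions sum to 1
    U, S, _ = np.linalg.svd(Xs, full_matrices=False)
    var = S**2
    var_frac = var / var.sum()
    pc1 = U[:, 0] * S[0]
    km = KMeans(n_clusters=2, n_init=10, random_state=random_state).fit(
        pc1.reshape(-1, 1)
    )
    labels = km.labels_
    candidates = [
        {0: REF, 1: INV},
        {0: INV, 1: REF},
    ]
    if coverage_calls:
        best, best_score = None, -1
        for mapping in candidates:
            score = sum(
                1
                for s, lab in zip(gm.samples, labels)
                if coverage_calls.get(s) == mapping[lab]
            )
            if score > best_score:
                best, best_score = mapping, score
        mapping = best
    else:
        big = 0 if (labels == 0).sum() >= (labels == 1).sum() else 1
        mapping = {big: REF, 1 - big: INV}
    calls = {s: mapping[lab] for s, lab in zip(gm.samples, labels)}
    return calls, var_frac


def reconcile(
    coverage_calls: Mapping[str, str],
    pca_calls: Mapping[str, str],
    covered_fractions: Mapping[str, float] | None = None,
) -> list[InversionGenotype]:
    """Combine coverage and PCA calls into final genotypes.

    Concordant calls pass through. Discordant calls keep the coverage call
    (the primary signal) with the conflict flag set, replacing the study's
    manual review step with an explicit report. Accessions present in only
    one input are called NA with a warning.
    """
    out: list[InversionGenotype] = []
    all_accs = list(dict.fromkeys(list(coverage_calls) + list(pca_calls)))
    for acc in all_accs:
        cov = coverage_calls.get(acc)
        pca = pca_calls.get(acc)
        if cov is None or pca is None:
            warnings.warn(f"accession {acc} present in only one genotyping input")
            out.append(
                InversionGenotype(acc, None, cov or NA, pca or NA, NA, conflict=False)
            )
            continue
        conflict = pca != NA and cov != pca
        out.append(
            InversionGenotype(
                accession=acc,
                covered_fraction=(
                    covered_fractions.get(acc) if covered_fractions else None
                ),
                coverage_call=cov,
                pca_call=pca,
                final_call=cov,
                conflict=conflict,
            )
        )
    return out


def group_carrier_frequencies(
    genotypes: Sequence[InversionGenotype],
    groups: Mapping[str, str],
) -> dict[str, float]:
    """Per-group frequency of the inverted (INV) final call among called
    accessions."""
    counts: dict[str, list[int]] = {}
    for g in genotypes:
        if g.final_call == NA:
            continue
        grp = groups.get(g.accession)
        if grp is None:
            continue
        tally = counts.setdefault(grp, [0, 0])
        tally[1] += 1
        if g.final_call == INV:
            tally[0] += 1
    return {grp: inv / tot for grp, (inv, tot) in counts.items() if tot > 0}
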