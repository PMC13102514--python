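"""Variant filtering, sliding-window pi and F_ST, and population PCA.

Hard filters follow the GATK convention (a site is removed when ANY
criterion fires; missing annotations never fire). Windowed nucleotide
diversity and F_ST follow the VCFtools conventions: per-site pi summed over
a window and divided by window length, and the Weir & Cockerham (1984)
two-population estimator combined over a window as sum(a)/sum(a+b+c).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core_io import GenotypeMatrix, Interval, VariantRecord

__all__ = [
    "HardFilterThresholds",
    "WindowStat",
    "apply_hard_filters",
    "maf_missing_filter",
    "window_pi",
    "window_fst",
    "site_fst_components",
    "population_pca",
]


@dataclass
class HardFilterThresholds:
    """Removal thresholds; a record is removed when any criterion fires.

    The rank-sum criteria default to the GATK convention (remove when
    MQRankSum <= -12.5 or ReadPosRankSum <= -8.0). ``literal_ranksum=True``
    applies the thresholds as +12.5/+8.0 instead — the literal reading of
    the filter expression, which would remove nearly every site.
    """

    qd_min: float = 2.0
    qual_min: float = 30.0
    sor_max: float = 3.0
    fs_max: float = 60.0
    mq_min: float = 40.0
    mqranksum_min: float = -12.5
    readposranksum_min: float = -8.0
    literal_ranksum: bool = False

    def criteria(self):
        mqrs = 12.5 if self.literal_ranksum else self.mqranksum_min
        rprs = 8.0 if self.literal_ranksum else self.readposranksum_min
        return [
            ("QD", lambda r: _info(r, "QD") is not None and _info(r, "QD") < self.qd_min),
            ("QUAL", lambda r: r.qual is not None and r.qual < self.qual_min),
            ("SOR", lambda r: _info(r, "SOR") is not None and _info(r, "SOR") > self.sor_max),
            ("FS", lambda r: _info(r, "FS") is not None and _info(r, "FS") > self.fs_max),
            ("MQ", lambda r: _info(r, "MQ") is not None and _info(r, "MQ") < self.mq_min),
            ("MQRankSum", lambda r: _info(r, "MQRankSum") is not None and _info(r, "MQRankSum") <= mqrs),
            ("ReadPosRankSum", lambda r: _info(r, "ReadPosRankSum") is not None and _info(r, "ReadPosRankSum") <= rprs),
        ]


def _info(rec: VariantRecord, key: str) -> float | None:
    val = rec.info.get(key)
    if val is None:
        return None
    try:
        return float(val)
    except (TypeError, ValueError):
        import warnings

        warnings.warn(
            f"non-numeric {key} annotation at {rec.chrom}:{rec.pos}; treated as missing"
        )
        return None


@dataclass
class WindowStat:
    chrom: str
    window: Interval
    statistic: str  # "pi" | "fst"
    value: float | None
    n_sites: int


def apply_hard_filters(
    records: Sequence[VariantRecord],
    thresholds: HardFilterThresholds | None = None,
) -> tuple[list[VariantRecord], list[VariantRecord], dict[str, int]]:
    """Split records into (kept, removed) under the hard-filter disjunction,
    with per-criterion removal counts (a record can fire several)."""
    thresholds = thresholds or HardFilterThresholds()
    criteria = thresholds.criteria()
    kept, removed = [], []
    counts = {name: 0 for name, _ in criteria}
    for rec in records:
        fired = False
        for name, crit in criteria:
            if crit(rec):
                counts[name] += 1
                fired = True
        (removed if fired else kept).append(rec)
    return kept, removed, counts


def maf_missing_filter(
    gm: GenotypeMatrix,
    maf: float = 0.03,
    max_missing: float = 0.1,
) -> GenotypeMatrix:
    """Keep sites with minor-allele frequency >= ``maf`` (inclusive, over
    non-missing alleles) and missing-genotype fraction <= ``max_missing``.
    Fully missing sites are removed."""
    keep = []
    for rec in gm.records:
        g = rec.genotypes
        miss = g < 0
        n_called = int((~miss).sum())
        if n_called == 0:
            keep.append(False)
            continue
        miss_frac = miss.mean()
        alt = int(g[~miss].sum())
        total = 2 * n_called
        freq = alt / total
        site_maf = min(freq, 1 - freq)
        keep.append(site_maf >= maf and miss_frac <= max_missing)
    return gm.subset_sites(keep)


def _windows(positions: np.ndarray, chrom_length: int | None, window: int, step: int):
    upper = chrom_length if chrom_length is not None else (
        int(positions.max()) + 1 if len(positions) else window
    )
    start = 0
    while start < upper:
        yield start, min(start + window, upper)
        start += step


def window_pi(
    gm: GenotypeMatrix,
    group: Sequence[str],
    window: int = 50_000,
    step: int | None = None,
    chrom_length: int | None = None,
    per_site: bool = False,
) -> list[WindowStat]:
    """Windowed nucleotide diversity for one group of accessions.

    Per site, pi = 2*c_ref*c_alt / (n*(n-1)) over non-missing allele counts;
    window pi sums sites and divides by window length (monomorphic bases
    contribute zero). ``per_site=True`` divides by the number of variant
    sites instead.
    """
    if not group:
        raise ValueError("group accession list is empty")
    idx = [gm.samples.index(s) for s in group]
    out: list[WindowStat] = []
    by_chrom: dict[str, list[VariantRecord]] = {}
    for rec in gm.records:
        by_chrom.setdefault(rec.chrom, []).append(rec)
    step = step or window
    for chrom in sorted(by_chrom):
        recs = sorted(by_chrom[chrom], key=lambda r: r.pos)
        positions = np.array([r.pos for r in recs])
        site_pi = np.empty(len(recs))
        for i, rec in enumerate(recs):
            g = rec.genotypes[idx]
            g = g[g >= 0]
            n = 2 * len(g)
            c_alt = int(g.sum())
            c_ref = n - c_alt
            site_pi[i] = (2 * c_ref * c_alt) / (n * (n - 1)) if n > 1 else 0.0
        for lo, hi in _windows(positions, chrom_length, window, step):
            in_win = (positions >= lo) & (positions < hi)
            n_sites = int(in_win.sum())
            total = float(site_pi[in_win].sum())
            denom = n_sites if per_site else (hi - lo)
            value = total / denom if denom > 0 else 0.0
            out.append(WindowStat(chrom, Interval(chrom, lo, hi), "pi", value, n_sites))
    return out


def site_fst_components(
    g1: np.ndarray, g2: np.ndarray
) -> tuple[float, float, float]:
    """Weir & Cockerham (1984) variance components (a, b, c) for one
    biallelic site and two populations of diploids.

    ``g1``/``g2`` are dosage vectors {0,1,2} with -1 missing. Returns zeros
    for sites that are monomorphic across both groups or lack data.
    """
    g1 = g1[g1 >= 0]
    g2 = g2[g2 >= 0]
    n1, n2 = len(g1), len(g2)
    if n1 < 1 or n2 < 1 or n1 + n2 < 2:
        return 0.0, 0.0, 0.0
    r = 2
    p1 = g1.sum() / (2 * n1)
    p2 = g2.sum() / (2 * n2)
    h1 = (g1 == 1).mean()
    h2 = (g2 == 1).mean()
    nbar = (n1 + n2) / r
    if nbar <= 1:
        return 0.0, 0.0, 0.0
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    ssq = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    if pbar <= 0 or pbar >= 1:
        return 0.0, 0.0, 0.0
    a = (nbar / nc) * (
        ssq - (pbar * (1 - pbar) - (r - 1) / r * ssq - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * ssq - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return float(a), float(b), float(c)


def window_fst(
    gm: GenotypeMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    window: int = 50_000,
    step: int | None = None,
    chrom_length: int | None = None,
) -> list[WindowStat]:
    """Windowed Weir & Cockerham F_ST between two groups: sum(a) over
    sum(a+b+c) across sites in each window (the ratio-of-sums, VCFtools
    weighted convention). Windows without polymorphic sites report None."""
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 accessions")
    ia = [gm.samples.index(s) for s in group_a]
    ib = [gm.samples.index(s) for s in group_b]
    out: list[WindowStat] = []
    by_chrom: dict[str, list[VariantRecord]] = {}
    for rec in gm.records:
        by_chrom.setdefault(rec.chrom, []).append(rec)
    step = step or window
    for chrom in sorted(by_chrom):
        recs = sorted(by_chrom[chrom], key=lambda r: r.pos)
        positions = np.array([r.pos for r in recs])
        comps = np.array(
            [
                site_fst_components(rec.genotypes[ia], rec.genotypes[ib])
                for rec in recs
            ]
        )
        for lo, hi in _windows(positions, chrom_length, window, step):
            in_win = (positions >= lo) & (positions < hi)
            n_sites = int(in_win.sum())
            a_sum = comps[in_win, 0].sum() if n_sites else 0.0
            denom = comps[in_win].sum() if n_sites else 0.0
            value = float(a_sum / denom) if denom != 0 else None
            out.append(
                WindowStat(chrom, Interval(chrom, lo, hi), "fst", value, n_sites)
            )
    return out


def population_pca(
    gm: GenotypeMatrix, n_components: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the accession x site dosage matrix.

    Sites are mean-imputed for missing calls, centered, and scaled by their
    standard deviation; zero-variance sites are dropped. Returns accession
    coordinates and per-PC variance fractions (full spectrum, summing to 1).
    """
    X = gm.matrix().astype(float).T
    n, p = X.shape
    if n < 2 or p < 1:
        raise ValueError("PCA requires >=2 accessions and >=1 site")
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
        raise ValueError("all sites are monomorphic")
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    U, S, _ = np.linalg.svd(Xs, full_matrices=False)
    var = S**2
    var_frac = var / var.sum()
    coords = U * S
    if n_components is not None:
        coords = coords[:, :n_components]
    return coords, var_frac
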