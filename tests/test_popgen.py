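"""Hard filters, MAF/missingness, windowed pi and F_ST, population PCA."""

import numpy as np
import pytest

from t2tpop.core_io import GenotypeMatrix, Interval, VariantRecord
from t2tpop.popgen import (
    HardFilterThresholds,
    apply_hard_filters,
    maf_missing_filter,
    population_pca,
    site_fst_components,
    window_fst,
    window_pi,
)
from t2tpop.synthetic_data import simulate_variant_annotations


def make_site(genos, pos=0, chrom="c", **info):
    qual = info.pop("qual", 1000.0)
    return VariantRecord(chrom, pos, "A", "T", qual=qual, info=info,
                         genotypes=np.array(genos, dtype=np.int8))


def filter_oracle(rec, literal=False):
    """Brute-force evaluation of the removal disjunction."""
    mqrs_thr = 12.5 if literal else -12.5
    rprs_thr = 8.0 if literal else -8.0
    g = rec.info.get
    checks = [
        g("QD") is not None and g("QD") < 2.0,
        rec.qual is not None and rec.qual < 30.0,
        g("SOR") is not None and g("SOR") > 3.0,
        g("FS") is not None and g("FS") > 60.0,
        g("MQ") is not None and g("MQ") < 40.0,
        g("MQRankSum") is not None and g("MQRankSum") <= mqrs_thr,
        g("ReadPosRankSum") is not None and g("ReadPosRankSum") <= rprs_thr,
    ]
    return any(checks)


class TestHardFilters:
    def test_low_qd_removed_with_criterion_recorded(self):
        rec = make_site([0, 1], QD=1.5, SOR=1.0, FS=5.0, MQ=60.0,
                        MQRankSum=0.0, ReadPosRankSum=0.0)
        kept, removed, counts = apply_hard_filters([rec])
        assert removed == [rec] and counts["QD"] == 1

    def test_all_passing_kept(self):
        rec = make_site([0, 1], QD=20.0, SOR=1.0, FS=5.0, MQ=60.0,
                        MQRankSum=0.0, ReadPosRankSum=0.0)
        kept, removed, _ = apply_hard_filters([rec])
        assert kept == [rec] and not removed

    def test_missing_annotations_never_fire(self):
        rec = make_site([0, 1])  # no INFO at all
        kept, removed, _ = apply_hard_filters([rec])
        assert kept == [rec]

    def test_random_records_match_disjunction_oracle(self):
        records = simulate_variant_annotations(100, seed=5)
        kept, removed, _ = apply_hard_filters(records)
        expected_kept = [r for r in records if not filter_oracle(r)]
        assert kept == expected_kept
        assert len(kept) + len(removed) == 100

    def test_idempotent(self):
        records = simulate_variant_annotations(100, seed=6)
        kept, _, _ = apply_hard_filters(records)
        kept2, removed2, _ = apply_hard_filters(kept)
        assert kept2 == kept and not removed2

    def test_literal_ranksum_reading_available(self):
        rec = make_site([0, 1], QD=20.0, SOR=1.0, FS=5.0, MQ=60.0,
                        MQRankSum=5.0, ReadPosRankSum=5.0)
        kept, _, _ = apply_hard_filters([rec])
        assert kept  # GATK-convention default keeps it
        kept_lit, _, _ = apply_hard_filters(
            [rec], HardFilterThresholds(literal_ranksum=True))
        assert not kept_lit  # literal reading removes nearly everything


class TestMafMissing:
    def make_gm(self, genos):
        return GenotypeMatrix([f"s{i}" for i in range(len(genos[0]))],
                              [make_site(g, pos=i) for i, g in enumerate(genos)])

    def test_common_site_kept(self):
        gm = self.make_gm([[0, 0, 2, 2]])
        assert maf_missing_filter(gm).n_sites == 1

    def test_boundary_maf_inclusive(self):
        # 50 diploids, 3 alt alleles of 100 -> MAF exactly 0.03
        g = [0] * 47 + [1] * 3
        assert maf_missing_filter(self.make_gm([g]), maf=0.03).n_sites == 1
        # 2 alt alleles of 100 -> MAF 0.02, removed
        g2 = [0] * 48 + [1] * 2
        assert maf_missing_filter(self.make_gm([g2]), maf=0.03).n_sites == 0

    def test_missingness_bound(self):
        g = [0, 2, 1, -1, -1]  # 40% missing
        assert maf_missing_filter(self.make_gm([g]), max_missing=0.1).n_sites == 0
        assert maf_missing_filter(self.make_gm([g]), max_missing=0.5).n_sites == 1

    def test_all_missing_removed(self):
        assert maf_missing_filter(self.make_gm([[-1, -1, -1, -1]])).n_sites == 0


class TestWindowPi:
    def test_monomorphic_window_zero(self):
        gm = GenotypeMatrix(["a", "b"], [make_site([0, 0], pos=10)])
        stats = window_pi(gm, ["a", "b"], window=100, chrom_length=100)
        assert stats[0].value == 0.0

    def test_single_het_pair_toy(self):
        # one site, 2 haplotypes differing among n=2 alleles, window 100 bp
        gm = GenotypeMatrix(["a"], [make_site([1], pos=10)])
        stats = window_pi(gm, ["a"], window=100, chrom_length=100)
        assert stats[0].value == pytest.approx(0.01)

    def test_matches_pairwise_difference_oracle(self, rng):
        n_acc, n_sites, window = 12, 40, 2_000
        genos = rng.integers(0, 3, size=(n_sites, n_acc))
        positions = np.sort(rng.choice(window, size=n_sites, replace=False))
        gm = GenotypeMatrix(
            [f"s{i}" for i in range(n_acc)],
            [make_site(genos[i], pos=int(positions[i])) for i in range(n_sites)],
        )
        stats = window_pi(gm, gm.samples, window=window, chrom_length=window)
        # oracle: explicit mean pairwise difference among pooled alleles
        total = 0.0
        for i in range(n_sites):
            alleles = np.concatenate([[0] * (2 - g) + [1] * g for g in genos[i]])
            n = len(alleles)
            diffs = sum(alleles[a] != alleles[b]
                        for a in range(n) for b in range(a + 1, n))
            total += diffs / (n * (n - 1) / 2)
        assert stats[0].value == pytest.approx(total / window)


def wc_fst_oracle(genos1, genos2):
    """Independent Weir-Cockerham (1984) per-site computation written
    directly from allele and heterozygote counts."""
    g1, g2 = np.asarray(genos1), np.asarray(genos2)
    n1, n2 = len(g1), len(g2)
    p1, p2 = g1.sum() / (2 * n1), g2.sum() / (2 * n2)
    h1, h2 = np.mean(g1 == 1), np.mean(g2 == 1)
    nbar = (n1 + n2) / 2
    nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / 1
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
    hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
    a = nbar / nc * (s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - s2 / 2 - hbar / 4))
    b = nbar / (nbar - 1) * (pbar * (1 - pbar) - s2 / 2 - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


class TestWindowFst:
    def test_per_site_components_match_textbook_oracle(self):
        cases = [
            ([0, 1, 1, 2], [2, 2, 1, 2]),
            ([0, 0, 0, 1], [1, 2, 2, 2]),
            ([0, 1], [1, 2, 2]),
        ]
        for g1, g2 in cases:
            got = site_fst_components(np.array(g1, dtype=np.int8),
                                      np.array(g2, dtype=np.int8))
            expected = wc_fst_oracle(g1, g2)
            assert got == pytest.approx(expected)

    def test_fixed_differences_give_one(self):
        gm = GenotypeMatrix(
            ["a1", "a2", "b1", "b2"],
            [make_site([0, 0, 2, 2], pos=p) for p in (10, 20, 30)],
        )
        stats = window_fst(gm, ["a1", "a2"], ["b1", "b2"], window=100,
                           chrom_length=100)
        assert stats[0].value == pytest.approx(1.0)

    def test_equal_frequencies_give_nonpositive(self, rng):
        n = 20
        sites = []
        for p in range(30):
            g = rng.binomial(2, 0.5, size=2 * n)
            sites.append(make_site(g, pos=p * 10))
        gm = GenotypeMatrix([f"s{i}" for i in range(2 * n)], sites)
        a = gm.samples[:n]
        b = gm.samples[n:]
        stats = window_fst(gm, a, b, window=1_000, chrom_length=1_000)
        assert stats[0].value <= 0.05  # estimator noise around zero

    def test_symmetric_under_group_swap_and_order(self, rng):
        sites = [make_site(rng.integers(0, 3, size=10), pos=p * 10)
                 for p in range(20)]
        gm = GenotypeMatrix([f"s{i}" for i in range(10)], sites)
        a, b = gm.samples[:5], gm.samples[5:]
        v1 = window_fst(gm, a, b, window=500, chrom_length=500)[0].value
        v2 = window_fst(gm, b, a, window=500, chrom_length=500)[0].value
        v3 = window_fst(gm, a[::-1], b[::-1], window=500, chrom_length=500)[0].value
        assert v1 == pytest.approx(v2) == pytest.approx(v3)

    def test_empty_window_reported_na(self):
        gm = GenotypeMatrix(["a1", "a2", "b1", "b2"],
                            [make_site([0, 1, 1, 2], pos=10)])
        stats = window_fst(gm, ["a1", "a2"], ["b1", "b2"], window=100,
                           chrom_length=300)
        assert stats[1].value is None and stats[1].n_sites == 0


class TestPopulationPca:
    def test_duplicated_blocks_separate_on_pc1(self, rng):
        block_a = rng.integers(0, 3, size=50)
        block_b = 2 - block_a
        sites = [make_site(list(np.repeat([block_a[i], block_b[i]], 6)), pos=i)
                 for i in range(50)]
        gm = GenotypeMatrix([f"s{i}" for i in range(12)], sites)
        coords, var_frac = population_pca(gm)
        pc1 = coords[:, 0]
        assert (pc1[:6] > 0).all() != (pc1[6:] > 0).all()
        assert set(np.sign(pc1[:6])) != set(np.sign(pc1[6:]))

    def test_variance_fractions_normalized_and_sorted(self, rng):
        sites = [make_site(rng.integers(0, 3, size=15), pos=i) for i in range(40)]
        gm = GenotypeMatrix([f"s{i}" for i in range(15)], sites)
        _, var_frac = population_pca(gm)
        assert var_frac.sum() == pytest.approx(1.0)
        assert (np.diff(var_frac) <= 1e-12).all()
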