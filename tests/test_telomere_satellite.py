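"""Telomere runs, satellite scanning, consensus and identity statistics."""

import numpy as np
import pytest

from t2tpop.core_io import GenomeSequence, Interval, revcomp
from t2tpop.synthetic_data import mutate_sequence, random_sequence
from t2tpop.telomere_satellite import (
    MonomerRecord,
    build_consensus,
    count_variants,
    find_telomeres,
    pairwise_identity,
    scan_satellite,
    similarity_classes,
)

MOTIF = "CCCTAAA"


def nw_identity_oracle(a: str, b: str) -> float:
    """Independent unit-cost alignment DP with traceback; identity =
    matches / alignment columns of one optimal alignment."""
    n, m = len(a), len(b)
    D = np.zeros((n + 1, m + 1), dtype=int)
    D[:, 0] = np.arange(n + 1)
    D[0, :] = np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            D[i, j] = min(
                D[i - 1, j - 1] + (a[i - 1] != b[j - 1]),
                D[i - 1, j] + 1,
                D[i, j - 1] + 1,
            )
    i, j, matches, cols = n, m, 0, 0
    while i > 0 or j > 0:
        if i > 0 and j > 0 and D[i, j] == D[i - 1, j - 1] + (a[i - 1] != b[j - 1]):
            matches += a[i - 1] == b[j - 1]
            i, j = i - 1, j - 1
        elif i > 0 and D[i, j] == D[i - 1, j] + 1:
            i -= 1
        else:
            j -= 1
        cols += 1
    return matches / cols


class TestTelomeres:
    def test_constructed_caps_found_with_exact_copy_counts(self, rng):
        seq = MOTIF * 20 + random_sequence(rng, 1_000) + revcomp(MOTIF) * 20
        g = GenomeSequence({"c": seq})
        hits = find_telomeres(g, MOTIF, terminal_window=2_000)
        assert len(hits) == 2
        five, three = hits
        assert (five.end_label, five.copies, len(five.interval)) == ("5prime", 20, 140)
        assert (three.end_label, three.copies, len(three.interval)) == ("3prime", 20, 140)

    def test_motif_absent_gives_empty(self, rng):
        g = GenomeSequence({"c": random_sequence(rng, 5_000).replace("CCCT", "AAAA")})
        assert find_telomeres(g, MOTIF) == []

    def test_run_outside_terminal_window_ignored(self, rng):
        seq = random_sequence(rng, 15_000) + MOTIF * 20 + random_sequence(rng, 15_000)
        g = GenomeSequence({"c": seq})
        assert find_telomeres(g, MOTIF, terminal_window=10_000) == []

    def test_below_min_copies_ignored(self):
        g = GenomeSequence({"c": MOTIF * 3 + "G" * 500})
        assert find_telomeres(g, MOTIF, min_copies=4, terminal_window=1_000) == []

    def test_strand_symmetry(self, rng):
        seq = MOTIF * 15 + random_sequence(rng, 2_000) + revcomp(MOTIF) * 25
        g = GenomeSequence({"c": seq})
        g_rc = GenomeSequence({"c": revcomp(seq)})
        hits = {h.end_label: h for h in find_telomeres(g, MOTIF, terminal_window=3_000)}
        hits_rc = {h.end_label: h for h in find_telomeres(g_rc, MOTIF, terminal_window=3_000)}
        L = len(seq)
        # reverse-complementing swaps ends and mirrors coordinates
        assert hits["5prime"].copies == hits_rc["3prime"].copies
        assert hits["3prime"].copies == hits_rc["5prime"].copies
        assert hits_rc["3prime"].interval.end == L - hits["5prime"].interval.start
        assert hits_rc["5prime"].interval.start == L - hits["3prime"].interval.end


class TestSatelliteScan:
    def make_array(self, rng, monomer, mutated_copy=None, n=10):
        flank1, flank2 = random_sequence(rng, 2_000), random_sequence(rng, 2_000)
        copies = [monomer] * n
        if mutated_copy is not None:
            copies[n // 2] = mutated_copy
        return GenomeSequence({"c": flank1 + "".join(copies) + flank2})

    def test_perfect_copies_all_found_identity_one(self, rng):
        monomer = random_sequence(rng, 200)
        g = self.make_array(rng, monomer)
        hits = scan_satellite(g, monomer)
        assert len(hits) == 10
        assert all(h.identity == 1.0 for h in hits)
        assert hits[0].interval.start == 2_000 and hits[-1].interval.end == 4_000

    def test_degenerate_copy_below_threshold_excluded(self, rng):
        monomer = random_sequence(rng, 300)
        bad = mutate_sequence(rng, monomer, 0.15)
        while pairwise_identity(bad, monomer) > 0.88:
            bad = mutate_sequence(rng, monomer, 0.15)
        g = self.make_array(rng, monomer, mutated_copy=bad)
        hits = scan_satellite(g, monomer, min_identity=0.90)
        assert len(hits) == 9
        bad_span = Interval("c", 2_000 + 5 * 300, 2_000 + 6 * 300)
        assert not any(h.interval.overlaps(bad_span) for h in hits)

    def test_random_sequence_without_array_is_empty(self, rng):
        g = GenomeSequence({"c": random_sequence(rng, 20_000)})
        monomer = random_sequence(rng, 300)
        assert scan_satellite(g, monomer) == []

    def test_reverse_orientation_detected(self, rng):
        monomer = random_sequence(rng, 200)
        g = GenomeSequence(
            {"c": random_sequence(rng, 1_000) + revcomp(monomer) * 5 + random_sequence(rng, 1_000)}
        )
        hits = scan_satellite(g, monomer)
        assert len(hits) == 5 and all(h.orientation == "-" for h in hits)

    def test_seeded_and_exact_modes_agree(self, rng):
        monomer = random_sequence(rng, 250)
        copies = [mutate_sequence(rng, monomer, 0.03) for _ in range(30)]
        seq = (random_sequence(rng, 5_000) + "".join(copies[:15])
               + random_sequence(rng, 8_000) + "".join(copies[15:])
               + random_sequence(rng, 5_000))
        g = GenomeSequence({"c": seq})  # ~25 kb
        seeded = scan_satellite(g, monomer, exact=False)
        exact = scan_satellite(g, monomer, exact=True)
        assert [(h.interval, h.orientation) for h in seeded] == \
               [(h.interval, h.orientation) for h in exact]
        assert len(seeded) == 30

    def test_invalid_monomer_rejected(self, rng):
        g = GenomeSequence({"c": random_sequence(rng, 1_000)})
        with pytest.raises(ValueError, match="non-ACGTN"):
            scan_satellite(g, "ACGTRYSW" * 10)
        with pytest.raises(ValueError, match="at least 50"):
            scan_satellite(g, "ACGT")


class TestConsensus:
    def test_identical_monomers_return_monomer(self, rng):
        m = random_sequence(rng, 120)
        assert build_consensus([m] * 5) == m

    def test_single_substitution_outvoted(self, rng):
        m = random_sequence(rng, 120)
        mutated = ("A" if m[60] != "A" else "C") + m[61:]
        mutated = m[:60] + mutated
        assert build_consensus([m, m, mutated]) == m

    def test_majority_vote_recovers_true_monomer_at_two_percent(self, rng):
        m = random_sequence(rng, 455)
        copies = [mutate_sequence(rng, m, 0.02) for _ in range(100)]
        assert build_consensus(copies) == m

    def test_length_heterogeneity_rejected(self, rng):
        with pytest.raises(ValueError, match="length"):
            build_consensus([random_sequence(rng, 100), random_sequence(rng, 300)])


class TestVariantCounts:
    def test_identical_zero(self, rng):
        m = random_sequence(rng, 455)
        assert count_variants(m, m) == 0

    def test_three_substitutions(self, rng):
        m = random_sequence(rng, 200)
        sub = {"A": "C", "C": "G", "G": "T", "T": "A"}
        mutated = list(m)
        for i in (10, 80, 150):
            mutated[i] = sub[mutated[i]]
        assert count_variants("".join(mutated), m) == 3

    def test_deletion_counts_one_gap_opening_plus_mismatch(self):
        # one 2-bp deletion (a single gap opening) plus one substitution,
        # verified by hand alignment: ACGGTT--GATCCGAAAGCT
        consensus = "ACGGTTCAGATCCGTAAGCT"
        monomer = consensus[:6] + consensus[8:]  # drop "CA"
        monomer = monomer[:12] + "A" + monomer[13:]  # T -> A
        assert count_variants(monomer, consensus) == 2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            count_variants("", "ACGT")


class TestPairwiseIdentity:
    def test_identical_455mers(self, rng):
        m = random_sequence(rng, 455)
        assert pairwise_identity(m, m) == 1.0

    def test_single_mismatch_in_455(self, rng):
        m = random_sequence(rng, 455)
        other = m[:100] + ("A" if m[100] != "A" else "C") + m[101:]
        assert pairwise_identity(m, other) == pytest.approx(454 / 455)

    def test_matches_dp_oracle_on_random_pairs(self, rng):
        # co-optimal alignments can differ slightly in column count, so the
        # oracle comparison allows a small identity tolerance while the
        # underlying edit distance must agree exactly
        import edlib

        for _ in range(10):
            a = random_sequence(rng, 80)
            b = mutate_sequence(rng, a, 0.1)
            ed_impl = edlib.align(a, b, mode="NW")["editDistance"]
            n, m = len(a), len(b)
            D = np.zeros((n + 1, m + 1), dtype=int)
            D[:, 0], D[0, :] = np.arange(n + 1), np.arange(m + 1)
            for i in range(1, n + 1):
                for j in range(1, m + 1):
                    D[i, j] = min(D[i - 1, j - 1] + (a[i - 1] != b[j - 1]),
                                  D[i - 1, j] + 1, D[i, j - 1] + 1)
            assert ed_impl == D[n, m]
            assert pairwise_identity(a, b) == pytest.approx(
                nw_identity_oracle(a, b), abs=0.02
            )
        for _ in range(5):
            a = random_sequence(rng, 60)
            b = random_sequence(rng, 55)
            assert pairwise_identity(a, b) == pytest.approx(
                nw_identity_oracle(a, b), abs=0.05
            )


class TestSimilarityClasses:
    def make_monomers(self, rng, per_group=6, eps=0.0):
        base = random_sequence(rng, 150)
        out = []
        for genome in ("G1", "G2"):
            for chrom in ("c1", "c2"):
                chrom_base = mutate_sequence(rng, base, eps * 2)
                for i in range(per_group):
                    seq = mutate_sequence(rng, chrom_base, eps)
                    out.append(MonomerRecord(genome, chrom, Interval(chrom, i, i + 150), seq))
        return out

    def test_identical_monomers_give_mean_one_everywhere(self, rng):
        monomers = self.make_monomers(rng, eps=0.0)
        df = similarity_classes(monomers)
        assert set(df["stratum"]) == {"within-chromosome", "among-chromosome", "between-genome"}
        assert (df["mean_identity"] == 1.0).all()

    def test_within_chromosome_homogeneity_exceeds_among(self, rng):
        monomers = self.make_monomers(rng, eps=0.03)
        df = similarity_classes(monomers).set_index("stratum")
        assert (
            df.loc["within-chromosome", "mean_identity"]
            > df.loc["among-chromosome", "mean_identity"]
        )

    def test_subsampling_respects_cap(self, rng):
        monomers = self.make_monomers(rng, per_group=30)  # 120 monomers
        df = similarity_classes(monomers, cap=40, max_pairs_per_stratum=200)
        n = df["n_monomers"].iloc[0]
        assert abs(n - 40) <= 4
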