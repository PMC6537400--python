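"""hr palindrome detection, IUPAC consensus derivation, and the CNE scan."""

import numpy as np
import pytest

from baculoscan.genome_io import GenomeRecord, GenomeValidationError, reverse_complement
from baculoscan.repeat_elements import (
    HrRegion,
    PalindromeHit,
    build_consensus,
    cluster_into_hrs,
    consensus_stats,
    find_palindromes,
    hr_genome_fraction,
    load_reference_cne,
    scan_cne,
)
from baculoscan.genome_io import SequenceInterval
from baculoscan.synthetic import make_near_palindrome, random_dna


class TestFindPalindromes:
    def test_perfect_palindrome(self):
        hits = find_palindromes("GGATCC", word_length=6, max_mismatch=0)
        assert len(hits) == 1
        assert hits[0].self_complementary_pairs == 3

    def test_homopolymer_rejected(self):
        assert find_palindromes("AAAAAA", word_length=6, max_mismatch=0) == []

    def test_parameter_errors(self):
        with pytest.raises(ValueError):
            find_palindromes("ACGT", word_length=10)
        with pytest.raises(ValueError):
            find_palindromes("ACGTACGT", word_length=6, max_mismatch=3)

    def test_planted_recovery_and_scrambled_control(self):
        rng = np.random.default_rng(11)
        motif = make_near_palindrome(30, 0.4, rng)
        background = random_dna(2000, 0.4, rng)
        starts = [100, 450, 800, 1300, 1800]
        seq = list(background)
        planted = []
        for s in starts:
            copy = list(motif)
            for p in rng.choice(15, size=2, replace=False):  # breaks <= 2 pairs
                copy[p] = "ACGT"[(rng.integers(1, 4) + "ACGT".index(copy[p])) % 4]
            seq[s : s + 30] = copy
            planted.append("".join(copy))
        seq = "".join(seq)
        hits = find_palindromes(seq, 30, max_mismatch=2)
        hit_starts = {h.interval.start for h in hits}
        assert set(s + 1 for s in starts) <= hit_starts
        # scrambling each planted copy removes the signal
        scrambled = list(seq)
        for s, copy in zip(starts, planted):
            perm = rng.permutation(list(copy))
            scrambled[s : s + 30] = perm
        control = {h.interval.start for h in find_palindromes("".join(scrambled), 30, 2)}
        assert not (set(s + 1 for s in starts) & control)

    def test_revcomp_invariance(self):
        rng = np.random.default_rng(3)
        motif = make_near_palindrome(20, 0.4, rng)
        seq = random_dna(300, 0.4, rng) + motif + random_dna(300, 0.4, rng)
        fwd = find_palindromes(seq, 20, 1)
        rev = find_palindromes(reverse_complement(seq), 20, 1)
        L = len(seq)
        mirrored = {(L - h.interval.end + 1, L - h.interval.start + 1) for h in rev}
        assert {(h.interval.start, h.interval.end) for h in fwd} == mirrored


class TestClusterIntoHrs:
    def _hits(self, starts, w=30):
        return [
            PalindromeHit(SequenceInterval(s, s + w - 1), "A" * w, 15) for s in starts
        ]

    def test_single_cluster(self):
        hrs = cluster_into_hrs(self._hits([1000, 1130, 1260]), max_gap=500)
        assert len(hrs) == 1
        assert hrs[0].repeat_count == 3
        assert hrs[0].hr_id == "hr1"

    def test_distant_hits_split(self):
        hrs = cluster_into_hrs(self._hits([1000, 11_000]), max_gap=1000)
        assert [h.hr_id for h in hrs] == ["hr1", "hr2"]

    def test_min_repeats_filter(self):
        hrs = cluster_into_hrs(self._hits([1000, 1100, 9000]), max_gap=500, min_repeats=2)
        assert len(hrs) == 1 and hrs[0].repeat_count == 2

    def test_planted_clusters(self, small_genome):
        rec, truth = small_genome
        hrs = cluster_into_hrs(find_palindromes(rec.seq))
        assert len(hrs) == truth.n_hrs
        assert sum(h.repeat_count for h in hrs) == truth.n_repeats


class TestConsensus:
    def test_identical_repeats(self):
        m = build_consensus(["ACGT", "ACGT"])
        assert m.iupac == "ACGT" and m.unambiguous_positions == 4

    def test_threshold_rule(self):
        m = build_consensus(["ACGT", "ACGA"], inclusion_threshold=0.25)
        assert m.iupac == "ACGW"
        assert m.unambiguous_positions == 3

    def test_unequal_lengths_rejected(self):
        with pytest.raises(GenomeValidationError):
            build_consensus(["ACGT", "ACG"])

    def test_permutation_invariance(self, rng):
        reps = ["ACGTAC", "ACCTAC", "ATGTAC", "ACGTAA"]
        m1 = build_consensus(reps)
        m2 = build_consensus(list(rng.permutation(reps)))
        assert m1.iupac == m2.iupac

    def test_planted_motif_recovered_under_mutation(self):
        """Consensus over many lightly mutated copies reproduces the motif at
        every strong-majority column (per-column tally oracle)."""
        rng = np.random.default_rng(3)
        motif = make_near_palindrome(30, 0.4, rng)
        reps = []
        for _ in range(30):
            copy = list(motif)
            for i in range(30):
                if rng.random() < 0.05:
                    copy[i] = "ACGT"[(rng.integers(1, 4) + "ACGT".index(copy[i])) % 4]
            reps.append("".join(copy))
        m = build_consensus(reps, inclusion_threshold=0.125)
        counts = np.zeros((30, 4), int)
        for r in reps:
            for i, b in enumerate(r):
                counts[i, "ACGT".index(b)] += 1
        for i in range(30):
            if counts[i].max() / 30 >= 0.75:
                majority = "ACGT"[counts[i].argmax()]
                assert majority == motif[i]
                from baculoscan.repeat_elements import IUPAC_SET

                assert majority in IUPAC_SET[m.iupac[i]]


class TestConsensusStats:
    @pytest.mark.parametrize(
        "iupac, unamb, pairs",
        [
            ("NNNN", 0, 2),
            ("GGATCC", 6, 3),
            ("GHKTTACRAGTAGAATTCTACDNGTAAHVC", 23, 15),
        ],
    )
    def test_examples(self, iupac, unamb, pairs):
        st = consensus_stats(iupac)
        assert st["length"] == len(iupac)
        assert st["unambiguous_positions"] == unamb
        assert st["complementary_pairs"] == pairs

    def test_unambiguous_equals_length_minus_degenerate(self):
        # independent character-class table
        degenerate = set("RYSWKMBDHVN")
        for s in ("ACGT", "ARNT", "GHKTTACRAGTAGAATTCTACDNGTAAHVC"):
            st = consensus_stats(s)
            assert st["unambiguous_positions"] == len(s) - sum(
                1 for c in s if c in degenerate
            )

    def test_invalid_code(self):
        with pytest.raises(GenomeValidationError):
            consensus_stats("ACGE")


class TestHrGenomeFraction:
    def test_empty(self):
        assert hr_genome_fraction([], 100_000) == 0.0

    def test_arithmetic(self):
        hrs = []
        pos = 1000
        for i in range(3):
            reps = [
                PalindromeHit(SequenceInterval(pos + k * 100, pos + k * 100 + 29), "A" * 30, 15)
                for k in range(10)
            ]
            hrs.append(HrRegion(f"hr{i+1}", SequenceInterval(pos, pos + 929), reps))
            pos += 5000
        # 30 repeats x 30 bp on 125,477 bp
        assert hr_genome_fraction(hrs, 125_477) == pytest.approx(0.717, abs=5e-4)

    def test_overlapping_regions_rejected(self):
        r = [PalindromeHit(SequenceInterval(10, 39), "A" * 30, 15)]
        hrs = [
            HrRegion("hr1", SequenceInterval(10, 200), r),
            HrRegion("hr2", SequenceInterval(150, 400), r),
        ]
        with pytest.raises(GenomeValidationError):
            hr_genome_fraction(hrs, 1000)

    def test_planted_fraction(self, small_genome):
        rec, truth = small_genome
        hrs = cluster_into_hrs(find_palindromes(rec.seq))
        expected = truth.repeat_total_bp / rec.length * 100
        assert hr_genome_fraction(hrs, rec.length) == pytest.approx(expected)


class TestScanCne:
    def test_exact_copy(self):
        ref, _ = load_reference_cne()
        rng = np.random.default_rng(2)
        seq = random_dna(3000, 0.4, rng) + ref + random_dna(3000, 0.4, rng)
        match = scan_cne(GenomeRecord("g", seq), ref)
        assert match is not None
        assert match.identity_pct == pytest.approx(100.0)
        assert (match.interval.start, match.interval.end) == (3001, 3000 + len(ref))
        assert all(match.cluster_hits.values())

    def test_mutated_copy_identity(self):
        ref, _ = load_reference_cne()
        rng = np.random.default_rng(5)
        copy = list(ref)
        for p in rng.choice(len(ref), size=6, replace=False):
            copy[p] = "ACGT"[(rng.integers(1, 4) + "ACGT".index(copy[p])) % 4]
        seq = random_dna(2000, 0.4, rng) + "".join(copy) + random_dna(2000, 0.4, rng)
        match = scan_cne(GenomeRecord("g", seq), ref)
        assert match is not None
        assert match.identity_pct == pytest.approx((156 - 6) / 156 * 100, abs=0.1)
        assert match.interval.start == 2001

    def test_minus_strand_detection(self):
        ref, _ = load_reference_cne()
        rng = np.random.default_rng(8)
        seq = random_dna(1000, 0.4, rng) + reverse_complement(ref) + random_dna(1000, 0.4, rng)
        match = scan_cne(GenomeRecord("g", seq), ref)
        assert match is not None
        assert match.interval.strand == "-"
        assert match.identity_pct == pytest.approx(100.0)

    def test_absent_returns_none(self):
        rng = np.random.default_rng(9)
        assert scan_cne(GenomeRecord("g", random_dna(5000, 0.4, rng))) is None

    def test_planted_cne(self, small_genome):
        rec, truth = small_genome
        match = scan_cne(rec)
        assert match is not None
        assert match.interval.start == truth.cne_interval.start
        assert match.interval.end == truth.cne_interval.end
        assert match.identity_pct == pytest.approx(truth.cne_identity_pct, abs=0.1)
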