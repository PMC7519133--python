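"""Read matching: exact and identity-threshold regimes against brute force."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cqcov.matching import (ContigSet, ReadSet, count_exact, count_ident,
                            coverage_per_contig, decode, encode, revcomp)
from helpers import (brute_exact_counts, brute_ident_counts, planted_reads,
                     random_contigs)


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------


@settings(derandomize=True, max_examples=50)
@given(st.text(alphabet="ACGTN", min_size=1, max_size=80))
def test_encode_decode_roundtrip(seq):
    assert decode(encode(seq)) == seq


@settings(derandomize=True, max_examples=50)
@given(st.text(alphabet="ACGT", min_size=1, max_size=80))
def test_revcomp_involution(seq):
    codes = encode(seq)
    assert np.array_equal(revcomp(revcomp(codes)), codes)


# ---------------------------------------------------------------------------
# exact regime
# ---------------------------------------------------------------------------


class TestCountExact:
    def _count(self, read, contig, **kw):
        reads = ReadSet.from_sequences([read])
        contigs = ContigSet.from_records({"c": contig})
        return int(count_exact(reads, contigs, **kw).counts["c"])

    def test_direct_substring(self):
        # ACGTACGT is a reverse-complement palindrome: with both strands
        # searched the single offset carries one placement per strand
        assert self._count("ACGTACGT", "TTACGTACGTTT", both_strands=False) == 1
        assert self._count("ACGTACGT", "TTACGTACGTTT") == 2

    def test_single_mismatch_never_counts(self):
        assert self._count("ACGTACGA", "TTACGTACGTTT", both_strands=False) == 0

    def test_reverse_complement_placement(self):
        # revcomp(ACGTAACC) = GGTTACGT
        assert self._count("ACGTAACC", "TTGGTTACGTTT") == 1
        assert self._count("ACGTAACC", "TTGGTTACGTTT", both_strands=False) == 0

    def test_multiple_offsets_count_separately(self):
        # AACC at offsets 0 and 6; its reverse complement GGTT is absent
        assert self._count("AACC", "AACCTTAACC") == 2

    def test_palindromic_read_counts_both_strands(self):
        # ACGT equals its own reverse complement: each offset counts twice
        assert self._count("ACGT", "AAACGTAA") == 2
        assert self._count("ACGT", "AAACGTAA", both_strands=False) == 1

    def test_n_is_always_a_mismatch(self):
        assert self._count("ACGTN", "AAACGTNAA") == 0
        assert self._count("ACGTA", "AANCGTAAA") == 0

    def test_multi_contig_multi_counting(self):
        reads = ReadSet.from_sequences(["ACGTACGTAC"])
        contigs = ContigSet.from_records({
            "a": "TTACGTACGTACTT", "b": "ACGTACGTAC", "c": "GGGGGGGGGGGG"})
        counts = count_exact(reads, contigs).counts
        assert counts["a"] == 1 and counts["b"] == 1 and counts["c"] == 0
        assert count_exact(reads, contigs).library_total_reads == 1

    @pytest.mark.parametrize("trial", range(6))
    def test_agrees_with_bruteforce(self, trial):
        rng = np.random.default_rng(100 + trial)
        contigs = random_contigs(rng, 3, 400, with_n=trial % 2 == 1)
        reads = planted_reads(rng, contigs, 80, 30, max_mut=3)
        ours = count_exact(reads, contigs).counts.to_dict()
        assert ours == brute_exact_counts(reads, contigs)

    def test_invariant_under_contig_revcomp(self, rng):
        contigs = random_contigs(rng, 4, 500)
        reads = planted_reads(rng, contigs, 100, 40, max_mut=2)
        fwd = count_exact(reads, contigs).counts
        rc = count_exact(reads, contigs.reverse_complemented()).counts
        assert fwd.sum() == rc.sum()
        assert (fwd == rc).all()

    def test_empty_inputs_rejected(self, rng):
        contigs = random_contigs(rng, 1, 100)
        with pytest.raises(ValueError, match="empty"):
            count_exact(ReadSet(np.empty((0, 30), dtype=np.uint8)), contigs)


# ---------------------------------------------------------------------------
# identity regime
# ---------------------------------------------------------------------------


class TestCountIdent:
    def _mutated_read(self, rng, contig_codes, L, nmut):
        d = rng.integers(contig_codes.size - L + 1)
        codes = contig_codes[d : d + L].copy()
        pos = rng.choice(L, size=nmut, replace=False)
        codes[pos] = (codes[pos] + rng.integers(1, 4, size=nmut)) % 4
        return decode(codes)

    def test_mismatch_budget_boundary(self, rng):
        contigs = random_contigs(rng, 1, 2000)
        within = self._mutated_read(rng, contigs.seqs[0], 100, 15)
        beyond = self._mutated_read(rng, contigs.seqs[0], 100, 25)
        c_within = count_ident(ReadSet.from_sequences([within]), contigs, 0.8)
        c_beyond = count_ident(ReadSet.from_sequences([beyond]), contigs, 0.8)
        assert int(c_within.counts.sum()) == 1  # 15 <= floor(0.2 * 100)
        assert int(c_beyond.counts.sum()) == 0  # 25 > 20

    def test_best_placement_tie_breaks_to_lowest_name(self, rng):
        seq = decode(rng.integers(0, 4, 300).astype(np.uint8))
        contigs = ContigSet.from_records({"zz": seq, "aa": seq})
        read = seq[50:130]
        counts = count_ident(ReadSet.from_sequences([read]), contigs, 0.8)
        assert counts.counts["aa"] == 1 and counts.counts["zz"] == 0

    @pytest.mark.parametrize("method", ["qgram", "seed"])
    @pytest.mark.parametrize("trial", range(4))
    def test_agrees_with_bruteforce(self, trial, method):
        rng = np.random.default_rng(300 + trial)
        contigs = random_contigs(rng, 3, 350, with_n=trial % 2 == 1)
        max_mut = 7 if method == "qgram" else 1  # seed mode is complete below L//k
        reads = planted_reads(rng, contigs, 60, 40, max_mut=max_mut)
        ours = count_ident(reads, contigs, 0.8, method=method).counts.to_dict()
        assert ours == brute_ident_counts(reads, contigs, 0.8)

    def test_exact_match_survives_any_identity_bar(self, rng):
        # a read with an exact placement is placed at min_identity 1.0 and 0.8
        contigs = random_contigs(rng, 2, 500)
        reads = planted_reads(rng, contigs, 50, 40, max_mut=0)
        exact = count_exact(reads, contigs).counts
        strict = count_ident(reads, contigs, 1.0).counts
        loose = count_ident(reads, contigs, 0.8).counts
        placed_exact = int((exact > 0).sum())
        assert int(strict.sum()) >= placed_exact > 0
        assert int(loose.sum()) >= int(strict.sum())

    def test_invalid_identity_rejected(self, rng):
        contigs = random_contigs(rng, 1, 100)
        reads = planted_reads(rng, contigs, 5, 30, max_mut=0)
        with pytest.raises(ValueError, match="min_identity"):
            count_ident(reads, contigs, 0.0)


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------


class TestCoverage:
    def test_arithmetic_identity(self, rng):
        contigs = random_contigs(rng, 1, 10_000)
        reads = planted_reads(rng, contigs, 300, 100, max_mut=0)
        counts = count_exact(reads, contigs)
        cov = coverage_per_contig(counts)
        assert cov["c0"] == pytest.approx(counts.counts["c0"] * 100 / 10_000)

    def test_zero_alignments_zero_coverage(self, rng):
        contigs = ContigSet.from_records({"c": "A" * 200})
        reads = ReadSet.from_sequences(["G" * 50])
        assert coverage_per_contig(count_exact(reads, contigs))["c"] == 0.0

    def test_recovers_simulated_depth(self):
        from cqcov.simulate import (GenomeBlueprint, SampleSpec, SegmentSpec,
                                    build_genome, simulate_reads)
        bp = GenomeBlueprint([SegmentSpec("a", 50_000, "AUTOSOME")], seed=11)
        genome, truth = build_genome(bp)
        reads = simulate_reads(genome, truth, SampleSpec("m", "M", 30, 100, 0, seed=12))
        cov = coverage_per_contig(count_exact(reads, genome))["a"]
        lam = 30 * 50_000 / 100
        sigma_cov = np.sqrt(lam) * 100 / 50_000
        assert abs(cov - 30) <= 4 * sigma_cov

    def test_tsv_roundtrip(self, rng, tmp_path):
        from cqcov.matching import AlignmentCounts
        contigs = random_contigs(rng, 3, 300)
        reads = planted_reads(rng, contigs, 40, 50, max_mut=0)
        counts = count_exact(reads, contigs)
        counts.write_tsv(tmp_path / "counts.tsv")
        back = AlignmentCounts.read_tsv(tmp_path / "counts.tsv")
        assert back.counts.to_dict() == counts.counts.to_dict()
        assert back.library_total_reads == counts.library_total_reads
        assert back.regime == counts.regime
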