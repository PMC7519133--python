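"""Synthetic-data generator: determinism, copy-number structure, throughput."""

import logging

import numpy as np
import pandas as pd
import pytest

from cqcov.matching import ReadSet
from cqcov.simulate import (GenomeBlueprint, SampleSpec, SegmentSpec,
                            build_genome, make_anchor_table, read_origin,
                            simulate_contig_coverages, simulate_reads)


def _read_counts_by_contig(reads):
    counts: dict[str, int] = {}
    for name in reads.names:
        contig, _start, _strand = read_origin(name)
        counts[contig] = counts.get(contig, 0) + 1
    return counts


class TestBuildGenome:
    def test_basic_construction(self):
        bp = GenomeBlueprint([SegmentSpec("a", 1000, "AUTOSOME")], seed=1)
        genome, truth = build_genome(bp)
        assert genome.names == ["a"]
        assert genome.lengths.tolist() == [1000]
        assert len(truth) == 1
        assert truth.loc[0, "klass"] == "AUTOSOME"
        assert (truth.loc[0, "female_copies"], truth.loc[0, "male_copies"]) == (2, 2)

    def test_deterministic_fasta(self, tmp_path):
        bp = GenomeBlueprint([SegmentSpec("a", 2000, "AUTOSOME"),
                              SegmentSpec("b", 1500, "X_LINKED")], seed=9)
        for name in ("one.fasta", "two.fasta"):
            genome, _ = build_genome(bp)
            genome.to_fasta(tmp_path / name)
        assert (tmp_path / "one.fasta").read_bytes() == (tmp_path / "two.fasta").read_bytes()

    def test_pure_gc_composition(self):
        bp = GenomeBlueprint([SegmentSpec("a", 500, "AUTOSOME")],
                             base_composition=1.0, seed=2)
        genome, _ = build_genome(bp)
        assert set(np.unique(genome.seqs[0])) <= {1, 2}  # C and G only

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            GenomeBlueprint([SegmentSpec("a", 100, "AUTOSOME"),
                             SegmentSpec("a", 100, "AUTOSOME")], seed=0)

    def test_segment_validation(self):
        with pytest.raises(ValueError, match="length"):
            SegmentSpec("a", 0, "AUTOSOME")
        with pytest.raises(ValueError, match="y_leak"):
            SegmentSpec("a", 100, "AUTOSOME", y_leak=0.5)
        with pytest.raises(ValueError, match="class"):
            SegmentSpec("a", 100, "CHROMOSOME")


class TestSimulateReads:
    DEPTH = 30.0
    RL = 100

    @pytest.fixture
    def genome_truth(self, mixed_blueprint):
        return build_genome(mixed_blueprint)

    @pytest.mark.parametrize("sex_type,expected", [
        # expected reads = depth * length * copies/2 / read_length
        ("M", {"auto1": 3000, "xlin1": 1500, "ylin1": 1500, "dupc1": 6000}),
        ("TF", {"auto1": 3000, "xlin1": 3000, "ylin1": 0, "dupc1": 6000}),
    ])
    def test_copy_number_scaling(self, genome_truth, sex_type, expected):
        genome, truth = genome_truth
        spec = SampleSpec("s", sex_type, self.DEPTH, self.RL, 0.0, seed=42)
        reads = simulate_reads(genome, truth, spec)
        observed = _read_counts_by_contig(reads)
        for contig, lam in expected.items():
            obs = observed.get(contig, 0)
            if lam == 0:
                assert obs == 0  # zero-copy Y segments yield no female reads
            else:
                assert abs(obs - lam) <= 4 * np.sqrt(lam)

    def test_female_x_is_twice_male(self, genome_truth):
        genome, truth = genome_truth
        male = simulate_reads(genome, truth, SampleSpec("m", "M", 30, 100, 0, seed=1))
        female = simulate_reads(genome, truth, SampleSpec("f", "AF", 30, 100, 0, seed=2))
        m_x = _read_counts_by_contig(male)["xlin1"]
        f_x = _read_counts_by_contig(female)["xlin1"]
        # lambda_f = 2 * lambda_m = 3000; 4 sigma on the difference
        assert abs(f_x - 2 * m_x) <= 4 * np.sqrt(3000 + 4 * 1500)

    def test_y_leak_reads_confined_to_prefix(self):
        bp = GenomeBlueprint([SegmentSpec("y", 10_000, "Y_LINKED", y_leak=0.2),
                              SegmentSpec("a", 10_000, "AUTOSOME")], seed=3)
        genome, truth = build_genome(bp)
        reads = simulate_reads(genome, truth, SampleSpec("f", "TF", 30, 100, 0, seed=4))
        leak_len = 2000
        y_reads = [read_origin(n) for n in reads.names if read_origin(n)[0] == "y"]
        lam = 30 * leak_len * (2 / 2) / 100  # leak prefix at two copies
        assert abs(len(y_reads) - lam) <= 4 * np.sqrt(lam)
        assert all(start + 100 <= leak_len for _c, start, _s in y_reads)

    def test_throughput_conservation(self, genome_truth):
        genome, truth = genome_truth
        spec = SampleSpec("m", "M", 30, 100, 0.0, seed=5)
        reads = simulate_reads(genome, truth, spec)
        lam_total = sum(30 * l * c / 2 / 100 for l, c in
                        zip(truth["length"], truth["male_copies"]))
        total_bases = reads.n_reads * 100
        assert abs(total_bases - lam_total * 100) <= 4 * np.sqrt(lam_total) * 100

    def test_short_contig_warns_and_contributes_nothing(self, caplog):
        bp = GenomeBlueprint([SegmentSpec("tiny", 50, "AUTOSOME"),
                              SegmentSpec("big", 5000, "AUTOSOME")], seed=6)
        genome, truth = build_genome(bp)
        with caplog.at_level(logging.WARNING, logger="cqcov.simulate"):
            reads = simulate_reads(genome, truth, SampleSpec("m", "M", 30, 100, 0, seed=7))
        assert "tiny" in caplog.text
        assert all(read_origin(n)[0] != "tiny" for n in reads.names)

    def test_error_rate_perturbs_bases(self):
        # single contig: the rng stream up to the error draw is shared, so
        # clean and noisy libraries have identical placements
        bp = GenomeBlueprint([SegmentSpec("a", 40_000, "AUTOSOME")], seed=8)
        genome, truth = build_genome(bp)
        clean = simulate_reads(genome, truth, SampleSpec("m", "M", 10, 100, 0.0, seed=8))
        noisy = simulate_reads(genome, truth, SampleSpec("m", "M", 10, 100, 0.05, seed=8))
        assert clean.n_reads == noisy.n_reads
        frac = (clean.codes != noisy.codes).mean()
        assert 0.04 < frac < 0.06

    def test_fastq_roundtrip_and_determinism(self, genome_truth, tmp_path):
        genome, truth = genome_truth
        spec = SampleSpec("m", "M", 2, 100, 0.0, seed=9)
        reads = simulate_reads(genome, truth, spec)
        reads.to_fastq(tmp_path / "a.fastq")
        simulate_reads(genome, truth, spec).to_fastq(tmp_path / "b.fastq")
        assert (tmp_path / "a.fastq").read_bytes() == (tmp_path / "b.fastq").read_bytes()
        back = ReadSet.from_fastq(tmp_path / "a.fastq")
        assert np.array_equal(back.codes, reads.codes)
        assert back.names == reads.names


class TestAnchorTable:
    @pytest.fixture
    def truth(self):
        segs = [SegmentSpec(f"c{i}", 100, "AUTOSOME", muller_element="ABCDEF"[i % 6])
                for i in range(1000)]
        _genome, truth = build_genome(GenomeBlueprint(segs, seed=1))
        return truth

    def test_zero_mislabeling_is_identity(self, truth):
        table = make_anchor_table(truth, mislabel_rate=0.0)
        merged = table.merge(truth, left_on="contig", right_on="name")
        assert (merged["element"] == merged["muller_element"]).all()

    def test_full_mislabeling_matches_nothing(self, truth):
        table = make_anchor_table(truth, mislabel_rate=1.0, seed=2)
        merged = table.merge(truth, left_on="contig", right_on="name")
        assert not (merged["element"] == merged["muller_element"]).any()

    def test_mislabel_count_binomial(self, truth):
        table = make_anchor_table(truth, mislabel_rate=0.1, seed=3)
        merged = table.merge(truth, left_on="contig", right_on="name")
        wrong = int((merged["element"] != merged["muller_element"]).sum())
        sigma = np.sqrt(1000 * 0.1 * 0.9)
        assert abs(wrong - 100) <= 4 * sigma

    def test_invalid_element_rejected(self, truth):
        with pytest.raises(ValueError, match="A-F"):
            make_anchor_table(truth, elements={"c0": "G"})


def test_contig_coverage_model_doubles_on_duplications():
    segs = ([SegmentSpec(f"a{i}", 5000, "AUTOSOME") for i in range(100)]
            + [SegmentSpec(f"d{i}", 5000, "DUP_COLLAPSED") for i in range(100)])
    _genome, truth = build_genome(GenomeBlueprint(segs, seed=4))
    hist = simulate_contig_coverages(truth, SampleSpec("m", "M", 30, 100, 0, seed=5))
    auto = hist[hist["contig"].str.startswith("a")]["coverage"].mean()
    dup = hist[hist["contig"].str.startswith("d")]["coverage"].mean()
    assert dup / auto == pytest.approx(2.0, rel=0.05)
    assert auto == pytest.approx(30.0, rel=0.05)
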