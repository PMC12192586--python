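"""Alignment, pileup and diagnostic-position quantification."""

import random

import numpy as np
import pytest

from abotype import SimulationConfig, simulate_reads
from abotype.align import (
    AlignmentConfig,
    align_read,
    assign_reads,
    build_pileup,
    filter_reads,
    mean_quality,
    read_fastq,
    variant_profile,
    write_pileup_csv,
    write_sam,
)
from abotype.reference import (
    ALLELE_PATTERNS,
    ALLELES,
    DEL,
    DIAGNOSTIC_POSITIONS,
    EXON6_NAME,
    EXON7_NAME,
    allele_sequence,
)
from abotype.simulate import FastqRead, write_fastq

from _oracles import gotoh_local_score
from conftest import type_simulated


def _read(seq, name="r1", q="I"):
    return FastqRead(name, seq, q * len(seq))


class TestFastqInput:
    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.fastq"
        path.write_text("")
        assert read_fastq(path) == []

    def test_truncated_record_reports_index(self, tmp_path):
        path = tmp_path / "bad.fastq"
        path.write_text("@r0\nACGT\n+\nIIII\n@r1\nACGT\n+\nII\n")
        with pytest.raises(ValueError, match="index 1"):
            read_fastq(path)

    def test_simulator_output_round_trips(self, references, tmp_path):
        cfg = SimulationConfig(genotype=("A", "B"), n_reads=5, seed=8)
        reads = simulate_reads(cfg, references)["exon6"]
        path = tmp_path / "sim.fastq"
        write_fastq(reads, path)
        assert [r.sequence for r in read_fastq(path)] == [r.sequence for r in reads]


class TestReadFilter:
    def test_zero_thresholds_identity(self):
        reads = [_read("ACGT"), _read("A")]
        assert filter_reads(reads, 0, 0) == reads

    def test_length_filter(self):
        assert filter_reads([_read("A" * 50)], min_length=100) == []

    def test_mean_quality_filter(self):
        q20 = [_read("ACGT" * 10, q=chr(20 + 33)) for _ in range(10)]
        assert filter_reads(q20, min_mean_q=30) == []
        assert len(filter_reads(q20, min_mean_q=20)) == 10
        assert mean_quality(q20[0]) == pytest.approx(20.0)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            filter_reads([], min_length=-1)


class TestAlignRead:
    def test_perfect_read_full_identity(self, references):
        exon6 = references[0]
        aln = align_read(_read(exon6), exon6, EXON6_NAME)
        assert aln is not None
        assert aln.identity == 1.0
        assert aln.target_blocks == [(0, len(exon6))]
        assert aln.query_blocks == [(0, len(exon6))]

    def test_o1_deletion_lands_on_diagnostic_column(self, references):
        exon6 = references[0]
        o1_exon6, _ = allele_sequence("O1", references)
        aln = align_read(_read(o1_exon6), exon6, EXON6_NAME)
        assert aln is not None
        assert len(aln.target_blocks) == 2
        gap_start = aln.target_blocks[0][1]
        gap_end = aln.target_blocks[1][0]
        # single-base deletion at 1-based reference position 22
        assert (gap_start, gap_end) == (21, 22)

    def test_unrelated_read_discarded(self, references):
        rng = random.Random(1234)
        junk = "".join(rng.choice("ACGT") for _ in range(100))
        assert align_read(_read(junk), references[0], EXON6_NAME) is None

    def test_empty_input_rejected(self, references):
        with pytest.raises(ValueError):
            align_read(_read(""), references[0], EXON6_NAME)

    def test_alignment_deterministic(self, references):
        cfg = SimulationConfig(genotype=("B", "B"), n_reads=5, seed=3)
        reads = simulate_reads(cfg, references)["exon7"]
        for read in reads:
            a1 = align_read(read, references[1], EXON7_NAME)
            a2 = align_read(read, references[1], EXON7_NAME)
            assert a1.target_blocks == a2.target_blocks
            assert a1.query_blocks == a2.query_blocks
            assert a1.score == a2.score

    def test_score_matches_brute_force_oracle(self):
        # small random pairs, exhaustive DP oracle
        rng = random.Random(99)
        cfg = AlignmentConfig(min_identity=0.0, min_window_cov=0.0)
        for trial in range(50):
            ref = "".join(rng.choice("ACGT") for _ in range(rng.randint(10, 80)))
            read = "".join(rng.choice("ACGT") for _ in range(rng.randint(5, 60)))
            if trial % 2:  # make half the pairs related
                read = ref[: len(ref) // 2] + read[:10]
            aln = align_read(_read(read), ref, EXON6_NAME, cfg, window=(1, 1))
            expected = gotoh_local_score(ref, read)
            got = aln.score if aln is not None else 0.0
            assert got == pytest.approx(expected)


class TestPileup:
    def test_single_perfect_read(self, references):
        exon7 = references[1]
        aln = align_read(_read(exon7), exon7, EXON7_NAME)
        pileup = build_pileup([aln], exon7, EXON7_NAME)
        assert pileup.counts.sum() == len(exon7)
        for offset in (422, 428, 429, 431):
            col = pileup.column(offset)
            assert col.depth == 1
            assert col.counts[exon7[offset - 1]] == 1

    def test_heterozygous_deletion_counts(self, references):
        # 45 A-allele reads (G at 22) + 55 O1 reads (deletion) at zero error
        cfg = SimulationConfig(
            genotype=("A", "O1"), n_reads=100, allele_ratio=0.45,
            sub_rate=0, ins_rate=0, del_rate=0, seed=2,
        )
        reads = simulate_reads(cfg, references)["exon6"]
        refmap = {EXON6_NAME: references[0], EXON7_NAME: references[1]}
        alignments = assign_reads(reads, refmap)
        pileup = build_pileup(alignments[EXON6_NAME], references[0], EXON6_NAME)
        col = pileup.column(22)
        assert col.counts["G"] == 45
        assert col.counts[DEL] == 55
        assert col.depth == 100

    def test_no_alignments_empty_pileup(self, references):
        pileup = build_pileup([], references[0], EXON6_NAME)
        assert pileup.counts.sum() == 0
        assert pileup.column(22).depth == 0

    def test_conservation_counts_equal_aligned_span(self, references):
        cfg = SimulationConfig(genotype=("O1", "B"), n_reads=20, seed=5)
        reads = simulate_reads(cfg, references)["exon7"]
        refmap = {EXON6_NAME: references[0], EXON7_NAME: references[1]}
        alignments = assign_reads(reads, refmap)[EXON7_NAME]
        pileup = build_pileup(alignments, references[1], EXON7_NAME)
        # per column, depth equals the sum of counts by construction;
        # in total, every read contributes its aligned reference extent
        total_span = sum(a.reference_end - a.reference_start for a in alignments)
        assert pileup.counts.sum() == total_span

    def test_mismatched_reference_rejected(self, references):
        aln = align_read(_read(references[0]), references[0], EXON6_NAME)
        with pytest.raises(ValueError):
            build_pileup([aln], references[1], EXON7_NAME)


class TestVariantProfile:
    @pytest.mark.parametrize("allele", ALLELES)
    def test_zero_error_round_trip_recovers_pattern(self, references, allele):
        _, profile = type_simulated(
            (allele, allele), references, n_reads=25, seed=1,
            sub_rate=0.0, ins_rate=0.0, del_rate=0.0,
        )
        expected = dict(zip(DIAGNOSTIC_POSITIONS, ALLELE_PATTERNS[allele]))
        for pos, symbol in expected.items():
            assert profile.fractions[pos] == {symbol: 1.0}
            assert profile.depths[pos] == 25

    def test_fraction_arithmetic(self, references):
        cfg = SimulationConfig(
            genotype=("A", "O1"), n_reads=100, allele_ratio=0.45,
            sub_rate=0, ins_rate=0, del_rate=0, seed=2,
        )
        reads = simulate_reads(cfg, references)["exon6"]
        refmap = {EXON6_NAME: references[0], EXON7_NAME: references[1]}
        alignments = assign_reads(reads, refmap)
        pileups = {
            rid: build_pileup(alns, refmap[rid], rid)
            for rid, alns in alignments.items()
        }
        profile = variant_profile(pileups, "s")
        pos22 = DIAGNOSTIC_POSITIONS[0]
        assert profile.fractions[pos22] == pytest.approx({"G": 0.45, DEL: 0.55})

    def test_zero_depth_position_flagged(self, references):
        refmap = {EXON6_NAME: references[0], EXON7_NAME: references[1]}
        pileups = {
            rid: build_pileup([], refmap[rid], rid) for rid in refmap
        }
        profile = variant_profile(pileups, "empty")
        for pos in DIAGNOSTIC_POSITIONS:
            assert profile.fractions[pos] == {}
            assert profile.depths[pos] == 0


class TestExports:
    def test_sam_parses_with_pysam(self, references, tmp_path):
        pysam = pytest.importorskip("pysam")
        cfg = SimulationConfig(genotype=("A", "B"), n_reads=10, seed=3)
        reads = simulate_reads(cfg, references)
        refmap = {EXON6_NAME: references[0], EXON7_NAME: references[1]}
        alignments = assign_reads(reads["exon6"] + reads["exon7"], refmap)
        path = tmp_path / "aln.sam"
        write_sam(alignments, refmap, path)
        with pysam.AlignmentFile(str(path)) as sam:
            records = list(sam)
        assert len(records) == sum(len(v) for v in alignments.values())
        for rec in records:
            # CIGAR-consumed query length must equal the stored sequence
            assert rec.infer_read_length() == len(rec.query_sequence)

    def test_pileup_csv(self, references, tmp_path):
        import pandas as pd

        aln = align_read(_read(references[0]), references[0], EXON6_NAME)
        pileup = build_pileup([aln], references[0], EXON6_NAME)
        path = tmp_path / "pileup.csv"
        write_pileup_csv(pileup, path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["position", "A", "C", "G", "T", "DEL", "depth"]
        assert len(df) == len(references[0])
        assert df["depth"].sum() == len(references[0])
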