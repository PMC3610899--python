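import numpy as np
import pytest

from amplotype import (
    MotifConfig,
    SimulationConfig,
    clean_batch,
    default_motif_config,
    demultiplex,
    filter_blacklist,
    orient_and_trim,
    reverse_complement,
    simulate_cohort,
)
from conftest import make_read


@pytest.fixture
def small_config():
    # synthetic mini-locus: 6bp boundary motifs around a variable core
    return MotifConfig(
        start_motif="ATGCCA",
        end_motif="TTGACG",
        blacklist=("GGCCTAGC",),
        min_exon_length=10,
        max_exon_length=60,
    )


class TestDemultiplex:
    def test_exact_match_clips_barcode(self):
        reads = [make_read("AAAACGTT", read_id="x")]
        assigned, unassigned = demultiplex(reads, {"AAAA": "S1"})
        assert unassigned == 0
        assert assigned[0].subject_id == "S1"
        assert assigned[0].sequence == "CGTT"
        assert assigned[0].quals.tolist() == [40] * 4

    def test_unmatched_dropped(self):
        assigned, unassigned = demultiplex(
            [make_read("TTTTCGTT")], {"AAAA": "S1"}
        )
        assert assigned == [] and unassigned == 1

    def test_simulated_corrupt_barcodes_counted(self):
        cfg = SimulationConfig(
            allele_pairs={"S1": ("SYN*01:01:01", "SYN*02:01:01")},
            reads_per_subject=100,
            per_base_error=0.0,
            barcode_corrupt_fraction=0.1,
            seed=7,
        )
        reads, bmap, (truth,) = simulate_cohort(cfg)
        assigned, unassigned = demultiplex(reads, bmap)
        # barcodes are Hamming >= 3 apart: one corrupted base can never
        # hit another barcode, so attrition equals the planted count
        assert unassigned == truth.n_barcode_corrupted
        assert len(assigned) == 100 - truth.n_barcode_corrupted


class TestOrientAndTrim:
    def test_forward_trim(self, small_config):
        core = "ACGTACGTACGTACGT"
        read = make_read("NNN" + "ATGCCA" + core + "TTGACG" + "NN")
        out = orient_and_trim(read, small_config)
        assert out is not None
        assert out.sequence == "ATGCCA" + core + "TTGACG"
        assert out.strand == "forward"

    def test_reverse_strand_recovers_same_sequence(self, small_config):
        core = "ACGTACGTACGTACGT"
        fwd = make_read("ATGCCA" + core + "TTGACG")
        rev = make_read(reverse_complement(fwd.sequence))
        out_f = orient_and_trim(fwd, small_config)
        out_r = orient_and_trim(rev, small_config)
        assert out_r is not None
        assert out_r.sequence == out_f.sequence
        assert out_r.strand == "reverse"

    def test_missing_end_motif_rejected(self, small_config):
        read = make_read("ATGCCA" + "ACGT" * 5)
        assert orient_and_trim(read, small_config) is None

    def test_out_of_order_rejected(self, small_config):
        read = make_read("TTGACG" + "ACGT" * 4 + "ATGCCA")
        # end before start in forward; reverse complement has them in
        # order but trimmed length must still satisfy the bounds
        out = orient_and_trim(read, small_config)
        if out is not None:
            assert out.strand == "reverse"

    def test_length_bounds_rejected(self, small_config):
        read = make_read("ATGCCA" + "TTGACG")  # trimmed length 12 < ... ok
        cfg = MotifConfig(
            "ATGCCA", "TTGACG", (), min_exon_length=20, max_exon_length=60
        )
        assert orient_and_trim(read, cfg) is None

    def test_idempotent(self, small_config):
        read = make_read("NN" + "ATGCCA" + "ACGTACGTACGTACGT" + "TTGACG")
        once = orient_and_trim(read, small_config)
        twice = orient_and_trim(once, small_config)
        assert twice.sequence == once.sequence
        assert twice.quals.tolist() == once.quals.tolist()

    def test_strand_invariance_on_simulated_reads(self, motif_config):
        cfg = SimulationConfig(
            allele_pairs={"S1": ("SYN*03:01:01", "SYN*05:01:01")},
            reads_per_subject=30,
            per_base_error=0.0,
            seed=5,
        )
        reads, bmap, _ = simulate_cohort(cfg)
        assigned, _ = demultiplex(reads, bmap)
        for r in assigned:
            flipped = make_read(
                reverse_complement(r.sequence),
                quals=r.quals[::-1].copy(),
                read_id=r.read_id,
            )
            a = orient_and_trim(r, motif_config)
            b = orient_and_trim(flipped, motif_config)
            assert a is not None and b is not None
            assert a.sequence == b.sequence


class TestBlacklist:
    def test_planted_motif_removed(self, small_config):
        dirty = make_read("AAAA" + "GGCCTAGC" + "TTTT")
        clean = make_read("AAAATTTT")
        kept, removed = filter_blacklist([dirty, clean], small_config)
        assert removed == 1 and kept == [clean]

    def test_empty_blacklist_keeps_all(self):
        cfg = MotifConfig("ATGCCA", "TTGACG", ())
        reads = [make_read("GGCCTAGC")]
        kept, removed = filter_blacklist(reads, cfg)
        assert removed == 0 and kept == reads


class TestCleanBatch:
    def test_attrition_monotone_and_exact(self):
        cfg = SimulationConfig(
            allele_pairs={
                "S1": ("SYN*01:01:01", "SYN*04:01:01"),
                "S2": ("SYN*02:01:01", "SYN*07:01:01"),
            },
            reads_per_subject=100,
            per_base_error=0.0,
            contaminant_fraction=0.15,
            seed=9,
        )
        reads, bmap, truths = simulate_cohort(cfg)
        by_subject, log = clean_batch(reads, bmap, default_motif_config())
        counts = [log.counts[s] for s in
                  ("input", "demultiplexed", "trimmed", "blacklist_filtered")]
        assert counts == sorted(counts, reverse=True)
        planted = sum(t.n_contaminants for t in truths)
        assert counts[0] == 200
        assert counts[1] == 200          # no barcode corruption
        assert counts[2] == 200          # error-free: every read trims
        assert counts[3] == 200 - planted
        for t in truths:
            assert len(by_subject[t.subject_id]) == t.n_reads - t.n_contaminants

    def test_clean_input_no_losses(self):
        cfg = SimulationConfig(
            allele_pairs={"S1": ("SYN*01:01:01", "SYN*06:01:01")},
            reads_per_subject=50,
            per_base_error=0.0,
            seed=2,
        )
        reads, bmap, _ = simulate_cohort(cfg)
        _, log = clean_batch(reads, bmap, default_motif_config())
        assert len(set(log.counts.values())) == 1

    def test_empty_input(self, motif_config):
        by_subject, log = clean_batch([], {"AAAACCCC": "S1"}, motif_config)
        assert log.counts["input"] == 0
        assert by_subject == {"S1": []}
        assert log.empty_subjects == ["S1"]

    def test_log_tsv(self, tmp_path, motif_config):
        _, log = clean_batch([], {"AAAACCCC": "S1"}, motif_config)
        p = tmp_path / "attrition.tsv"
        log.write_tsv(p)
        assert p.read_text().startswith("stage\tcount\tfraction_of_input\n")
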