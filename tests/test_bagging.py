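import numpy as np
import pytest

from amplotype import (
    AggregateCall,
    AlleleCall,
    BaggingConfig,
    GenotypeReport,
    InsufficientReadsError,
    IterationResult,
    SimulationConfig,
    aggregate,
    call_genotype,
    clean_batch,
    default_motif_config,
    genotype_subject,
    run_iteration,
    score_genotypes,
    simulate_cohort,
    write_report,
)


def _subject_reads(pair, n_reads, error=0.0, minor=0.5, seed=0):
    cfg = SimulationConfig(
        allele_pairs={"S": pair},
        reads_per_subject=n_reads,
        per_base_error=error,
        minor_fraction=minor,
        seed=seed,
    )
    reads, bmap, _ = simulate_cohort(cfg)
    by_subject, _ = clean_batch(reads, bmap, default_motif_config())
    return by_subject["S"]


HET = ("SYN*01:01:01", "SYN*08:01:01")
HOM = ("SYN*03:01:01", "SYN*03:01:01")


class TestRunIteration:
    def test_exact_sample_size_uses_all_reads(self, library):
        reads = _subject_reads(HET, 20)
        cfg = BaggingConfig(iterations=1, sample_size=20, seed=5)
        res = run_iteration(reads, library, cfg, 0, "S")
        assert sum(c.cluster_size for c in res.calls) == len(reads)

    def test_balanced_heterozygote_error_free(self, library):
        reads = _subject_reads(HET, 60)
        cfg = BaggingConfig(iterations=1, sample_size=20, seed=5)
        res = run_iteration(reads, library, cfg, 0, "S")
        names = sorted(c.allele for c in res.calls)
        assert names == sorted(HET)
        for c in res.calls:
            assert c.identity_score == 100.0
            assert 1 <= c.cluster_size <= 19

    def test_homozygote_merges_to_single_call(self, library):
        reads = _subject_reads(HOM, 60)
        cfg = BaggingConfig(iterations=1, sample_size=20, seed=5)
        res = run_iteration(reads, library, cfg, 0, "S")
        assert len(res.calls) == 1
        assert res.calls[0].allele == HOM[0]
        assert res.calls[0].cluster_size == 20

    def test_too_few_reads_raises(self, library):
        reads = _subject_reads(HET, 60)[:1]
        cfg = BaggingConfig(iterations=1, sample_size=20, seed=5)
        with pytest.raises(InsufficientReadsError):
            run_iteration(reads, library, cfg, 0, "S")


class TestAggregate:
    def _result(self, iteration, names_sizes):
        return IterationResult(
            iteration=iteration,
            calls=[
                AlleleCall(allele=n, identity_score=100.0, cluster_size=s)
                for n, s in names_sizes
            ],
        )

    def test_call_rate_arithmetic(self):
        cfg = BaggingConfig(iterations=10, sample_size=20)
        results = [self._result(b, [("A*01", 12), ("B*01", 8)]) for b in range(9)]
        results.append(self._result(9, [("A*01", 20)]))
        aggs = aggregate(results, cfg)
        assert [a.allele for a in aggs] == ["A*01", "B*01"]
        assert aggs[0].call_rate == 100.0
        assert aggs[1].call_rate == 90.0
        assert aggs[0].avg_cluster_size == pytest.approx((12 * 9 + 20) / 10)
        assert aggs[1].avg_cluster_size == pytest.approx(8.0)

    def test_single_iteration(self):
        cfg = BaggingConfig(iterations=1, sample_size=20)
        aggs = aggregate([self._result(0, [("A*01", 20)])], cfg)
        assert aggs[0].call_rate == 100.0 and aggs[0].n_detections == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate([], BaggingConfig())


class TestCallGenotype:
    def _agg(self, name, rate, size=10.0, ident=100.0):
        return AggregateCall(name, rate, size, ident, int(rate))

    def test_two_strong_alleles_heterozygous(self):
        rep = call_genotype(
            [self._agg("A*01", 100.0), self._agg("B*01", 95.0)],
            BaggingConfig(min_call_rate=10.0),
            "S",
        )
        assert rep.zygosity == "heterozygous"
        assert (rep.allele1, rep.allele2) == ("A*01", "B*01")

    def test_weak_second_allele_dropped(self):
        rep = call_genotype(
            [self._agg("A*01", 100.0), self._agg("B*01", 4.0)],
            BaggingConfig(min_call_rate=10.0),
            "S",
        )
        assert rep.zygosity == "homozygous"
        assert rep.allele1 == rep.allele2 == "A*01"

    def test_single_aggregate_homozygous(self):
        rep = call_genotype([self._agg("A*01", 100.0)], BaggingConfig(), "S")
        assert rep.zygosity == "homozygous" and rep.allele2 == "A*01"

    def test_threshold_boundary_inclusive(self):
        rep = call_genotype(
            [self._agg("A*01", 100.0), self._agg("B*01", 10.0)],
            BaggingConfig(min_call_rate=10.0),
            "S",
        )
        assert rep.zygosity == "heterozygous"


class TestGenotypeSubject:
    def test_balanced_heterozygote_with_errors(self, library):
        reads = _subject_reads(HET, 120, error=0.01, seed=3)
        cfg = BaggingConfig(iterations=10, sample_size=20, seed=7)
        rep = genotype_subject(reads, library, cfg, "S")
        assert rep.zygosity == "heterozygous"
        assert sorted([rep.allele1, rep.allele2]) == sorted(HET)
        assert rep.avg_identity1 > 99.0 and rep.avg_identity2 > 99.0

    def test_deterministic_byte_identical_reports(self, library, tmp_path):
        reads = _subject_reads(HET, 80, error=0.01, seed=4)
        cfg = BaggingConfig(iterations=5, sample_size=20, seed=11)
        paths = []
        for i in range(2):
            rep = genotype_subject(reads, library, cfg, "S")
            p = tmp_path / f"rep{i}.tsv"
            write_report([rep], p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_seed_sensitivity_documented_contract(self, library):
        # different master seeds may sample different subsets but the
        # genotype of a clean balanced heterozygote must not change
        reads = _subject_reads(HET, 100, error=0.0, seed=6)
        for seed in (1, 2):
            cfg = BaggingConfig(iterations=5, sample_size=20, seed=seed)
            rep = genotype_subject(reads, library, cfg, "S")
            assert sorted([rep.allele1, rep.allele2]) == sorted(HET)


class TestScoring:
    def _report(self, a1, a2):
        zyg = "homozygous" if a1 == a2 else "heterozygous"
        return GenotypeReport("S", a1, a2, zyg, 100, 100, 10, 10, 100, 100)

    def test_concordant(self):
        tally = score_genotypes(
            [self._report("A", "B")], {"S": ("B", "A")}
        )
        assert (tally.concordant, tally.sensitivity_errors, tally.specificity_errors) == (2, 0, 0)

    def test_allele_dropout_is_sensitivity_error(self):
        tally = score_genotypes([self._report("A", "A")], {"S": ("A", "B")})
        assert tally.sensitivity_errors == 1
        assert tally.specificity_errors == 0
        assert tally.concordant == 1

    def test_alternate_allele_is_specificity_error(self):
        tally = score_genotypes([self._report("A", "C")], {"S": ("A", "B")})
        assert tally.specificity_errors == 1
        assert tally.sensitivity_errors == 0

    def test_wrong_homozygote_is_specificity(self):
        tally = score_genotypes([self._report("C", "C")], {"S": ("A", "B")})
        assert tally.specificity_errors == 2

    def test_resolution_projection(self):
        tally = score_genotypes(
            [self._report("SYN*01:01:01", "SYN*01:01:01")],
            {"S": ("SYN*01:01:02", "SYN*01:01:01")},
            resolution=lambda n: n.rsplit(":", 1)[0],
        )
        assert tally.concordant == 2
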