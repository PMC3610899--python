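"""Bootstrap-aggregated genotype calling.

A single cluster-and-call pass on all reads of a subject is an unstable
predictor: an under-amplified allele can be swamped and missed entirely
(allele dropout). Bagging stabilises the call by repeating the
cluster→consensus→match pipeline on random subsamples of N reads (drawn
without replacement within an iteration — each iteration sees a *subset*
of the reads) and aggregating the per-iteration calls. An allele's call
rate is the percentage of iterations detecting it; a second allele is
accepted into the genotype when its call rate clears ``min_call_rate``,
otherwise the subject is reported homozygous.

Everything is a pure function of (reads, library, config incl. seed):
per-iteration seeds are hashed from (master seed, subject id, iteration),
so results are independent of the order in which subjects are processed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .consensus import AlleleCall, build_consensus, match_allele
from .diffusion import DiffusionParams, cluster_reads
from .io import AlleleRecord, GenotypeReport, Read
from .similarity import SimilarityMatrix, SimilarityParams, weighted_similarity
from .util import derive_seed


class InsufficientReadsError(ValueError):
    """Subject has too few reads to genotype (needs at least 2)."""


@dataclass(frozen=True)
class BaggingConfig:
    """Bagging hyper-parameters.

    ``iterations`` (B) repeats of subsampled cluster-and-call; ``sample_size``
    (N) reads drawn per iteration without replacement; ``min_call_rate`` is
    the percent call-rate threshold a second allele must reach to be
    accepted into the genotype (below it the subject is called homozygous).
    """

    iterations: int = 60
    sample_size: int = 20
    seed: int = 0
    min_call_rate: float = 10.0
    similarity: SimilarityParams = field(default_factory=SimilarityParams)
    diffusion: DiffusionParams = field(default_factory=DiffusionParams)

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.sample_size < 2:
            raise ValueError("sample_size must be >= 2")
        if not 0.0 <= self.min_call_rate <= 100.0:
            raise ValueError("min_call_rate outside [0, 100]")


@dataclass
class IterationResult:
    """Calls from one subsampled cluster-and-call pass (1 or 2 calls)."""

    iteration: int
    calls: list[AlleleCall]

    def __post_init__(self) -> None:
        if not 1 <= len(self.calls) <= 2:
            raise ValueError("an iteration yields 1 or 2 calls")


@dataclass
class SubjectCache:
    """Alignment memos reused across a subject's bagging iterations.

    ``pair_scores`` is keyed by (i, j) indices into the subject's full read
    list; ``match_cache`` memoises library matching by consensus sequence.
    """

    pair_scores: dict[tuple[int, int], float] = field(default_factory=dict)
    match_cache: dict[str, tuple[str, float, tuple[str, ...]]] = field(default_factory=dict)


def _subsample_indices(n: int, size: int, rng: np.random.Generator) -> np.ndarray:
    if n <= size:
        return np.arange(n)
    return np.sort(rng.choice(n, size=size, replace=False))


def run_iteration(
    subject_reads: list[Read],
    library: list[AlleleRecord],
    config: BaggingConfig,
    iteration_index: int,
    subject_id: str,
    cache: SubjectCache | None = None,
) -> IterationResult:
    """One bagging pass: subsample N reads, cluster into 2 groups, call each.

    If both clusters match the same allele the two calls merge into one
    with summed cluster size (and size-weighted mean identity).
    """
    n = len(subject_reads)
    if n < 2:
        raise InsufficientReadsError(
            f"subject {subject_id!r}: {n} read(s), need at least 2"
        )
    if cache is None:
        cache = SubjectCache()
    it_seed = derive_seed(config.seed, subject_id, iteration_index)
    rng = np.random.default_rng(it_seed)
    idx = _subsample_indices(n, config.sample_size, rng)
    sample = [subject_reads[i] for i in idx]
    k = len(sample)

    # similarity over the subsample, memoised on full-list index pairs
    S = np.empty((k, k), dtype=float)
    for a in range(k):
        S[a, a] = len(sample[a])
        for b in range(a + 1, k):
            key = (int(idx[a]), int(idx[b]))
            s = cache.pair_scores.get(key)
            if s is None:
                s = weighted_similarity(sample[a], sample[b], config.similarity)
                cache.pair_scores[key] = s
            S[a, b] = S[b, a] = s
    matrix = SimilarityMatrix(scores=S, read_ids=[r.read_id for r in sample])

    from .similarity import to_dissimilarity

    assignment, _ = cluster_reads(
        sample,
        similarity_params=config.similarity,
        diffusion_params=config.diffusion,
        seed=it_seed,
        K=2,
        precomputed_D=to_dissimilarity(matrix),
    )

    calls: list[AlleleCall] = []
    for c in range(assignment.K):
        members = assignment.cluster_indices(c)
        cluster = [sample[i] for i in members]
        cons = build_consensus(
            cluster,
            params=config.similarity,
            similarity=S[np.ix_(members, members)],
        )
        calls.append(match_allele(cons, library, cache=cache.match_cache))

    if len(calls) == 2 and calls[0].allele == calls[1].allele:
        a, b = calls
        total = a.cluster_size + b.cluster_size
        merged = AlleleCall(
            allele=a.allele,
            identity_score=(
                a.identity_score * a.cluster_size + b.identity_score * b.cluster_size
            )
            / total,
            cluster_size=total,
            tied=a.tied if a.cluster_size >= b.cluster_size else b.tied,
        )
        calls = [merged]
    return IterationResult(iteration=iteration_index, calls=calls)


@dataclass
class AggregateCall:
    """Bagged summary for one distinct allele across iterations."""

    allele: str
    call_rate: float  # percent of iterations detecting the allele
    avg_cluster_size: float  # mean reads assigned per detecting iteration
    avg_identity: float  # mean identity score over detecting iterations
    n_detections: int


def aggregate(results: list[IterationResult], config: BaggingConfig) -> list[AggregateCall]:
    """Per-allele call rate / mean cluster size / mean identity.

    Sorted by descending call rate, then descending mean cluster size,
    then name (for determinism).
    """
    if not results:
        raise ValueError("aggregate requires at least one iteration result")
    B = len(results)
    sizes: dict[str, list[int]] = {}
    idents: dict[str, list[float]] = {}
    for res in results:
        for call in res.calls:
            sizes.setdefault(call.allele, []).append(call.cluster_size)
            idents.setdefault(call.allele, []).append(call.identity_score)
    aggs = [
        AggregateCall(
            allele=name,
            call_rate=100.0 * len(sizes[name]) / B,
            avg_cluster_size=float(np.mean(sizes[name])),
            avg_identity=float(np.mean(idents[name])),
            n_detections=len(sizes[name]),
        )
        for name in sizes
    ]
    aggs.sort(key=lambda a: (-a.call_rate, -a.avg_cluster_size, a.allele))
    return aggs


def call_genotype(
    aggregates: list[AggregateCall], config: BaggingConfig, subject_id: str
) -> GenotypeReport:
    """Final diploid call: top allele always; second if its call rate
    clears ``min_call_rate``, else homozygous for the top allele."""
    if not aggregates:
        raise ValueError("call_genotype requires at least one aggregate")
    a1 = aggregates[0]
    a2 = aggregates[1] if len(aggregates) > 1 else None
    if a2 is not None and a2.call_rate >= config.min_call_rate:
        return GenotypeReport(
            subject_id=subject_id,
            allele1=a1.allele,
            allele2=a2.allele,
            zygosity="heterozygous",
            call_rate1=a1.call_rate,
            call_rate2=a2.call_rate,
            avg_cluster_size1=a1.avg_cluster_size,
            avg_cluster_size2=a2.avg_cluster_size,
            avg_identity1=a1.avg_identity,
            avg_identity2=a2.avg_identity,
        )
    return GenotypeReport(
        subject_id=subject_id,
        allele1=a1.allele,
        allele2=a1.allele,
        zygosity="homozygous",
        call_rate1=a1.call_rate,
        call_rate2=a1.call_rate,
        avg_cluster_size1=a1.avg_cluster_size,
        avg_cluster_size2=a1.avg_cluster_size,
        avg_identity1=a1.avg_identity,
        avg_identity2=a1.avg_identity,
    )


def genotype_subject(
    subject_reads: list[Read],
    library: list[AlleleRecord],
    config: BaggingConfig,
    subject_id: str,
    return_aggregates: bool = False,
):
    """Full bagged genotype for one subject.

    Deterministic given the master seed. Subjects with fewer than
    ``sample_size`` reads use all reads every iteration (variation then
    comes only from K-means restarts); callers may flag them low-coverage.
    """
    cache = SubjectCache()
    results = [
        run_iteration(subject_reads, library, config, b, subject_id, cache)
        for b in range(config.iterations)
    ]
    aggs = aggregate(results, config)
    report = call_genotype(aggs, config, subject_id)
    if return_aggregates:
        return report, aggs
    return report
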