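"""Per-cluster consensus sequences and known-allele matching.

A cluster's consensus is built by star alignment: every read is globally
aligned to the cluster medoid (the read with maximal summed similarity to
its cluster mates) and the aligned columns are voted per position. The
plurality base wins each column; ties go to the larger summed Phred
quality, then alphabetically. Columns whose plurality is a gap are
deleted — homopolymer over-calls are the dominant pyrosequencing artifact
and deletion restores the modal length. Star alignment costs O(n)
pairwise alignments and is an adequate stand-in for a full multiple
alignment because same-cluster reads are near-identical.

The consensus is then matched against the known-allele library by global
alignment identity (percent matching columns); the best-identity allele
is the call, with ties resolved alphabetically and recorded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AlleleRecord, Read
from .similarity import (
    SimilarityMatrix,
    SimilarityParams,
    align_pair,
    build_matrix,
)


@dataclass
class ConsensusSequence:
    """Column-voted consensus of one read cluster."""

    sequence: str
    cluster_size: int
    column_support: np.ndarray  # plurality fraction per kept column

    def __post_init__(self) -> None:
        if self.cluster_size < 1:
            raise ValueError("cluster_size must be >= 1")
        self.column_support = np.asarray(self.column_support, dtype=float)
        if self.column_support.size and not (
            np.all(self.column_support > 0) and np.all(self.column_support <= 1)
        ):
            raise ValueError("column support must lie in (0, 1]")


def _medoid_index(reads: list[Read], similarity: SimilarityMatrix | np.ndarray | None,
                  params: SimilarityParams | None) -> int:
    if len(reads) == 1:
        return 0
    if similarity is None:
        similarity = build_matrix(reads, params)
    S = similarity.scores if isinstance(similarity, SimilarityMatrix) else np.asarray(similarity)
    if S.shape != (len(reads), len(reads)):
        raise ValueError("similarity matrix does not match the read set")
    return int(np.argmax(S.sum(axis=1)))


def build_consensus(
    reads: list[Read],
    params: SimilarityParams | None = None,
    similarity: SimilarityMatrix | np.ndarray | None = None,
) -> ConsensusSequence:
    """Medoid-anchored star-alignment consensus of a read cluster.

    ``similarity`` may carry the precomputed matrix over exactly these
    reads (as produced during clustering) to avoid re-alignment.
    """
    if not reads:
        raise ValueError("cannot build a consensus from an empty cluster")
    n = len(reads)
    medoid = reads[_medoid_index(reads, similarity, params)]

    # Column key: (p, 0) is the column anchored at medoid position p;
    # (p, j>0) is the j-th inserted column between medoid positions p and
    # p+1 (p = -1 for insertions before the first medoid base).
    columns: dict[tuple[int, int], dict[str, list[float]]] = {}

    def vote(key: tuple[int, int], base: str, qual: float) -> None:
        col = columns.setdefault(key, {})
        entry = col.setdefault(base, [0, 0.0])
        entry[0] += 1
        entry[1] += qual

    for read in reads:
        if read.sequence == medoid.sequence:
            for p, (base, q) in enumerate(zip(read.sequence, read.quals)):
                vote((p, 0), base, float(q))
            continue
        blocks_m, blocks_r, _ = _blocks_of(medoid, read, params)
        prev_m = prev_r = 0
        for (sm, em), (sr, er) in list(zip(blocks_m, blocks_r)) + [
            ((len(medoid), len(medoid)), (len(read), len(read)))
        ]:
            for p in range(prev_m, sm):  # deletion in read
                vote((p, 0), "-", 0.0)
            anchor = prev_m - 1
            for j, rp in enumerate(range(prev_r, sr), start=1):  # insertion in read
                vote((anchor, j), read.sequence[rp], float(read.quals[rp]))
            for k in range(em - sm):
                vote((sm + k, 0), read.sequence[sr + k], float(read.quals[sr + k]))
            prev_m, prev_r = em, er

    bases: list[str] = []
    support: list[float] = []
    for key in sorted(columns):
        col = columns[key]
        explicit = sum(entry[0] for entry in col.values())
        implicit_gaps = n - explicit  # reads lacking this inserted column
        if implicit_gaps:
            entry = col.setdefault("-", [0, 0.0])
            entry[0] += implicit_gaps
        # plurality; ties -> larger summed quality -> alphabetically first
        winner = min(col, key=lambda b: (-col[b][0], -col[b][1], b))
        if winner == "-":
            continue
        bases.append(winner)
        support.append(col[winner][0] / n)

    if not bases:
        raise ValueError("consensus degenerated to the empty sequence")
    return ConsensusSequence(
        sequence="".join(bases), cluster_size=n, column_support=np.array(support)
    )


def _blocks_of(a: Read, b: Read, params: SimilarityParams | None):
    """Aligned blocks of a vs b (identity fast path included)."""
    from .similarity import _aligned_blocks

    if a.sequence == b.sequence:
        block = np.array([[0, len(a)]])
        return block, block, len(a)
    return _aligned_blocks(a.sequence, b.sequence)


@dataclass
class AlleleCall:
    """Best library match for one cluster consensus."""

    allele: str
    identity_score: float  # percent, 0–100
    cluster_size: int
    tied: tuple[str, ...] = ()  # all equally-near alleles when ambiguous

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity_score <= 100.0:
            raise ValueError("identity score outside [0, 100]")


def identity_score(consensus: ConsensusSequence | str, allele: AlleleRecord | str) -> float:
    """Percent identity of a global alignment: 100 × matches / columns.

    Unrounded; report writers round at output time only.
    """
    seq_c = consensus.sequence if isinstance(consensus, ConsensusSequence) else consensus
    seq_a = allele.sequence if isinstance(allele, AlleleRecord) else allele
    if not seq_c or not seq_a:
        raise ValueError("identity_score requires non-empty sequences")
    if seq_c == seq_a:
        return 100.0
    ra = Read("c", seq_c, np.full(len(seq_c), 40))
    rb = Read("a", seq_a, np.full(len(seq_a), 40))
    res = align_pair(ra, rb)
    matches = res.aln_length - res.mismatches - res.gaps
    return 100.0 * matches / res.aln_length


def match_allele(
    consensus: ConsensusSequence,
    library: list[AlleleRecord],
    cache: dict[str, tuple[str, float, tuple[str, ...]]] | None = None,
) -> AlleleCall:
    """Best-identity library allele for a consensus.

    Ties (identical identity) are broken alphabetically with every tied
    name recorded in the call's ambiguity annotation. ``cache`` memoises
    by consensus sequence for bagging, where consensuses repeat.
    """
    if not library:
        raise ValueError("empty allele library: genotyping impossible")
    if cache is not None and consensus.sequence in cache:
        name, ident, tied = cache[consensus.sequence]
        return AlleleCall(name, ident, consensus.cluster_size, tied)

    scores = [(rec.name, identity_score(consensus, rec)) for rec in library]
    best = max(s for _, s in scores)
    tied_names = tuple(sorted(name for name, s in scores if abs(s - best) < 1e-9))
    name = tied_names[0]
    tied = tied_names if len(tied_names) > 1 else ()
    if cache is not None:
        cache[consensus.sequence] = (name, best, tied)
    return AlleleCall(name, best, consensus.cluster_size, tied)
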