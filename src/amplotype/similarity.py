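"""Quality-weighted pairwise similarity between amplicon reads.

Reads from the same allele differ only by sequencing error, so a global
alignment of two same-allele reads has few mismatches, while reads from
different alleles disagree at every allele-defining position. The
similarity score of a pair is

    S(a, b) = L_aln − Σ_k w_k − G

where L_aln is the alignment length, the sum runs over mismatch columns,
and G is the number of gap columns (each penalised with weight 1). A
mismatch's weight w_k is 1, down-weighted to ``low_quality_weight`` when
either base has Phred quality below ``quality_threshold`` (default Q30):
a disagreement between confident base calls is evidence of distinct
alleles, while a low-quality disagreement is likely sequencing error.

Alignment is optimal global dynamic programming (match +1, mismatch −1,
gap −2) computed by Biopython's PairwiseAligner; amplicons from a single
locus are near-identical ~270 bp sequences, for which global alignment is
exact and banded/heuristic methods are unnecessary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align

from .io import Read

#: Global alignment scoring used throughout the pipeline (similarity,
#: consensus anchoring, library matching).
MATCH_SCORE = 1
MISMATCH_SCORE = -1
GAP_SCORE = -2

_ALIGNER = Align.PairwiseAligner(
    mode="global",
    match_score=MATCH_SCORE,
    mismatch_score=MISMATCH_SCORE,
    open_gap_score=GAP_SCORE,
    extend_gap_score=GAP_SCORE,
)


@dataclass(frozen=True)
class SimilarityParams:
    """Knobs of the mismatch weighting scheme."""

    quality_threshold: int = 30
    low_quality_weight: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.quality_threshold <= 60:
            raise ValueError("quality_threshold outside [0, 60]")
        if not 0.0 <= self.low_quality_weight <= 1.0:
            raise ValueError("low_quality_weight outside [0, 1]")


@dataclass
class AlignmentResult:
    """Summary of one optimal global alignment of a read pair."""

    aln_length: int
    mismatches: int
    weighted_mismatch_sum: float
    gaps: int
    #: (position in a, position in b) of every mismatch column
    mismatch_positions: list[tuple[int, int]]

    @property
    def score(self) -> int:
        """Raw DP score: matches − mismatches − 2·gaps."""
        matches = self.aln_length - self.mismatches - self.gaps
        return MATCH_SCORE * matches + MISMATCH_SCORE * self.mismatches + GAP_SCORE * self.gaps


def mismatch_weight(
    qa: int, qb: int, threshold: int = 30, low_weight: float = 0.5
) -> float:
    """Weight of a mismatch column given the two base qualities.

    Returns ``low_weight`` when min(qa, qb) < threshold, else 1.0.
    """
    return low_weight if min(qa, qb) < threshold else 1.0


def _aligned_blocks(seq_a: str, seq_b: str) -> tuple[np.ndarray, np.ndarray, int]:
    """Align two sequences; return per-strand aligned blocks and length."""
    aln = _ALIGNER.align(seq_a, seq_b)[0]
    blocks_a, blocks_b = aln.aligned
    return np.asarray(blocks_a), np.asarray(blocks_b), aln.length


def align_pair(a: Read, b: Read, params: SimilarityParams | None = None) -> AlignmentResult:
    """Optimal global alignment of two reads with quality-weighted mismatches.

    Co-optimal alignments can differ in their mismatch/gap column counts,
    so the traceback choice matters for the weighted score. The pair is
    aligned in a canonical order (lexicographically smaller sequence
    first) and mismatch positions mirrored back, which makes the result
    deterministic and exactly symmetric in its arguments.
    """
    if params is None:
        params = SimilarityParams()
    if not a.sequence or not b.sequence:
        raise ValueError("cannot align empty sequences")

    if a.sequence == b.sequence:  # fast path: identity alignment is optimal
        return AlignmentResult(len(a), 0, 0.0, 0, [])

    if (b.sequence, bytes(b.quals.data)) < (a.sequence, bytes(a.quals.data)):
        res = align_pair(b, a, params)
        return AlignmentResult(
            aln_length=res.aln_length,
            mismatches=res.mismatches,
            weighted_mismatch_sum=res.weighted_mismatch_sum,
            gaps=res.gaps,
            mismatch_positions=[(pa, pb) for pb, pa in res.mismatch_positions],
        )

    blocks_a, blocks_b, aln_length = _aligned_blocks(a.sequence, b.sequence)
    bytes_a = np.frombuffer(a.sequence.encode("ascii"), dtype=np.uint8)
    bytes_b = np.frombuffer(b.sequence.encode("ascii"), dtype=np.uint8)

    aligned_cols = 0
    mismatch_positions: list[tuple[int, int]] = []
    weighted = 0.0
    for (sa, ea), (sb, eb) in zip(blocks_a, blocks_b):
        aligned_cols += ea - sa
        diff = np.nonzero(bytes_a[sa:ea] != bytes_b[sb:eb])[0]
        if diff.size:
            pos_a = diff + sa
            pos_b = diff + sb
            mismatch_positions.extend(zip(pos_a.tolist(), pos_b.tolist()))
            w = np.where(
                np.minimum(a.quals[pos_a], b.quals[pos_b]) < params.quality_threshold,
                params.low_quality_weight,
                1.0,
            )
            weighted += float(w.sum())
    gaps = (len(a) - aligned_cols) + (len(b) - aligned_cols)
    return AlignmentResult(
        aln_length=aln_length,
        mismatches=len(mismatch_positions),
        weighted_mismatch_sum=weighted,
        gaps=gaps,
        mismatch_positions=mismatch_positions,
    )


def weighted_similarity(a: Read, b: Read, params: SimilarityParams | None = None) -> float:
    """S(a,b) = alignment length − weighted mismatches − gap columns."""
    res = align_pair(a, b, params)
    return float(res.aln_length - res.weighted_mismatch_sum - res.gaps)


@dataclass
class SimilarityMatrix:
    """Symmetric quality-weighted similarity over an ordered read set.

    The diagonal holds read lengths (a read's similarity to itself).
    """

    scores: np.ndarray
    read_ids: list[str]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        n = self.scores.shape[0]
        if self.scores.shape != (n, n) or n != len(self.read_ids):
            raise ValueError("scores must be n×n matching read_ids")

    @property
    def n(self) -> int:
        return self.scores.shape[0]

    def to_tsv(self, path) -> None:
        """Debug dump of the matrix."""
        import pandas as pd

        pd.DataFrame(self.scores, index=self.read_ids, columns=self.read_ids).to_csv(
            path, sep="\t"
        )


def build_matrix(
    reads: list[Read],
    params: SimilarityParams | None = None,
    pair_scores: dict[tuple[int, int], float] | None = None,
) -> SimilarityMatrix:
    """All-pairs weighted similarity matrix (each pair computed once).

    ``pair_scores`` is an optional memo keyed by index pair; callers that
    repeatedly score overlapping read subsets (bagging) pass a persistent
    dict keyed by stable read indices to avoid realigning the same pair.
    """
    n = len(reads)
    if n < 2:
        raise ValueError(f"clustering requires at least 2 reads, got {n}")
    S = np.empty((n, n), dtype=float)
    for i in range(n):
        S[i, i] = len(reads[i])
    for i in range(n):
        for j in range(i + 1, n):
            if pair_scores is not None and (i, j) in pair_scores:
                s = pair_scores[(i, j)]
            else:
                s = weighted_similarity(reads[i], reads[j], params)
                if pair_scores is not None:
                    pair_scores[(i, j)] = s
            S[i, j] = S[j, i] = s
    return SimilarityMatrix(scores=S, read_ids=[r.read_id for r in reads])


def to_dissimilarity(matrix: SimilarityMatrix) -> np.ndarray:
    """Normalised dissimilarity D_ij = 1 − S_ij / min(S_ii, S_jj), in [0,1].

    Dividing by the shorter read's self-similarity makes D scale-free so a
    single kernel bandwidth works across read-length variation; gap-heavy
    pairs can push the raw ratio slightly outside [0,1], hence the clip.
    """
    S = matrix.scores
    self_sim = np.diag(S)
    denom = np.minimum.outer(self_sim, self_sim)
    D = 1.0 - S / denom
    np.clip(D, 0.0, 1.0, out=D)
    np.fill_diagonal(D, 0.0)
    return D
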