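"""Diffusion-map embedding and K-means partitioning of read sets.

The dissimilarity matrix is turned into a Gaussian kernel
W_ij = exp(−D_ij² / ε) and row-normalised into a Markov transition matrix
P. Euclidean distance between rows in the eigenspace of P (the diffusion
space) is small when two reads are highly connected through the read
graph, which makes the two allelic groups of a diploid amplicon pool
nearly linearly separable even in the presence of outlier reads such as
PCR artifacts. K-means in diffusion coordinates then recovers the groups.

K is fixed to 2 by callers (one cluster per haplotype of a diploid
locus); homozygosity is resolved downstream when both cluster consensuses
match the same allele.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from sklearn.cluster import KMeans

from .io import Read
from .similarity import SimilarityParams, build_matrix, to_dissimilarity


@dataclass
class TransitionMatrix:
    """Row-stochastic diffusion operator plus the kernel row sums.

    The degree vector is kept because the symmetric conjugate
    A = Δ^{1/2} P Δ^{−1/2} (Δ = diag(degrees)) is needed to obtain real
    eigenpairs of P.
    """

    P: np.ndarray
    degrees: np.ndarray


def build_kernel(D: np.ndarray, epsilon: float) -> TransitionMatrix:
    """Gaussian kernel W = exp(−D²/ε), row-normalised to a Markov matrix."""
    if epsilon <= 0:
        raise ValueError(f"kernel bandwidth epsilon must be > 0, got {epsilon}")
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("D must be a square matrix")
    if not np.allclose(D, D.T):
        raise ValueError("D must be symmetric")
    if not np.allclose(np.diag(D), 0.0):
        raise ValueError("D must have a zero diagonal")
    W = np.exp(-(D**2) / epsilon)
    degrees = W.sum(axis=1)
    P = W / degrees[:, None]
    return TransitionMatrix(P=P, degrees=degrees)


def median_epsilon(D: np.ndarray) -> float:
    """Self-tuning bandwidth: median of the squared nonzero distances."""
    vals = D[np.triu_indices_from(D, k=1)]
    nz = vals[vals > 0]
    if nz.size == 0:
        return 1.0  # all reads identical; any bandwidth gives the flat kernel
    return float(np.median(nz**2))


@dataclass
class DiffusionEmbedding:
    """Eigenpairs of the diffusion operator and the scaled coordinates.

    Row i of ``coordinates`` is (λ_1^t ψ_1(i), …, λ_m^t ψ_m(i)) where ψ_k
    are right eigenvectors of P and the trivial λ=1 constant eigenvector
    is excluded.
    """

    eigenvalues: np.ndarray
    coordinates: np.ndarray
    epsilon: float
    t: int
    m: int


def embed(transition: TransitionMatrix, m: int = 4, t: int = 1,
          epsilon: float = float("nan")) -> DiffusionEmbedding:
    """Spectral embedding of the diffusion operator.

    Eigenpairs are computed on the symmetric conjugate
    A = Δ^{−1/2} W Δ^{−1/2}, which shares eigenvalues with P and yields
    real eigenvectors; right eigenvectors of P are recovered as
    ψ = Δ^{−1/2} v. Per-eigenvector sign is fixed by making the
    largest-magnitude entry positive. m is clipped to n−1 with a warning.
    """
    P, degrees = transition.P, transition.degrees
    n = P.shape[0]
    if m >= n:
        warnings.warn(f"embedding dimension m={m} clipped to n-1={n - 1}")
        m = n - 1
    d_sqrt = np.sqrt(degrees)
    d_isqrt = 1.0 / d_sqrt
    A = (d_sqrt[:, None] * P) * d_isqrt[None, :]  # Δ^{1/2} P Δ^{-1/2} = Δ^{-1/2} W Δ^{-1/2}
    A = (A + A.T) / 2.0  # symmetrise away roundoff
    eigvals, eigvecs = scipy.linalg.eigh(A)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    psi = d_isqrt[:, None] * eigvecs  # right eigenvectors of P
    # drop the trivial leading pair (λ=1, constant eigenvector)
    lam = eigvals[1 : m + 1]
    psi = psi[:, 1 : m + 1]
    flip = np.sign(psi[np.argmax(np.abs(psi), axis=0), np.arange(psi.shape[1])])
    flip[flip == 0] = 1.0
    psi = psi * flip
    coords = psi * (lam**t)
    return DiffusionEmbedding(
        eigenvalues=lam, coordinates=coords, epsilon=epsilon, t=t, m=m
    )


@dataclass
class ClusterAssignment:
    """K-means labels over the embedded reads."""

    labels: np.ndarray
    K: int
    within_ss: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        sizes = np.bincount(self.labels, minlength=self.K)
        if np.any(sizes == 0):
            raise ValueError("every cluster must be non-empty")

    def cluster_indices(self, k: int) -> np.ndarray:
        return np.nonzero(self.labels == k)[0]


#: K-means restarts. On very small instances (a bagging subsample is
#: ~20 points) ten k-means++ restarts measurably miss the global optimum
#: a few percent of the time; thirty make best-of-restarts reliably
#: attain it at negligible cost.
KMEANS_RESTARTS = 30


def kmeans(embedding: DiffusionEmbedding, K: int, seed: int) -> ClusterAssignment:
    """K-means in diffusion coordinates (k-means++, seeded restarts)."""
    X = embedding.coordinates
    n = X.shape[0]
    if K > n:
        raise ValueError(f"K={K} exceeds number of reads n={n}")
    with warnings.catch_warnings():
        # coincident points make sklearn warn about duplicate centroids
        warnings.simplefilter("ignore")
        km = KMeans(n_clusters=K, init="k-means++", n_init=KMEANS_RESTARTS, random_state=seed)
        labels = km.fit_predict(X)
    # Coincident coordinates (e.g. identical reads) can leave a cluster
    # empty; repopulate deterministically so every cluster is non-empty.
    sizes = np.bincount(labels, minlength=K)
    for empty in np.nonzero(sizes == 0)[0]:
        donor = int(np.argmax(sizes))
        idx = int(np.nonzero(labels == donor)[0][-1])
        labels[idx] = empty
        sizes[donor] -= 1
        sizes[empty] += 1
    return ClusterAssignment(labels=labels, K=K, within_ss=float(km.inertia_))


@dataclass(frozen=True)
class DiffusionParams:
    """Embedding hyper-parameters.

    ``epsilon=None`` selects the self-tuning median heuristic. Defaults
    t=1, m=4: a two-allele read pool concentrates in very few diffusion
    coordinates, so a small embedding suffices.
    """

    epsilon: float | None = None
    t: int = 1
    m: int = 4


def cluster_reads(
    reads: list[Read],
    similarity_params: SimilarityParams | None = None,
    diffusion_params: DiffusionParams | None = None,
    seed: int = 0,
    K: int = 2,
    pair_scores: dict[tuple[int, int], float] | None = None,
    precomputed_D: np.ndarray | None = None,
):
    """similarity → dissimilarity → kernel → embedding → K-means.

    Returns (assignment, similarity_matrix_or_None). ``pair_scores`` is an
    optional alignment memo passed through to build_matrix.
    """
    if diffusion_params is None:
        diffusion_params = DiffusionParams()
    matrix = None
    if precomputed_D is None:
        matrix = build_matrix(reads, similarity_params, pair_scores)
        D = to_dissimilarity(matrix)
    else:
        D = precomputed_D
    eps = diffusion_params.epsilon if diffusion_params.epsilon is not None else median_epsilon(D)
    transition = build_kernel(D, eps)
    embedding = embed(transition, m=diffusion_params.m, t=diffusion_params.t, epsilon=eps)
    assignment = kmeans(embedding, K=K, seed=seed)
    return assignment, matrix
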