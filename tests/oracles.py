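"""Independent oracles for alignment, clustering and eigenstructure.

Deliberately naive implementations that share no code with the package:
exhaustive enumeration of alignment paths, a textbook quadratic DP, and
exhaustive 2-partition search. Used to pin the package's optimised
routes to ground truth on small inputs.
"""

import itertools

MATCH, MISMATCH, GAP = 1, -1, -2


def enum_align_score(a: str, b: str) -> int:
    """Best global alignment score by enumerating every alignment path."""
    best = [-(10**9)]

    def go(i: int, j: int, score: int) -> None:
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            go(i + 1, j + 1, score + (MATCH if a[i] == b[j] else MISMATCH))
        if i < len(a):
            go(i + 1, j, score + GAP)
        if j < len(b):
            go(i, j + 1, score + GAP)

    go(0, 0, 0)
    return best[0]


def dp_align_score(a: str, b: str) -> int:
    """Textbook Needleman–Wunsch score, pure-Python lists."""
    n, m = len(a), len(b)
    prev = [GAP * j for j in range(m + 1)]
    for i in range(1, n + 1):
        cur = [GAP * i] + [0] * m
        for j in range(1, m + 1):
            sub = prev[j - 1] + (MATCH if a[i - 1] == b[j - 1] else MISMATCH)
            cur[j] = max(sub, prev[j] + GAP, cur[j - 1] + GAP)
        prev = cur
    return prev[m]


def best_two_partition_ss(points) -> float:
    """Minimum total within-cluster sum of squares over all 2-partitions."""
    import numpy as np

    X = np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(X)
    best = float("inf")
    for mask in range(1, 2 ** (n - 1)):  # point 0 always in cluster A
        in_a = [(mask >> i) & 1 == 0 for i in range(n)]
        A = X[[i for i in range(n) if in_a[i]]]
        B = X[[i for i in range(n) if not in_a[i]]]
        ss = 0.0
        for grp in (A, B):
            if len(grp):
                ss += float(((grp - grp.mean(axis=0)) ** 2).sum())
        best = min(best, ss)
    return best


def all_sequences(alphabet: str, max_len: int):
    for L in range(1, max_len + 1):
        for tup in itertools.product(alphabet, repeat=L):
            yield "".join(tup)
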