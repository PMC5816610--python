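"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by exhaustive enumeration or elementary
arithmetic, never by calling the implementation path it checks.
"""

from __future__ import annotations

from itertools import permutations


def boundary_check_partition(starts_ends: list[tuple[int, int]], max_gap: int, min_genes: int) -> list[list[int]]:
    """Cassette membership by testing every partition boundary independently.

    Returns runs of gene indices.  A boundary between consecutive genes is a
    split iff the gap (next start - previous end) is >= max_gap.
    """
    n = len(starts_ends)
    if n == 0:
        return []
    splits = [
        starts_ends[i + 1][0] - starts_ends[i][1] >= max_gap for i in range(n - 1)
    ]
    runs: list[list[int]] = [[0]]
    for i, split in enumerate(splits):
        if split:
            runs.append([i + 1])
        else:
            runs[-1].append(i + 1)
    return [r for r in runs if len(r) >= min_genes]


def brute_force_match_size(labels_a: list[set], labels_b: list[set]) -> int:
    """Maximum number of one-to-one compatible gene pairs, by enumerating
    every injective assignment of the smaller cassette into the larger."""
    if len(labels_a) > len(labels_b):
        labels_a, labels_b = labels_b, labels_a
    na, nb = len(labels_a), len(labels_b)
    best = 0
    for perm in permutations(range(nb), na):
        size = sum(1 for i, j in enumerate(perm) if labels_a[i] & labels_b[j])
        best = max(best, size)
    return best


def brute_force_global_score(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -1.0,
) -> float:
    """Optimal global affine-gap alignment score by exhaustive recursion.

    A gap of length L costs gap_open + L * gap_extend.  Exponential; only for
    strings of length <= 8.
    """
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, state: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = float("-inf")
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            best = max(best, s + rec(i + 1, j + 1, "M"))
        if i < len(a):
            cost = gap_extend + (gap_open if state != "U" else 0.0)
            best = max(best, cost + rec(i + 1, j, "U"))
        if j < len(b):
            cost = gap_extend + (gap_open if state != "L" else 0.0)
            best = max(best, cost + rec(i, j + 1, "L"))
        return best

    return rec(0, 0, "M")
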