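"""Independent brute-force oracles, written without shared package code.

Everything here is deliberately plain Python (lists, loops, math.fsum) so
the oracles cannot share a bug with the numpy implementations they check.
"""

from __future__ import annotations

import math


def brute_force_align(
    m1: list[list[float]],
    m2: list[list[float]],
    min_overlap_fraction: float = 0.5,
    allow_mirror: bool = True,
):
    """Exhaustive enumeration of all (shift, orientation) candidates.

    m1/m2 are track-major matrices. Returns (r, mirrored, score, n_overlap)
    using the tie-break chain (score, |r|, non-mirrored first, signed r).
    Positive r moves m2 left relative to m1 (m2 bin j vs m1 bin j - r).
    """
    t = len(m1)
    l1, l2 = len(m1[0]), len(m2[0])
    min_ov = max(1, math.ceil(min_overlap_fraction * min(l1, l2) - 1e-9))
    orientations = [(False, m2)]
    if allow_mirror:
        orientations.append((True, [list(reversed(row)) for row in m2]))
    best_key = None
    best = None
    for mirrored, w2 in orientations:
        for d in range(-(l2 - 1), l1):  # d = offset of m2 in m1's frame = -r
            lo, hi = max(0, d), min(l1, d + l2)
            n_ov = hi - lo
            if n_ov < min_ov:
                continue
            terms = []
            for track in range(t):
                for i in range(lo, hi):
                    diff = m1[track][i] - w2[track][i - d]
                    terms.append(diff * diff)
            score = math.fsum(terms) / (n_ov * t)
            r = -d
            key = (score, abs(r), mirrored, r)
            if best_key is None or key < best_key:
                best_key = key
                best = (r, mirrored, score, n_ov)
    if best is None:
        raise ValueError("no admissible shift")
    return best


def brute_reproject(
    leaf_matrices: dict[str, list[list[float]]],
    placements: dict[str, tuple[int, bool]],
):
    """Average of weight-1 leaves placed at (offset, mirrored).

    Returns (matrix, coverage) over the union frame, origin at the
    minimum offset. Per bin: arithmetic mean of the contributing leaves.
    """
    lo = min(off for off, _ in placements.values())
    hi = max(off + len(leaf_matrices[leaf][0]) for leaf, (off, _) in placements.items())
    t = len(next(iter(leaf_matrices.values())))
    length = hi - lo
    sums = [[0.0] * length for _ in range(t)]
    counts = [0] * length
    for leaf, (off, mirrored) in placements.items():
        mat = leaf_matrices[leaf]
        if mirrored:
            mat = [list(reversed(row)) for row in mat]
        for j in range(len(mat[0])):
            pos = off - lo + j
            counts[pos] += 1
            for track in range(t):
                sums[track][pos] += mat[track][j]
    values = [
        [s / c if c else 0.0 for s, c in zip(row, counts)] for row in sums
    ]
    return values, counts


def per_base_bin_means(
    intervals: list[tuple[int, int, float]],
    region_start: int,
    bin_size: int,
    n_bins: int,
):
    """Bin means by literal per-base expansion; None where undefined."""
    out = []
    for b in range(n_bins):
        values = []
        for pos in range(region_start + b * bin_size, region_start + (b + 1) * bin_size):
            for s, e, v in intervals:
                if s <= pos < e:
                    values.append(v)
                    break
        out.append(math.fsum(values) / len(values) if values else None)
    return out


def closed_form_ari(labels_a: list[int], labels_b: list[int]) -> float:
    """Adjusted Rand index straight from the contingency-table formula."""

    def comb2(x: int) -> int:
        return x * (x - 1) // 2

    n = len(labels_a)
    table: dict[tuple[int, int], int] = {}
    for a, b in zip(labels_a, labels_b):
        table[(a, b)] = table.get((a, b), 0) + 1
    a_marg: dict[int, int] = {}
    b_marg: dict[int, int] = {}
    for (a, b), c in table.items():
        a_marg[a] = a_marg.get(a, 0) + c
        b_marg[b] = b_marg.get(b, 0) + c
    index = sum(comb2(c) for c in table.values())
    sum_a = sum(comb2(c) for c in a_marg.values())
    sum_b = sum(comb2(c) for c in b_marg.values())
    expected = sum_a * sum_b / comb2(n)
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0  # both partitions trivial and identical
    return (index - expected) / (max_index - expected)
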