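"""Pool-based agglomerative clustering of aligned profiles.

The pool starts as the set of input profiles. Each iteration aligns all
pairs (cached; only pairs involving the newest member are recomputed),
merges the most similar pair into its coverage-weighted average profile,
prunes sparsely covered alignment edges, and reinserts the representative.
The merge sequence defines a binary dendrogram whose node heights are the
merge scores. Merging the coverage-weighted averages is equivalent to the
true centroid: a node's representative equals the per-bin average of all
its leaves re-projected by their cumulative offsets and orientations
(see :func:`reproject_profiles`), as long as pruning is disabled.

Worker counts only parallelize pure score computations and never change
results: the same ordered list of alignments is produced at any
``n_workers``.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np

from .alignment import align_pair, mirror_profile
from .core import (
    AlignmentResult,
    CatchError,
    CatchParams,
    ClusterNode,
    Placement,
    Profile,
)

__all__ = [
    "merge_profiles",
    "prune_profile",
    "catch_cluster",
    "cut_tree",
    "cut_tree_nodes",
    "to_newick",
    "reproject_profiles",
    "ClusterStats",
]


def merge_profiles(p1: Profile, p2: Profile, a: AlignmentResult) -> Profile:
    """Average two profiles laid out at the aligned shift/orientation.

    ``p2`` is mirrored first when ``a.mirrored``. Overlapping bins take the
    coverage-weighted mean of the children; flanking bins copy the single
    contributing child. New coverage is the per-bin sum of child coverages,
    new weight the sum of child weights.
    """
    if p1.n_tracks != p2.n_tracks:
        raise CatchError(f"merge {p1.id}+{p2.id}: track counts differ")
    q2 = mirror_profile(p2) if a.mirrored else p2
    l1, l2 = p1.n_bins, q2.n_bins
    d = -a.r  # offset of p2 in p1's frame
    if min(l1, d + l2) - max(0, d) < 1:
        raise CatchError(f"merge {p1.id}+{p2.id}: alignment r={a.r} has no overlap")
    off1, off2 = max(0, -d), max(0, d)
    n_total = max(off1 + l1, off2 + l2)

    t = p1.n_tracks
    num = np.zeros((t, n_total))
    cov = np.zeros(n_total, dtype=np.int64)
    num[:, off1 : off1 + l1] += p1.coverage * p1.values
    cov[off1 : off1 + l1] += p1.coverage
    num[:, off2 : off2 + l2] += q2.coverage * q2.values
    cov[off2 : off2 + l2] += q2.coverage

    values = num / cov
    return Profile(
        id=f"({p1.id}+{p2.id})",
        values=values,
        bin_size=p1.bin_size,
        weight=p1.weight + p2.weight,
        coverage=cov,
        track_names=list(p1.track_names),
    )


def prune_profile(
    p: Profile, prune_fraction: float
) -> tuple[Profile, int, int]:
    """Trim low-coverage runs at the profile edges (never the interior).

    Bins at the left/right edge with ``coverage < prune_fraction * weight``
    are removed. If that would empty the profile, the maximum-coverage bin
    and its contiguous equals are kept instead.
    """
    if not (0.0 <= prune_fraction <= 1.0):
        raise CatchError(f"prune_fraction must be in [0, 1], got {prune_fraction}")
    cov = p.coverage
    length = p.n_bins
    threshold = prune_fraction * p.weight
    keep = cov >= threshold
    if not keep.any():
        best = cov.max()
        i = int(np.argmax(cov))
        lo = i
        while lo > 0 and cov[lo - 1] == best:
            lo -= 1
        hi = i + 1
        while hi < length and cov[hi] == best:
            hi += 1
    else:
        lo = int(np.argmax(keep))
        hi = length - int(np.argmax(keep[::-1]))
    if lo == 0 and hi == length:
        return p, 0, 0
    pruned = p.copy(values=p.values[:, lo:hi].copy(), coverage=cov[lo:hi].copy())
    return pruned, lo, length - hi


def _compose_placements(
    node1: ClusterNode, node2: ClusterNode, a: AlignmentResult, trim_left: int
) -> dict[str, Placement]:
    """Leaf placements in the merged (and pruned) frame.

    The first child keeps its orientation; the second child's frame is
    mirrored as a unit when ``a.mirrored``, which flips each of its leaves
    around the child frame.
    """
    l1 = node1.representative.n_bins
    l2 = node2.representative.n_bins
    d = -a.r
    off1, off2 = max(0, -d), max(0, d)
    placements: dict[str, Placement] = {}
    for leaf, pl in node1.placements.items():
        placements[leaf] = Placement(pl.offset + off1 - trim_left, pl.mirrored, pl.length)
    for leaf, pl in node2.placements.items():
        if a.mirrored:
            off = l2 - pl.offset - pl.length
            placements[leaf] = Placement(off + off2 - trim_left, not pl.mirrored, pl.length)
        else:
            placements[leaf] = Placement(pl.offset + off2 - trim_left, pl.mirrored, pl.length)
    return placements


@dataclass
class ClusterStats:
    """Run statistics; ``align_calls`` counts align_pair invocations."""

    align_calls: int = 0
    merges: list[tuple[str, str, str, AlignmentResult]] = field(default_factory=list)


def _align_or_none(
    p1: Profile, p2: Profile, params: CatchParams
) -> AlignmentResult | None:
    try:
        return align_pair(p1, p2, params)
    except CatchError:
        return None


def catch_cluster(
    profiles: list[Profile],
    params: CatchParams | None = None,
    n_workers: int = 1,
    stats: ClusterStats | None = None,
) -> ClusterNode | list[ClusterNode]:
    """Cluster profiles by iterative best-pair merging.

    Returns the dendrogram root, or — if at some point no remaining pool
    pair can satisfy the minimum-overlap constraint — a forest (list) of
    the remaining pool members in insertion order. A single input profile
    is returned as a leaf root.

    Determinism: ties in the best-pair choice are broken by the smaller
    pair of insertion-order indices; align_pair itself has a fixed
    tie-break chain. Identical inputs give identical trees at any worker
    count.
    """
    from .alignment import normalize_tracks

    if params is None:
        params = CatchParams()
    if not profiles:
        raise CatchError("catch_cluster: empty input")
    ids = [p.id for p in profiles]
    if len(set(ids)) != len(ids):
        raise CatchError("catch_cluster: duplicate profile ids")
    if n_workers < 1:
        raise CatchError("catch_cluster: n_workers must be >= 1")

    normalized = normalize_tracks(profiles, params.normalization)
    pool: dict[int, ClusterNode] = {}
    for i, p in enumerate(normalized):
        pool[i] = ClusterNode(
            node_id=p.id,
            representative=p,
            height=0.0,
            placements={p.id: Placement(0, False, p.n_bins)},
            order=i,
        )
    next_idx = len(pool)

    executor = ThreadPoolExecutor(max_workers=n_workers) if n_workers > 1 else None

    def compute(pairs: list[tuple[int, int]]) -> None:
        if stats is not None:
            stats.align_calls += len(pairs)
        args = [(pool[i].representative, pool[j].representative) for i, j in pairs]
        if executor is not None:
            results = list(
                executor.map(lambda ab: _align_or_none(ab[0], ab[1], params), args)
            )
        else:
            results = [_align_or_none(a, b, params) for a, b in args]
        for (i, j), res in zip(pairs, results):
            cache[(i, j)] = res

    cache: dict[tuple[int, int], AlignmentResult | None] = {}
    keys = sorted(pool)
    compute([(i, j) for n, i in enumerate(keys) for j in keys[n + 1 :]])

    try:
        while len(pool) > 1:
            best_key: tuple[float, int, int] | None = None
            for (i, j), res in cache.items():
                if res is None:
                    continue
                key = (res.score, i, j)
                if best_key is None or key < best_key:
                    best_key = key
            if best_key is None:
                break  # nothing alignable: return remaining pool as forest
            _, i, j = best_key
            a = cache[(i, j)]
            node1, node2 = pool[i], pool[j]
            merged = merge_profiles(node1.representative, node2.representative, a)
            merged, trim_left, _ = prune_profile(merged, params.prune_fraction)
            node_id = f"N{next_idx}"
            merged = merged.copy(id=node_id)
            node = ClusterNode(
                node_id=node_id,
                representative=merged,
                children=(node1, node2),
                merge=a,
                height=a.score,
                placements=_compose_placements(node1, node2, a, trim_left),
                order=next_idx,
            )
            if stats is not None:
                stats.merges.append((node_id, node1.node_id, node2.node_id, a))
            del pool[i], pool[j]
            for key in [k for k in cache if i in k or j in k]:
                del cache[key]
            pool[next_idx] = node
            compute([(k, next_idx) for k in sorted(pool) if k != next_idx])
            next_idx += 1
    finally:
        if executor is not None:
            executor.shutdown()

    remaining = [pool[k] for k in sorted(pool)]
    return remaining[0] if len(remaining) == 1 else remaining


def cut_tree_nodes(
    root: ClusterNode, k: int | None = None, max_height: float | None = None
) -> list[ClusterNode]:
    """Subtree roots after cutting by cluster count or by height.

    Cutting by ``k`` removes the k-1 highest merges (greedy top-down;
    height ties broken toward the later-created node). Cutting by
    ``max_height`` keeps the maximal subtrees whose merge height is at most
    the threshold (leaves count as height 0).
    """
    if (k is None) == (max_height is None):
        raise CatchError("cut_tree: specify exactly one of k, max_height")
    if k is not None:
        if k < 1:
            raise CatchError(f"cut_tree: k must be >= 1, got {k}")
        if k > root.n_leaves:
            raise CatchError(
                f"cut_tree: k={k} exceeds leaf count {root.n_leaves}"
            )
        groups = [root]
        while len(groups) < k:
            internal = [g for g in groups if not g.is_leaf]
            target = max(internal, key=lambda g: (g.height, g.order))
            groups.remove(target)
            groups.extend(target.children)
        return sorted(groups, key=lambda g: g.order)
    if max_height < 0:
        raise CatchError(f"cut_tree: max_height must be >= 0, got {max_height}")
    out: list[ClusterNode] = []

    def descend(node: ClusterNode) -> None:
        if node.is_leaf or node.height <= max_height:
            out.append(node)
        else:
            descend(node.children[0])
            descend(node.children[1])

    descend(root)
    return out


def cut_tree(
    root: ClusterNode, k: int | None = None, max_height: float | None = None
) -> list[set[str]]:
    """Partition of leaf ids induced by cutting the tree; see cut_tree_nodes."""
    return [set(n.placements) for n in cut_tree_nodes(root, k=k, max_height=max_height)]


def _newick_label(name: str) -> str:
    if any(c in name for c in "(),:;'\" \t\n[]"):
        return "'" + name.replace("'", "''") + "'"
    return name


def to_newick(root: ClusterNode) -> str:
    """Newick text with branch lengths = parent height - child height,
    floored at 0 (inversions would otherwise give negative lengths)."""

    def render(node: ClusterNode, parent_height: float | None) -> str:
        if node.is_leaf:
            body = _newick_label(node.node_id)
        else:
            body = "(%s,%s)" % (
                render(node.children[0], node.height),
                render(node.children[1], node.height),
            )
        if parent_height is None:
            return body
        bl = max(parent_height - node.height, 0.0)
        return f"{body}:{bl:.10g}"

    return render(root, None) + ";"


def reproject_profiles(
    profiles: dict[str, Profile], placements: dict[str, Placement]
) -> Profile:
    """Coverage-weighted average of profiles placed by offset/orientation.

    The output frame spans the union of the placed profiles; the frame
    origin is the minimum placement offset. With pruning disabled this
    reconstructs a cluster node's representative from its leaves.
    """
    if not placements:
        raise CatchError("reproject_profiles: empty placements")
    missing = set(placements) - set(profiles)
    if missing:
        raise CatchError(f"reproject_profiles: profiles missing for {sorted(missing)}")
    lo = min(pl.offset for pl in placements.values())
    hi = max(pl.offset + pl.length for pl in placements.values())
    length = hi - lo
    first = profiles[next(iter(placements))]
    t = first.n_tracks
    num = np.zeros((t, length))
    cov = np.zeros(length, dtype=np.int64)
    weight = 0
    for leaf, pl in placements.items():
        p = profiles[leaf]
        if p.n_bins != pl.length:
            raise CatchError(
                f"reproject_profiles: {leaf} has {p.n_bins} bins, placement says {pl.length}"
            )
        q = mirror_profile(p) if pl.mirrored else p
        sl = slice(pl.offset - lo, pl.offset - lo + pl.length)
        num[:, sl] += q.coverage * q.values
        cov[sl] += q.coverage
        weight += p.weight
    values = np.divide(num, cov, out=np.zeros_like(num), where=cov > 0)
    return Profile(
        id="reprojection",
        values=values,
        bin_size=first.bin_size,
        weight=weight,
        coverage=np.maximum(cov, 1),
        track_names=list(first.track_names),
    )
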