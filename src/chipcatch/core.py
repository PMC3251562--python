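"""Core data model: regions, signal tracks, profiles, alignments, tree nodes.

Coordinate conventions
----------------------
All genomic coordinates are 0-based half-open ([start, end)), matching BED
and bedGraph. Wiggle input is 1-based in the file and converted on read.

A :class:`Profile` is a dense T-track x L-bin matrix. Missing data is
resolved at extraction time (interpolation); profiles are always dense.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "GenomicRegion",
    "SignalTrack",
    "Profile",
    "AlignmentResult",
    "CatchParams",
    "Placement",
    "ClusterNode",
    "CatchError",
    "ParseError",
]

NORMALIZATION_METHODS = ("none", "per_track_max", "per_track_zscore")
SIMILARITY_MEASURES = ("ssd",)


class CatchError(ValueError):
    """Raised on invalid data or unsatisfiable algorithm constraints."""


class ParseError(CatchError):
    """Raised on malformed input files; message names the offending line."""


@dataclass(frozen=True)
class GenomicRegion:
    """A genomic window, 0-based half-open.

    ``strand`` is one of ``+``, ``-`` or ``.`` (unknown).
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise CatchError(f"region start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise CatchError(
                f"region start must be < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise CatchError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def label(self) -> str:
        return self.name if self.name else f"{self.chrom}:{self.start}-{self.end}"


class SignalTrack:
    """One genome-wide signal (one experiment/antibody).

    Per chromosome the data is three parallel arrays (starts, ends, values)
    of non-overlapping intervals sorted by start. Positions not covered by
    any interval are *missing*, not zero — the distinction drives
    interpolation at profile extraction.
    """

    def __init__(
        self,
        name: str,
        data: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
    ) -> None:
        self.name = name
        self.data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, values) in data.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=np.float64)
            if not (len(starts) == len(ends) == len(values)):
                raise CatchError(f"track {name}/{chrom}: ragged interval arrays")
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(starts >= ends):
                raise CatchError(f"track {name}/{chrom}: empty or inverted interval")
            if len(starts) > 1 and np.any(starts[1:] < ends[:-1]):
                raise CatchError(f"track {name}/{chrom}: overlapping intervals")
            self.data[chrom] = (starts, ends, values)

    @classmethod
    def from_intervals(
        cls, name: str, intervals: Mapping[str, list[tuple[int, int, float]]]
    ) -> "SignalTrack":
        data = {}
        for chrom, ivs in intervals.items():
            if not ivs:
                continue
            s, e, v = zip(*ivs)
            data[chrom] = (np.array(s), np.array(e), np.array(v, dtype=float))
        return cls(name, data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignalTrack):
            return NotImplemented
        if self.name != other.name or set(self.data) != set(other.data):
            return False
        return all(
            all(np.array_equal(a, b) for a, b in zip(self.data[c], other.data[c]))
            for c in self.data
        )

    def __repr__(self) -> str:
        n = sum(len(s) for s, _, _ in self.data.values())
        return f"SignalTrack({self.name!r}, {len(self.data)} chroms, {n} intervals)"


@dataclass
class Profile:
    """A T-track x L-bin signal matrix; the unit of alignment and merging.

    ``weight`` counts the leaf profiles represented; ``coverage`` counts,
    per bin, how many leaves contribute signal there.
    """

    id: str
    values: np.ndarray  # (T, L) float64
    bin_size: int = 1
    weight: int = 1
    coverage: np.ndarray | None = None  # (L,) int64
    track_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        t, length = self.values.shape
        if length < 1:
            raise CatchError(f"profile {self.id}: needs >= 1 bin")
        if self.bin_size < 1:
            raise CatchError(f"profile {self.id}: bin_size must be >= 1")
        if self.weight < 1:
            raise CatchError(f"profile {self.id}: weight must be >= 1")
        if self.coverage is None:
            self.coverage = np.ones(length, dtype=np.int64)
        else:
            self.coverage = np.asarray(self.coverage, dtype=np.int64)
        if self.coverage.shape != (length,):
            raise CatchError(f"profile {self.id}: coverage length mismatch")
        if np.any(self.coverage < 1) or np.any(self.coverage > self.weight):
            raise CatchError(
                f"profile {self.id}: coverage must lie in [1, weight={self.weight}]"
            )
        if not self.track_names:
            self.track_names = [f"track{i}" for i in range(t)]
        if len(self.track_names) != t:
            raise CatchError(f"profile {self.id}: {t} tracks, "
                             f"{len(self.track_names)} track names")

    @property
    def n_tracks(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def copy(self, **changes) -> "Profile":
        kwargs = dict(
            id=self.id,
            values=self.values.copy(),
            bin_size=self.bin_size,
            weight=self.weight,
            coverage=self.coverage.copy(),
            track_names=list(self.track_names),
        )
        kwargs.update(changes)
        return Profile(**kwargs)


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of one pairwise alignment.

    ``r`` is the shift of the second profile in bins: positive r moves it
    left relative to the first, negative r moves it right. ``score`` is the
    per-bin, per-track normalized sum of squared differences (lower is more
    similar).
    """

    r: int
    mirrored: bool
    score: float
    n_overlap: int
    n_total: int


@dataclass(frozen=True)
class CatchParams:
    """Tunable knobs of the alignment/clustering pipeline."""

    min_overlap_fraction: float = 0.5
    allow_mirror: bool = True
    normalization: str = "per_track_max"
    prune_fraction: float = 0.25
    similarity: str = "ssd"

    def __post_init__(self) -> None:
        if not (0.0 < self.min_overlap_fraction <= 1.0):
            raise CatchError(
                f"min_overlap_fraction must be in (0, 1], got {self.min_overlap_fraction}"
            )
        if not (0.0 <= self.prune_fraction <= 1.0):
            raise CatchError(
                f"prune_fraction must be in [0, 1], got {self.prune_fraction}"
            )
        if self.normalization not in NORMALIZATION_METHODS:
            raise CatchError(f"unknown normalization {self.normalization!r}")
        if self.similarity not in SIMILARITY_MEASURES:
            raise CatchError(f"unknown similarity {self.similarity!r}")

    def min_overlap_bins(self, l1: int, l2: int) -> int:
        # small epsilon guards float artefacts like 0.3 * 10 = 3.0000000000000004
        raw = self.min_overlap_fraction * min(l1, l2)
        return max(1, math.ceil(raw - 1e-9))


@dataclass(frozen=True)
class Placement:
    """Where one leaf sits inside a node's frame: bin offset, orientation,
    and the leaf's own length in bins (needed to compose mirrors)."""

    offset: int
    mirrored: bool
    length: int


@dataclass
class ClusterNode:
    """Binary dendrogram node.

    ``height`` is the merge score (leaves have height 0). Inversions
    (child higher than parent) are possible and permitted: centroid-style
    merging does not guarantee monotone heights.
    """

    node_id: str
    representative: Profile
    children: tuple["ClusterNode", "ClusterNode"] | None = None
    merge: AlignmentResult | None = None
    height: float = 0.0
    placements: dict[str, Placement] = field(default_factory=dict)
    order: int = 0  # creation index; used for deterministic tie-breaks

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    @property
    def n_leaves(self) -> int:
        return len(self.placements)

    def leaf_ids(self) -> frozenset[str]:
        return frozenset(self.placements)

    def iter_nodes(self) -> Iterator["ClusterNode"]:
        """Yield this node and all descendants (pre-order)."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            if node.children is not None:
                stack.extend(node.children)

    def validate(self) -> None:
        if self.n_leaves != self.representative.weight:
            raise CatchError(
                f"node {self.node_id}: {self.n_leaves} leaves but "
                f"representative weight {self.representative.weight}"
            )
        if self.children is not None:
            child_leaves = self.children[0].leaf_ids() | self.children[1].leaf_ids()
            if child_leaves != self.leaf_ids():
                raise CatchError(f"node {self.node_id}: placements/children mismatch")
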