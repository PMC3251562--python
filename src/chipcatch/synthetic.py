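"""Synthetic profile datasets with planted cluster structure.

Profiles are sums of Gaussian bumps plus optional i.i.d. Gaussian noise.
Each planted member gets a uniform integer shift of its peak centers, may
be mirrored, then receives noise — so alignment, orientation and recovery
behaviour are all known ground truth.

Randomness uses numpy's default generator (PCG64) seeded from the spec,
which fixes the stream across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .core import CatchError, Profile

__all__ = [
    "Peak",
    "PlantedSpec",
    "PlantedTruth",
    "make_profile",
    "generate_planted_dataset",
    "adjusted_rand_index",
]


class Peak(NamedTuple):
    center: float  # bin index
    width: float  # gaussian sigma, bins
    amplitude: float


class PlantedTruth(NamedTuple):
    cluster: int
    shift: int
    mirrored: bool


TrackPeaks = Sequence[Peak]  # peaks of one track
ClusterPeaks = Sequence[TrackPeaks]  # one entry per track


@dataclass(frozen=True)
class PlantedSpec:
    """Specification of a planted-cluster dataset."""

    n_clusters: int
    members_per_cluster: int
    n_tracks: int
    profile_len: int
    peak_spec: Sequence[ClusterPeaks]  # per cluster, per track, list of peaks
    max_shift: int = 0
    mirror_probability: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1 or self.members_per_cluster < 1:
            raise CatchError("spec: need >= 1 cluster and >= 1 member")
        if len(self.peak_spec) != self.n_clusters:
            raise CatchError(
                f"spec: peak_spec has {len(self.peak_spec)} entries for "
                f"{self.n_clusters} clusters"
            )
        if not (0.0 <= self.mirror_probability <= 1.0):
            raise CatchError("spec: mirror_probability must be in [0, 1]")
        if self.noise_sd < 0:
            raise CatchError("spec: noise_sd must be >= 0")
        if self.max_shift < 0 or self.max_shift >= self.profile_len / 2:
            raise CatchError("spec: require 0 <= max_shift < profile_len / 2")
        for c, cluster in enumerate(self.peak_spec):
            if len(cluster) != self.n_tracks:
                raise CatchError(f"spec: cluster {c} does not cover all tracks")
            for peaks in cluster:
                for peak in peaks:
                    center, width, amp = peak
                    if amp < 0:
                        raise CatchError("spec: amplitudes must be >= 0")
                    if width < 1:
                        raise CatchError("spec: widths must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "PlantedSpec":
        peak_spec = [
            [[Peak(*p) for p in track] for track in cluster]
            for cluster in d["peak_spec"]
        ]
        return cls(
            n_clusters=d["n_clusters"],
            members_per_cluster=d["members_per_cluster"],
            n_tracks=d["n_tracks"],
            profile_len=d["profile_len"],
            peak_spec=peak_spec,
            max_shift=d.get("max_shift", 0),
            mirror_probability=d.get("mirror_probability", 0.0),
            noise_sd=d.get("noise_sd", 0.0),
            seed=d.get("seed", 0),
        )


def _bump_matrix(
    peaks: Sequence[TrackPeaks], length: int
) -> np.ndarray:
    idx = np.arange(length, dtype=float)
    values = np.zeros((len(peaks), length))
    for t, track_peaks in enumerate(peaks):
        for center, width, amp in track_peaks:
            values[t] += amp * np.exp(-((idx - center) ** 2) / (2.0 * width**2))
    return values


def make_profile(
    peaks: Sequence[TrackPeaks],
    length: int,
    noise_sd: float,
    rng: np.random.Generator,
    profile_id: str = "synthetic",
    track_names: list[str] | None = None,
) -> Profile:
    """One profile: per track a sum of Gaussian bumps plus N(0, noise_sd^2)."""
    values = _bump_matrix(peaks, length)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    return Profile(id=profile_id, values=values, track_names=track_names or [])


def generate_planted_dataset(
    spec: PlantedSpec,
) -> tuple[list[Profile], dict[str, PlantedTruth]]:
    """Profiles with known cluster/shift/orientation ground truth.

    Each member's peak centers are shifted by a uniform integer in
    [-max_shift, max_shift] (positive moves the pattern toward higher
    bins), the whole profile is then mirrored with ``mirror_probability``,
    and finally noise is added. Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    track_names = [f"track{t}" for t in range(spec.n_tracks)]
    profiles: list[Profile] = []
    truth: dict[str, PlantedTruth] = {}
    for c in range(spec.n_clusters):
        for m in range(spec.members_per_cluster):
            pid = f"c{c}_m{m}"
            shift = int(rng.integers(-spec.max_shift, spec.max_shift + 1))
            mirrored = bool(rng.random() < spec.mirror_probability)
            shifted = [
                [Peak(center + shift, width, amp) for center, width, amp in track]
                for track in spec.peak_spec[c]
            ]
            values = _bump_matrix(shifted, spec.profile_len)
            if mirrored:
                values = values[:, ::-1].copy()
            if spec.noise_sd > 0:
                values = values + rng.normal(0.0, spec.noise_sd, size=values.shape)
            profiles.append(Profile(id=pid, values=values, track_names=track_names))
            truth[pid] = PlantedTruth(cluster=c, shift=shift, mirrored=mirrored)
    return profiles, truth


def adjusted_rand_index(
    partition_a: Sequence[set[str]], partition_b: Sequence[set[str]]
) -> float:
    """Chance-corrected agreement of two partitions of the same leaf set."""
    leaves_a = sorted(leaf for block in partition_a for leaf in block)
    leaves_b = sorted(leaf for block in partition_b for leaf in block)
    if leaves_a != leaves_b or len(set(leaves_a)) != len(leaves_a):
        raise CatchError("adjusted_rand_index: partitions cover different leaf sets")
    label_a = {leaf: i for i, block in enumerate(partition_a) for leaf in block}
    label_b = {leaf: i for i, block in enumerate(partition_b) for leaf in block}
    order = leaves_a
    return float(
        adjusted_rand_score([label_a[x] for x in order], [label_b[x] for x in order])
    )
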