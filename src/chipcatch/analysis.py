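"""Downstream statistics on clustering output.

Two computations: the correlation between profile orientation in a
cluster's alignment frame and an external annotation orientation (e.g. a
binding-motif strand), and meta-profiles (positional vs placement-aware
averages of a set of profiles).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .clustering import reproject_profiles
from .core import CatchError, Placement, Profile

__all__ = [
    "OrientationRow",
    "OrientationCorrelation",
    "orientation_correlation",
    "orientation_permutation_pvalue",
    "meta_profile",
]

# one row: (leaf_id, profile orientation ±1, annotation orientation ±1)
OrientationRow = tuple[str, int, int]


@dataclass(frozen=True)
class OrientationCorrelation:
    """Result of the orientation-correlation computation.

    ``correlation`` is |phi| maximized over the global flip of the profile
    orientation column (a cluster's frame has arbitrary handedness);
    ``flipped`` records whether the flip was applied; ``signed`` is the raw
    pre-flip coefficient. ``defined`` is False when either column is
    constant, in which case the coefficient does not exist (it is NOT 0).
    """

    defined: bool
    correlation: float | None = None
    flipped: bool | None = None
    signed: float | None = None


def _validate_table(table: Sequence[OrientationRow]) -> tuple[np.ndarray, np.ndarray]:
    if len(table) < 2:
        raise CatchError("orientation_correlation: need >= 2 rows")
    ids = [row[0] for row in table]
    if len(set(ids)) != len(ids):
        raise CatchError("orientation_correlation: duplicate leaf ids")
    prof = np.array([row[1] for row in table], dtype=int)
    anno = np.array([row[2] for row in table], dtype=int)
    if not np.isin(prof, (-1, 1)).all() or not np.isin(anno, (-1, 1)).all():
        raise CatchError("orientation_correlation: orientations must be +1 or -1")
    return prof, anno


def _phi(prof: np.ndarray, anno: np.ndarray) -> float | None:
    """Phi coefficient of the 2x2 table; equals the Pearson correlation of
    the two ±1 encodings. None when a margin is degenerate."""
    a = int(np.sum((prof == 1) & (anno == 1)))
    b = int(np.sum((prof == 1) & (anno == -1)))
    c = int(np.sum((prof == -1) & (anno == 1)))
    d = int(np.sum((prof == -1) & (anno == -1)))
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return None
    return (a * d - b * c) / float(np.sqrt(denom))


def orientation_correlation(table: Sequence[OrientationRow]) -> OrientationCorrelation:
    """Correlate profile orientation with annotation orientation.

    The statistic is the phi coefficient of the 2x2 orientation table,
    reported as a magnitude maximized over the global flip of the profile
    column (flip-maximized convention; the chosen flip is reported).
    Constant columns give an explicitly undefined result.
    """
    prof, anno = _validate_table(table)
    raw = _phi(prof, anno)
    if raw is None:
        return OrientationCorrelation(defined=False)
    return OrientationCorrelation(
        defined=True, correlation=abs(raw), flipped=raw < 0, signed=raw
    )


def orientation_permutation_pvalue(
    table: Sequence[OrientationRow],
    n_permutations: int = 10_000,
    seed: int = 0,
) -> float:
    """Two-sided permutation p-value for the orientation correlation.

    Permutes the annotation column; the test statistic is |phi|. Uses the
    add-one estimator (b+1)/(n+1).
    """
    prof, anno = _validate_table(table)
    observed = _phi(prof, anno)
    if observed is None:
        raise CatchError("orientation_permutation_pvalue: undefined statistic")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = _phi(prof, rng.permutation(anno))
        if perm is not None and abs(perm) >= abs(observed) - 1e-12:
            hits += 1
    return (hits + 1) / (n_permutations + 1)


def meta_profile(
    profiles: Sequence[Profile],
    placements: dict[str, Placement] | None = None,
    profile_id: str = "meta",
) -> Profile:
    """Average profile of a set, positionally or placement-aware.

    Without placements all profiles must share a length and the result is
    the plain per-bin coverage-weighted average (for weight-1 inputs: the
    arithmetic mean). With placements each profile is mirrored/offset per
    its placement first — the same re-projection machinery a cluster
    representative is built from.
    """
    if not profiles:
        raise CatchError("meta_profile: empty input")
    by_id = {p.id: p for p in profiles}
    if len(by_id) != len(profiles):
        raise CatchError("meta_profile: duplicate profile ids")
    if placements is None:
        lengths = {p.n_bins for p in profiles}
        if len(lengths) != 1:
            raise CatchError(
                "meta_profile: profiles of unequal length need placements"
            )
        placements = {p.id: Placement(0, False, p.n_bins) for p in profiles}
    else:
        missing = set(by_id) - set(placements)
        if missing:
            raise CatchError(f"meta_profile: placements missing for {sorted(missing)}")
    out = reproject_profiles(by_id, {pid: placements[pid] for pid in by_id})
    return out.copy(id=profile_id)
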