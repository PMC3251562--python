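import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from chipcatch import CatchParams, Peak, PlantedSpec, Profile


@pytest.fixture
def plain_params() -> CatchParams:
    """Params with everything that could mask a bug switched off."""
    return CatchParams(normalization="none", prune_fraction=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_profile(
    rng: np.random.Generator, pid: str, n_tracks: int, n_bins: int
) -> Profile:
    return Profile(
        id=pid,
        values=rng.normal(size=(n_tracks, n_bins)),
        track_names=[f"track{t}" for t in range(n_tracks)],
    )


def planted_spec_two_clusters(seed: int = 7, members: int = 4) -> PlantedSpec:
    """Two well-separated clusters with asymmetric patterns (so both the
    partition and the orientations are recoverable)."""
    return PlantedSpec(
        n_clusters=2,
        members_per_cluster=members,
        n_tracks=2,
        profile_len=40,
        peak_spec=[
            [[Peak(12, 3, 1.0), Peak(26, 3, 0.4)], []],
            [[Peak(15, 3, 1.0)], [Peak(25, 3, 1.0)]],
        ],
        max_shift=4,
        mirror_probability=0.5,
        noise_sd=0.05,
        seed=seed,
    )


def planted_spec_three_clusters(
    seed: int,
    members: int = 20,
    max_shift: int = 10,
    mirror_probability: float = 0.5,
    noise_sd: float = 0.1,
) -> PlantedSpec:
    """Three clusters, four tracks, L=100; distinct peak combinations per
    cluster, each asymmetric; peak amplitude 1.0 so noise_sd=0.1 is 10%."""
    return PlantedSpec(
        n_clusters=3,
        members_per_cluster=members,
        n_tracks=4,
        profile_len=100,
        peak_spec=[
            [
                [Peak(30, 4, 1.0), Peak(60, 4, 0.5)],
                [Peak(45, 4, 0.8)],
                [],
                [],
            ],
            [
                [],
                [Peak(35, 4, 1.0)],
                [Peak(55, 4, 1.0), Peak(70, 4, 0.4)],
                [],
            ],
            [
                [Peak(50, 4, 0.6)],
                [],
                [],
                [Peak(40, 4, 1.0), Peak(65, 4, 0.5)],
            ],
        ],
        max_shift=max_shift,
        mirror_probability=mirror_probability,
        noise_sd=noise_sd,
        seed=seed,
    )
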