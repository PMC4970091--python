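"""Shared fixtures: small rendered sequences and trained models.

Everything is generated at test time from the synthetic generator; the
small canvas and reduced forest size keep the suite fast while leaving
the geometry (stem band, petioles, leaves, nightly cadence) intact.
"""

from __future__ import annotations

import numpy as np
import pytest

from phenonode.pipeline import PipelineConfig, train_from_sequence
from phenonode.synthetic import SeedlingSpec, nightly_timestamps, render_sequence


def small_spec(**overrides) -> SeedlingSpec:
    defaults = dict(
        width=320,
        height=400,
        n_nodes=3,
        timestamps=nightly_timestamps(nights=4, per_night=3),
        seed=7,
    )
    defaults.update(overrides)
    return SeedlingSpec(**defaults)


@pytest.fixture(scope="session")
def small_sequence():
    spec = small_spec()
    frames, gt = render_sequence(spec)
    return spec, frames, gt


@pytest.fixture(scope="session")
def small_models(small_sequence):
    _, frames, gt = small_sequence
    config = PipelineConfig(n_trees=100, seed=7)
    return train_from_sequence(
        frames, gt, config,
        pixel_counts={0: 4000, 1: 4000, 2: 3000},
        n_node_patches=120, n_non_node_patches=150,
    ), config


@pytest.fixture(scope="session")
def test_sequence():
    """A second sequence, unseen by the trained models."""
    spec = small_spec(seed=8, stem_tilt=-4.0)
    frames, gt = render_sequence(spec)
    return spec, frames, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
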