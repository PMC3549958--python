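"""Shared fixtures: small rendered scenes reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from larvatrack import RunConfig, make_wander_scene, render_scene, track_movie


@pytest.fixture(scope="session")
def single_larva_scene():
    """One 40-px larva wandering with pauses and casts, 150 frames."""
    spec = make_wander_scene(1, 150, body_length=40.0, seed=3)
    frames, gt = render_scene(spec, keep_masks=True)
    return spec, frames, gt


@pytest.fixture(scope="session")
def single_larva_tracked(single_larva_scene):
    spec, frames, gt = single_larva_scene
    ts = track_movie(frames, RunConfig(seed=1))
    return ts, gt


@pytest.fixture(scope="session")
def five_larvae_tracked():
    """Five larvae in separate cells, 200 frames, tracked."""
    spec = make_wander_scene(5, 200, body_length=40.0, seed=12)
    frames, gt = render_scene(spec)
    ts = track_movie(frames, RunConfig(seed=2))
    return ts, gt


@pytest.fixture
def rect_mask():
    """A filled 8 x 60 horizontal bar (analytic midline oracle)."""
    m = np.zeros((30, 80), dtype=bool)
    m[10:18, 10:70] = True
    return m
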