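"""Shared fixtures: one small synthetic flight reused across test modules.

Everything is generated programmatically — no stored image data.
"""

from __future__ import annotations

import numpy as np
import pytest

from fieldmosaic.synthetic import (GroundTruth, SyntheticScene,
                                   TrajectorySpec, make_field_texture,
                                   make_trajectory, render_frames)

FRAME_SIZE = (256, 192)          # (width, height)


@pytest.fixture(scope="session")
def scene() -> SyntheticScene:
    return make_field_texture(1600, 1200, seed=7)


@pytest.fixture(scope="session")
def flight(scene) -> tuple[TrajectorySpec, GroundTruth, list]:
    spec = TrajectorySpec(kind="out_and_back", n_frames=20,
                          frame_size=FRAME_SIZE, overlap_target=0.9)
    gt = make_trajectory(scene, spec, seed=3)
    frames = render_frames(scene, gt, seed=3)
    return spec, gt, frames


@pytest.fixture(scope="session")
def gt(flight) -> GroundTruth:
    return flight[1]


@pytest.fixture(scope="session")
def frames(flight) -> list:
    return flight[2]


def gt_registration(gt: GroundTruth):
    """A registration provider that returns exact ground-truth transforms."""

    class _Result:
        def __init__(self, matrix: np.ndarray):
            self.matrix = matrix

    def register(frame, reference):
        return _Result(gt.relative(frame.index, reference.index))

    return register
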