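"""Grouping rules, homography chaining, canvas estimation, pixel filling."""

import numpy as np
import pytest

from fieldmosaic.geometry import (DegenerateTransformError, translation)
from fieldmosaic.mosaic import (CanvasSpec, ChainBreakError,
                                CanvasOverflowError, FrameGroup,
                                MosaicCanvas, UnmergeableShotsError,
                                assign_groups, build_mini_mosaic,
                                chain_homographies, estimate_canvas,
                                meta_mosaic, warp_and_blend)
from fieldmosaic.preprocess import Frame

from conftest import FRAME_SIZE, gt_registration


def motion_registration(step_x=0.0, step_y=0.0):
    """Stub register: frame i is displaced by (i-ref) * step from its ref."""

    class _R:
        def __init__(self, m):
            self.matrix = m

    def register(frame, reference):
        k = frame.index - reference.index
        return _R(translation(k * step_x, k * step_y))

    return register


def make_frames(n, width=120, height=90):
    rng = np.random.default_rng(0)
    img = rng.integers(0, 256, size=(height, width, 3), dtype=np.uint8)
    return [Frame(index=i + 1, image=img) for i in range(n)]


class TestAssignGroups:
    def test_zero_motion_single_group(self):
        frames = make_frames(10)
        groups, _ = assign_groups(frames, motion_registration(0, 0))
        assert len(groups) == 1
        assert groups[0].members == list(range(1, 11))

    def test_41st_member_starts_new_group(self):
        frames = make_frames(45)
        groups, _ = assign_groups(frames, motion_registration(0, 0))
        assert [len(g.members) for g in groups] == [40, 5]
        assert groups[1].reference_frame == 41

    def test_displacement_over_one_third_height_splits(self):
        frames = make_frames(4, width=300, height=100)
        # one step of 0.34 x height exceeds the one-third threshold
        groups, _ = assign_groups(frames, motion_registration(0, 34.0))
        assert len(groups) == 4           # every frame displaced past limit

    def test_displacement_under_one_third_does_not_split(self):
        frames = make_frames(2, width=300, height=100)
        groups, _ = assign_groups(frames, motion_registration(0, 30.0))
        assert len(groups) == 1

    def test_axiswise_width_rule(self):
        frames = make_frames(2, width=90, height=300)
        groups, _ = assign_groups(frames, motion_registration(31.0, 0))
        assert len(groups) == 2           # |dx| > width/3 even though < h/3

    def test_new_reference_gets_identity_hcr_and_direct_hrr(self):
        frames = make_frames(3, width=90, height=90)
        groups, _ = assign_groups(frames, motion_registration(40.0, 0))
        g2 = groups[1]
        assert np.allclose(g2.h_cr[g2.reference_frame], np.eye(3))
        assert np.allclose(g2.h_rr, translation(40, 0))


class TestChainHomographies:
    def test_all_identity_inputs_identity_chain(self):
        groups = [FrameGroup(index=1, reference_frame=1, members=[1, 2, 3],
                             h_cr={i: np.eye(3) for i in (1, 2, 3)},
                             h_rr=np.eye(3))]
        chain = chain_homographies(groups)
        for i in (1, 2, 3):
            assert np.allclose(chain.h_cb[i], np.eye(3))

    def test_two_group_translation_example(self):
        # H_RR = T(10,0); member H_CR = T(3,0) -> H_CB = T(13,0)
        groups = [
            FrameGroup(index=1, reference_frame=1, members=[1],
                       h_cr={1: np.eye(3)}, h_rr=np.eye(3)),
            FrameGroup(index=2, reference_frame=2, members=[2, 3],
                       h_cr={2: np.eye(3), 3: translation(3, 0)},
                       h_rr=translation(10, 0)),
        ]
        chain = chain_homographies(groups)
        assert np.allclose(chain.h_cb[3], translation(13, 0))
        assert np.allclose(chain.h_cb[2], translation(10, 0))

    def test_base_frame_maps_to_identity(self):
        groups = [FrameGroup(index=1, reference_frame=5, members=[5, 6],
                             h_cr={5: np.eye(3), 6: translation(1, 1)},
                             h_rr=np.eye(3))]
        chain = chain_homographies(groups)
        assert chain.base_frame == 5
        assert np.allclose(chain.h_cb[5], np.eye(3))

    def test_matches_brute_force_matrix_products(self):
        rng = np.random.default_rng(8)
        from fieldmosaic.geometry import similarity
        groups = []
        h_rr_list = [np.eye(3)]
        for g in range(1, 4):
            h_rr = similarity(scale=rng.uniform(0.9, 1.1),
                              angle_deg=rng.uniform(-10, 10),
                              tx=rng.uniform(-5, 5), ty=rng.uniform(-5, 5))
            members = list(range(g * 10, g * 10 + 4))
            h_cr = {members[0]: np.eye(3)}
            for m in members[1:]:
                h_cr[m] = similarity(tx=rng.uniform(-8, 8),
                                     ty=rng.uniform(-8, 8))
            groups.append(FrameGroup(index=g, reference_frame=members[0],
                                     members=members, h_cr=h_cr,
                                     h_rr=np.eye(3) if g == 1 else h_rr))
            if g > 1:
                h_rr_list.append(h_rr)
        chain = chain_homographies(groups)
        running = np.eye(3)
        for g, grp in enumerate(groups, start=1):
            if g > 1:
                running = running @ h_rr_list[g - 1]
            for m in grp.members:
                expected = running @ grp.h_cr[m]
                expected = expected / expected[2, 2]
                assert np.allclose(chain.h_cb[m], expected, atol=1e-12)

    def test_missing_hcr_raises_chain_break(self):
        groups = [FrameGroup(index=1, reference_frame=1, members=[1, 2],
                             h_cr={1: np.eye(3)}, h_rr=np.eye(3))]
        with pytest.raises(ChainBreakError, match="frame 2"):
            chain_homographies(groups)

    def test_singular_hrr_raises_chain_break(self):
        groups = [
            FrameGroup(index=1, reference_frame=1, members=[1],
                       h_cr={1: np.eye(3)}, h_rr=np.eye(3)),
            FrameGroup(index=2, reference_frame=2, members=[2],
                       h_cr={2: np.eye(3)}, h_rr=np.zeros((3, 3))),
        ]
        with pytest.raises(ChainBreakError):
            chain_homographies(groups)


class TestEstimateCanvas:
    def chain_of(self, h_cbs):
        from fieldmosaic.mosaic import HomographyChain
        return HomographyChain(h_cr={}, h_rb={},
                               h_cb={i + 1: H for i, H in enumerate(h_cbs)},
                               group_of={}, base_frame=1)

    def test_single_identity_frame(self):
        spec = estimate_canvas(self.chain_of([np.eye(3)]), (100, 80))
        assert (spec.width, spec.height) == (100, 80)
        assert spec.offset == (0, 0)

    def test_translated_frame_extends_canvas(self):
        spec = estimate_canvas(
            self.chain_of([np.eye(3), translation(100, 0)]), (200, 80))
        assert spec.width == 300
        assert spec.offset == (0, 0)

    def test_negative_translation_shifts_offset(self):
        spec = estimate_canvas(
            self.chain_of([np.eye(3), translation(-50, -50)]), (100, 80))
        assert spec.offset == (50, 50)
        assert (spec.width, spec.height) == (150, 130)

    def test_nonfinite_corner_raises(self):
        H = np.eye(3); H = H.copy(); H[2, 0] = np.nan
        with pytest.raises(DegenerateTransformError):
            estimate_canvas(self.chain_of([H]), (100, 80))

    def test_exploding_canvas_rejected(self):
        with pytest.raises(CanvasOverflowError):
            estimate_canvas(
                self.chain_of([np.eye(3), translation(1e6, 0)]), (100, 80))


class TestWarpAndBlend:
    def test_first_frame_fills_footprint_exactly(self):
        frame = make_frames(1)[0]
        canvas = MosaicCanvas.empty(CanvasSpec(120, 90, (0, 0)))
        warp_and_blend(canvas, frame, np.eye(3))
        assert np.array_equal(canvas.image, frame.image)
        assert np.all(canvas.provenance == 1)

    def test_reblending_is_noop(self):
        frame = make_frames(1)[0]
        canvas = MosaicCanvas.empty(CanvasSpec(120, 90, (0, 0)))
        warp_and_blend(canvas, frame, np.eye(3))
        before = canvas.image.copy()
        warp_and_blend(canvas, frame, np.eye(3))
        assert np.array_equal(canvas.image, before)
        assert np.all(canvas.provenance == 1)

    def test_overlap_keeps_earliest_frame_pixels(self):
        f1, f2 = make_frames(2, width=100, height=50)
        f2 = Frame(index=2, image=np.full((50, 100, 3), 200, np.uint8))
        canvas = MosaicCanvas.empty(CanvasSpec(150, 50, (0, 0)))
        warp_and_blend(canvas, f1, np.eye(3))
        warp_and_blend(canvas, f2, translation(50, 0))
        # overlap [50, 99] retains frame 1; only [100, 149] is frame 2
        assert np.array_equal(canvas.image[:, :100], f1.image)
        assert np.all(canvas.provenance[:, :100] == 1)
        assert np.all(canvas.provenance[:, 100:] == 2)
        assert np.all(canvas.image[:, 100:] == 200)

    def test_filled_count_non_decreasing(self):
        f1, f2 = make_frames(2, width=100, height=50)
        canvas = MosaicCanvas.empty(CanvasSpec(200, 50, (0, 0)))
        warp_and_blend(canvas, f1, np.eye(3))
        n1 = canvas.n_filled
        warp_and_blend(canvas, f2, translation(60, 0))
        assert canvas.n_filled >= n1

    def test_footprint_outside_canvas_raises(self):
        frame = make_frames(1)[0]
        canvas = MosaicCanvas.empty(CanvasSpec(100, 80, (0, 0)))
        with pytest.raises(CanvasOverflowError):
            warp_and_blend(canvas, frame, translation(500, 0))


class TestBuildMiniMosaic:
    def test_single_frame_shot_returns_the_frame(self, frames):
        mini = build_mini_mosaic(frames[:1], seed=0)
        assert np.array_equal(mini.canvas.image, frames[0].image)
        assert np.allclose(mini.chain.h_cb[frames[0].index], np.eye(3))

    def test_ground_truth_chain_composition_closure(self, frames, gt):
        mini = build_mini_mosaic(frames, register=gt_registration(gt))
        for i, H_cb in mini.chain.h_cb.items():
            g = mini.chain.group_of[i]
            expected = mini.chain.h_rb[g] @ mini.chain.h_cr[i]
            assert np.allclose(H_cb, expected / expected[2, 2], atol=1e-12)

    def test_provenance_unique_and_complete_coverage(self, frames, gt):
        mini = build_mini_mosaic(frames, register=gt_registration(gt))
        prov = mini.canvas.provenance
        used = np.unique(prov)
        assert used[0] == 0
        assert set(used[1:]) <= {f.index for f in frames}
        assert mini.canvas.n_filled > 0.5 * prov.size

    def test_empty_shot_rejected(self):
        with pytest.raises(ValueError):
            build_mini_mosaic([])


class TestMetaMosaic:
    def test_single_mini_passthrough_bit_identical(self, frames):
        mini = build_mini_mosaic(frames[:1], seed=0)
        meta = meta_mosaic([mini])
        assert meta is mini.canvas

    def test_disjoint_shots_raise_with_minis_attached(self, scene):
        from fieldmosaic.synthetic import TrajectorySpec, make_trajectory, \
            render_frames
        a = TrajectorySpec(kind="out_and_back", n_frames=6,
                           frame_size=(192, 144), overlap_target=0.9)
        gta = make_trajectory(scene, a, seed=1)
        fa = render_frames(scene, gta, seed=1)
        # far-away frames: reuse the same trajectory but different texture
        other = np.ascontiguousarray(scene.texture[::-1, ::-1])
        from fieldmosaic.synthetic import SyntheticScene
        scene_b = SyntheticScene(texture=other, row_period=48,
                                 alley_period=64, rng_seed=0)
        fb = render_frames(scene_b, gta, seed=1)
        m1 = build_mini_mosaic(fa, seed=0, shot_index=1)
        m2 = build_mini_mosaic(fb, seed=0, shot_index=2)
        with pytest.raises(UnmergeableShotsError) as exc:
            meta_mosaic([m1, m2], seed=0)
        assert len(exc.value.minis) == 2
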