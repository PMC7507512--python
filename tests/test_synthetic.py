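"""Synthetic flight generator: texture structure, trajectory contracts,
ground-truth rendering."""

import numpy as np
import pytest

from fieldmosaic.geometry import apply_homography, frame_corners, similarity
from fieldmosaic.synthetic import (ConfigurationError, GroundTruth,
                                   TrajectorySpec, make_field_texture,
                                   make_trajectory, render_frames,
                                   true_orthomosaic)

# ---------------------------------------------------------------------------
# independent convex-polygon clipping oracle (Sutherland-Hodgman + shoelace)


def _clip(subject, cx1, cy1, cx2, cy2):
    def inside(p):
        return (cx2 - cx1) * (p[1] - cy1) - (cy2 - cy1) * (p[0] - cx1) <= 0

    def intersect(a, b):
        dx1, dy1 = b[0] - a[0], b[1] - a[1]
        dx2, dy2 = cx2 - cx1, cy2 - cy1
        denom = dx1 * dy2 - dy1 * dx2
        t = ((cx1 - a[0]) * dy2 - (cy1 - a[1]) * dx2) / denom
        return (a[0] + t * dx1, a[1] + t * dy1)

    out = []
    for i, cur in enumerate(subject):
        prev = subject[i - 1]
        if inside(cur):
            if not inside(prev):
                out.append(intersect(prev, cur))
            out.append(tuple(cur))
        elif inside(prev):
            out.append(intersect(prev, cur))
    return out


def _area(poly):
    if len(poly) < 3:
        return 0.0
    x = np.array([p[0] for p in poly])
    y = np.array([p[1] for p in poly])
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def oracle_iou(poly_a, poly_b):
    """IoU of two convex quads, clockwise or counterclockwise."""
    def cw(p):
        p = np.asarray(p, dtype=float)
        area = 0.5 * (np.dot(p[:, 0], np.roll(p[:, 1], -1))
                      - np.dot(p[:, 1], np.roll(p[:, 0], -1)))
        return p if area < 0 else p[::-1]

    a, b = cw(poly_a), cw(poly_b)
    clipped = [tuple(p) for p in a]
    for i in range(len(b)):
        j = (i + 1) % len(b)
        clipped = _clip(clipped, b[i][0], b[i][1], b[j][0], b[j][1])
        if not clipped:
            break
    inter = _area(clipped)
    union = _area([tuple(p) for p in a]) + _area([tuple(p) for p in b]) - inter
    return inter / union if union > 0 else 0.0


# ---------------------------------------------------------------------------


class TestFieldTexture:
    def test_deterministic_for_fixed_seed(self):
        a = make_field_texture(400, 300, seed=5)
        b = make_field_texture(400, 300, seed=5)
        assert np.array_equal(a.texture, b.texture)

    def test_different_seed_differs(self):
        a = make_field_texture(400, 300, seed=5)
        b = make_field_texture(400, 300, seed=6)
        assert not np.array_equal(a.texture, b.texture)

    def test_zero_speckle_equal_periods_exactly_periodic(self):
        p = 40
        s = make_field_texture(400, 400, row_period=p, alley_period=p,
                               seed=0, speckle=0.0, psf_sigma=0.0)
        g = s.texture[..., 1].astype(float)
        assert np.array_equal(g[:360], g[p:360 + p])
        # autocorrelation of the column profile peaks at lag = row_period
        prof = g.mean(axis=1) - g.mean()
        n = len(prof)
        lags = range(1, 3 * p)
        ac = [np.dot(prof[:n - l], prof[l:]) / (n - l) for l in lags]
        assert int(np.argmax(ac)) + 1 == p

    def test_row_band_count_matches_floor(self):
        height, period = 600, 60
        s = make_field_texture(300, height, row_period=period,
                               alley_period=300, seed=0, speckle=0.0,
                               psf_sigma=0.0)
        # a column through crop (not in an alley): count green runs
        col = s.texture[:, 150, 1].astype(int)
        is_crop = col > 100
        n_bands = int(np.sum(is_crop[1:] & ~is_crop[:-1]) + is_crop[0])
        assert n_bands == height // period

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            make_field_texture(0, 100)
        with pytest.raises(ValueError):
            make_field_texture(100, 100, row_period=-3)


class TestTrajectory:
    def test_single_placement_is_similarity_with_axis_aligned_footprint(self,
                                                                        scene):
        spec = TrajectorySpec(kind="out_and_back", n_frames=2,
                              frame_size=(100, 80), overlap_target=0.95,
                              jitter=0.0)
        gt = make_trajectory(scene, spec, seed=0)
        H = gt.homographies[0]
        # pure translation+scale: no rotation or perspective terms
        assert H[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert H[1, 0] == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(H[2, :2], 0.0)
        fp = gt.footprints[0]
        assert fp[0, 1] == pytest.approx(fp[1, 1])   # top edge horizontal
        assert fp[0, 0] == pytest.approx(fp[3, 0])   # left edge vertical

    @pytest.mark.parametrize("kind", ["out_and_back", "serpentine", "orbit",
                                      "composite"])
    def test_overlap_contract_against_clipping_oracle(self, scene, kind):
        spec = TrajectorySpec(kind=kind, n_frames=40, frame_size=(256, 192),
                              overlap_target=0.88)
        gt = make_trajectory(scene, spec, seed=2)
        ious = [oracle_iou(gt.footprints[i], gt.footprints[i + 1])
                for i in range(gt.n_frames - 1)]
        assert min(ious) >= 0.88 - 0.02

    def test_footprints_match_homographies(self, gt):
        w, h = gt.frame_size
        for H, fp in zip(gt.homographies, gt.footprints):
            assert np.allclose(apply_homography(H, frame_corners(w, h)), fp)

    def test_shot_break_forces_low_overlap_once(self, scene):
        spec = TrajectorySpec(kind="out_and_back", n_frames=40,
                              frame_size=(256, 192), overlap_target=0.9,
                              shot_breaks=[20])
        gt = make_trajectory(scene, spec, seed=1)
        ious = [oracle_iou(gt.footprints[i], gt.footprints[i + 1])
                for i in range(gt.n_frames - 1)]
        low = [i + 1 for i, v in enumerate(ious) if v < 0.1]
        assert low == [20]

    def test_footprint_area_conserved_for_affine_truth(self, gt):
        w, h = gt.frame_size
        frame_area = (w - 1.0) * (h - 1.0)
        for H, fp in zip(gt.homographies, gt.footprints):
            det = abs(np.linalg.det(H[:2, :2]))
            assert _area([tuple(p) for p in fp]) == pytest.approx(
                frame_area * det, rel=0.01)

    def test_infeasible_trajectory_raises(self):
        tiny = make_field_texture(500, 400, seed=0)
        spec = TrajectorySpec(kind="out_and_back", n_frames=200,
                              frame_size=(256, 192), overlap_target=0.5)
        with pytest.raises(ConfigurationError):
            make_trajectory(tiny, spec, seed=0)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            TrajectorySpec(n_frames=1)
        with pytest.raises(ValueError):
            TrajectorySpec(overlap_target=0.0)
        with pytest.raises(ValueError):
            TrajectorySpec(n_frames=10, shot_breaks=[5, 5])
        with pytest.raises(ValueError):
            TrajectorySpec(n_frames=10, shot_breaks=[10])


class TestRendering:
    def test_identity_homography_renders_exact_crop(self, scene):
        from fieldmosaic.geometry import translation
        H = translation(200, 100)
        gt1 = GroundTruth(
            homographies=np.array([H]),
            footprints=np.array([apply_homography(H, frame_corners(64, 48))]),
            frame_size=(64, 48), shot_breaks=[])
        frame = render_frames(scene, gt1)[0]
        assert np.array_equal(frame.image,
                              scene.texture[100:148, 200:264])

    def test_rotation_roundtrip_rmse_small(self, scene):
        c = (500.0, 500.0)
        H = similarity(angle_deg=30.0, center=c)
        Hm = similarity(angle_deg=-30.0, center=c)
        base = scene.texture[400:600, 400:600].astype(float)
        from fieldmosaic.mosaic import warp_image
        rot, v1 = warp_image(scene.texture, similarity(angle_deg=30.0,
                                                       center=(500, 500)),
                             scene.texture.shape[:2])
        back, v2 = warp_image(rot, similarity(angle_deg=-30.0,
                                              center=(500, 500)),
                              scene.texture.shape[:2])
        roi = np.zeros(scene.texture.shape[:2], bool)
        roi[400:600, 400:600] = True
        roi &= v1 & v2
        diff = back[roi] - scene.texture.astype(float)[roi]
        assert np.sqrt(np.mean(diff ** 2)) < 2.0

    def test_render_deterministic_with_noise(self, scene, gt):
        a = render_frames(scene, gt, noise_sigma=3.0, seed=11)
        b = render_frames(scene, gt, noise_sigma=3.0, seed=11)
        assert all(np.array_equal(x.image, y.image) for x, y in zip(a, b))

    def test_illumination_drift_recorded_and_applied(self, scene, gt):
        frames = render_frames(scene, gt, illum_drift=0.2, seed=0)
        assert frames[0].metadata["gain"] == pytest.approx(1.0)
        assert frames[-1].metadata["gain"] == pytest.approx(1.2)
        plain = render_frames(scene, gt, seed=0)
        assert frames[-1].image.mean() > 1.1 * plain[-1].image.mean()

    def test_out_of_bounds_footprint_raises_with_frame_index(self, scene):
        H = np.eye(3)
        H = H.copy(); H[0, 2] = scene.width - 10   # footprint exits texture
        gtbad = GroundTruth(
            homographies=np.array([H]),
            footprints=np.array([apply_homography(H, frame_corners(64, 48))]),
            frame_size=(64, 48), shot_breaks=[])
        with pytest.raises(ValueError, match="frame 1"):
            render_frames(scene, gtbad)

    def test_true_orthomosaic_covers_footprints(self, scene, gt):
        ortho, T = true_orthomosaic(scene, gt)
        fp = gt.footprints.reshape(-1, 2)
        shifted = apply_homography(T, fp)
        assert shifted.min() >= -1.0
        assert shifted[:, 0].max() <= ortho.shape[1]
        assert shifted[:, 1].max() <= ortho.shape[0]
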