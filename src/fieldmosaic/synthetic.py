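"""Synthetic aerial flights over a planar crop field, with ground truth.

The simulator emulates the conditions that make crop-field video hard to
mosaic: a planar field whose crop rows and alleys form a repetitive visual
checkerboard, a smooth low-altitude camera trajectory with large
frame-to-frame overlap, and occasional abrupt viewpoint jumps (shot breaks).
Every frame carries an exact frame->scene homography, so registration and
mosaicking can be validated against ground truth.

Not modelled: 3D terrain, rolling shutter, plant motion between frames.
Sensor noise is generic (additive Gaussian plus multiplicative illumination
drift), not a calibrated model of field conditions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage.transform import ProjectiveTransform, warp

from .geometry import (footprint_polygon, invert, normalize_homography,
                       polygon_iou, similarity)
from .preprocess import Frame

__all__ = ["SyntheticScene", "TrajectorySpec", "GroundTruth",
           "make_field_texture", "make_trajectory", "render_frames",
           "true_orthomosaic", "save_dataset", "load_ground_truth",
           "ConfigurationError"]

TRAJECTORY_KINDS = ("serpentine", "orbit", "out_and_back", "composite")


class ConfigurationError(ValueError):
    """Trajectory cannot be realised inside the given scene/frame geometry."""


@dataclass
class SyntheticScene:
    """Planar field texture with known row/alley periods."""

    texture: np.ndarray          # (H, W, 3) uint8
    row_period: int              # pixels between crop-row band centers (along y)
    alley_period: int            # pixels between alleys (along x)
    rng_seed: int

    @property
    def height(self) -> int:
        return self.texture.shape[0]

    @property
    def width(self) -> int:
        return self.texture.shape[1]


@dataclass
class TrajectorySpec:
    """Parameters of a simulated camera path.

    ``overlap_target`` is the desired IoU between consecutive frame
    footprints; ``jitter`` adds a per-frame random perturbation (its value is
    the translation scale in pixels; rotational jitter is 0.02 deg per pixel
    of translation scale). A shot break at index ``b`` injects an abrupt
    viewpoint jump between frames ``b`` and ``b + 1`` (``b`` is the last
    frame of the preceding shot).
    """

    kind: str = "out_and_back"
    n_frames: int = 100
    frame_size: tuple[int, int] = (320, 240)       # (width, height)
    overlap_target: float = 0.9
    jitter: float = 0.0
    shot_breaks: list[int] = field(default_factory=list)
    scale: float = 1.0       # scene pixels per frame pixel (altitude proxy)

    def __post_init__(self) -> None:
        if self.kind not in TRAJECTORY_KINDS:
            raise ValueError(f"unknown trajectory kind {self.kind!r}")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if not 0.0 < self.overlap_target <= 1.0:
            raise ValueError("overlap_target must be in (0, 1]")
        breaks = list(self.shot_breaks)
        if breaks != sorted(set(breaks)):
            raise ValueError("shot_breaks must be strictly increasing")
        if any(not (1 < b < self.n_frames) for b in breaks):
            raise ValueError("shot_breaks must lie within (1, n_frames)")


@dataclass
class GroundTruth:
    """Per-frame truth for a simulated flight.

    ``homographies[i]`` maps frame ``i+1`` coordinates into scene (texture)
    coordinates; footprints are the frame corners mapped by that truth.
    """

    homographies: np.ndarray     # (n, 3, 3), each normalized
    footprints: np.ndarray       # (n, 4, 2) scene coordinates
    frame_size: tuple[int, int]
    shot_breaks: list[int]

    @property
    def n_frames(self) -> int:
        return len(self.homographies)

    def relative(self, i: int, j: int) -> np.ndarray:
        """True homography mapping frame i coordinates into frame j (1-based)."""
        return normalize_homography(
            invert(self.homographies[j - 1]) @ self.homographies[i - 1])


def make_field_texture(width: int, height: int, row_period: int = 48,
                       alley_period: int = 64, seed: int = 0,
                       speckle: float = 0.5,
                       psf_sigma: float = 0.8) -> SyntheticScene:
    """Generate a crop-field texture: periodic row/alley bands plus speckle.

    Crop rows are horizontal green bands repeating every ``row_period``
    pixels along y; alleys are soil-coloured vertical gaps repeating every
    ``alley_period`` pixels along x, so rows and alleys intersect at right
    angles in a checkerboard. ``speckle`` (0 disables) adds seeded per-plant
    intensity variation so feature detectors find keypoints, while the
    underlying pattern repeats — the repetitive-feature stressor of real
    crop imagery. ``psf_sigma`` applies a light Gaussian blur emulating the
    camera's optical point-spread function (real imagery never has
    one-pixel step edges); set it to 0 for an exactly crisp pattern.
    Deterministic for a fixed seed.
    """
    if width <= 0 or height <= 0 or row_period <= 0 or alley_period <= 0:
        raise ValueError("dimensions and periods must be positive")
    rng = np.random.default_rng(seed)
    y = np.arange(height)
    x = np.arange(width)
    # crop present in the middle 60% of each row period / between alleys
    row_phase = (y % row_period) / row_period
    alley_phase = (x % alley_period) / alley_period
    row_mask = ((row_phase >= 0.2) & (row_phase < 0.8)).astype(float)
    alley_mask = ((alley_phase >= 0.12) & (alley_phase < 0.88)).astype(float)
    crop = row_mask[:, None] * alley_mask[None, :]

    soil = np.array([120.0, 96.0, 70.0])
    plant = np.array([52.0, 130.0, 46.0])
    img = soil[None, None, :] * (1 - crop[..., None]) \
        + plant[None, None, :] * crop[..., None]

    if speckle > 0:
        # canopy brightness variation at two scales: leaf-scale detail plus
        # plant-crown-scale blobs (crowns span a substantial fraction of the
        # row spacing in real canopies), crop pixels only
        leaves = ndimage.gaussian_filter(
            rng.standard_normal((height, width)), sigma=3.0)
        crowns = ndimage.gaussian_filter(
            rng.standard_normal((height, width)), sigma=8.0)
        blobs = leaves / leaves.std() + 1.2 * crowns / crowns.std()
        blobs = blobs / (np.std(blobs) + 1e-12)
        img += 40.0 * speckle * (blobs * crop)[..., None]
        # faint soil-texture grain everywhere so bare ground is not flat
        grain = ndimage.gaussian_filter(
            rng.standard_normal((height, width)), sigma=1.0)
        img += 12.0 * speckle * grain[..., None]
        # broad diagonal brightness gradient (soil moisture / vigor trend
        # across the field): real fields are not statistically stationary,
        # so large displacements shift the global intensity distribution
        # in proportion to the distance moved
        theta = np.deg2rad(rng.uniform(25.0, 65.0))
        sign = rng.choice([-1.0, 1.0], size=2)
        gx = sign[0] * np.cos(theta) * (x - width / 2.0) / width
        gy = sign[1] * np.sin(theta) * (y - height / 2.0) / height
        grad = gy[:, None] + gx[None, :]
        img *= (1.0 + 0.35 * speckle * grad)[..., None]
    if psf_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=(psf_sigma, psf_sigma, 0))
    texture = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return SyntheticScene(texture=texture, row_period=row_period,
                          alley_period=alley_period, rng_seed=seed)


def _placement(center_xy: tuple[float, float], angle_deg: float, scale: float,
               frame_size: tuple[int, int]) -> np.ndarray:
    """Frame->scene homography putting the frame center at ``center_xy``."""
    w, h = frame_size
    fcx, fcy = (w - 1) / 2.0, (h - 1) / 2.0
    # scale + rotate about the frame center, then move center to center_xy
    RS = similarity(scale=scale, angle_deg=angle_deg)
    T_out = np.array([[1.0, 0.0, center_xy[0]],
                      [0.0, 1.0, center_xy[1]],
                      [0.0, 0.0, 1.0]])
    T_in = np.array([[1.0, 0.0, -fcx], [0.0, 1.0, -fcy], [0.0, 0.0, 1.0]])
    return normalize_homography(T_out @ RS @ T_in)


def _footprint(center, angle, scale, frame_size):
    return footprint_polygon(_placement(center, angle, scale, frame_size),
                             *frame_size)


def _solve_step(frame_size: tuple[int, int], scale: float, overlap: float,
                direction: np.ndarray, dangle: float = 0.0) -> float:
    """Step length along ``direction`` giving consecutive-footprint IoU ==
    ``overlap`` (bisection against the polygon-intersection oracle)."""
    w, h = frame_size
    c0 = (0.0, 0.0)
    f0 = _footprint(c0, 0.0, scale, frame_size)

    def iou_at(d: float) -> float:
        c1 = tuple(np.asarray(c0) + d * direction)
        return polygon_iou(f0, _footprint(c1, dangle, scale, frame_size))

    lo, hi = 0.0, scale * max(w, h) * 2.0
    if iou_at(hi) > overlap:     # even the largest step overlaps enough
        return hi
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if iou_at(mid) >= overlap:
            lo = mid
        else:
            hi = mid
    return lo


def _waypoints(spec: TrajectorySpec, scene: SyntheticScene,
               rng: np.random.Generator) -> list[tuple[np.ndarray, float]]:
    """Ideal (center, heading-angle) per frame, before jitter and breaks."""
    w, h = spec.frame_size
    s = spec.scale
    half_diag = 0.5 * s * float(np.hypot(w, h))
    margin = half_diag * 1.05
    W, H = scene.width, scene.height
    ex = np.array([1.0, 0.0])
    ey = np.array([0.0, 1.0])
    step = _solve_step(spec.frame_size, s, spec.overlap_target, ex)
    n = spec.n_frames
    pts: list[tuple[np.ndarray, float]] = []

    if spec.kind == "out_and_back":
        n_out = (n + 1) // 2
        lat = min(step, 0.8 * _solve_step(spec.frame_size, s,
                                          spec.overlap_target, ey))
        x0, y0 = margin, H / 2.0
        span = (n_out - 1) * step
        if x0 + span > W - margin:
            raise ConfigurationError(
                f"out-and-back span {span:.0f}px exceeds texture width "
                f"{W} with margin {margin:.0f}; enlarge texture or overlap")
        for i in range(n_out):
            pts.append((np.array([x0 + i * step, y0]), 0.0))
        # purely lateral turn, then the return pass
        for i in range(n - n_out):
            pts.append((np.array([x0 + span - i * step, y0 + lat]), 0.0))
    elif spec.kind == "serpentine":
        n_pass = (n - 1) // 2
        n_pass = max(n_pass, 1)
        dy = 0.9 * _solve_step(spec.frame_size, s, spec.overlap_target, ey)
        x0, y0 = margin, H / 2.0 - dy
        span = (n_pass - 1) * step
        if x0 + span > W - margin or y0 + 2 * dy > H - margin or y0 < margin:
            raise ConfigurationError("serpentine does not fit the texture")
        for i in range(n_pass):
            pts.append((np.array([x0 + i * step, y0]), 0.0))
        # right-angled connector, one dy at a time, then the return pass
        pts.append((np.array([x0 + span, y0 + dy]), 0.0))
        for i in range(n - n_pass - 1):
            pts.append((np.array([x0 + span - i * step, y0 + 2 * dy]), 0.0))
    elif spec.kind == "orbit":
        radius = min(W, H) / 2.0 - margin
        if radius <= half_diag:
            raise ConfigurationError("texture too small for an orbit")
        pts = _orbit_points(np.array([W / 2.0, H / 2.0]), radius,
                            theta0_deg=0.0, heading0_deg=90.0, n=n,
                            spec=spec, step=step)
    elif spec.kind == "composite":
        # serpentine connected by an orbit joined at the serpentine's end
        n_serp = max(3, (2 * n) // 3)
        n_serp = min(n_serp, n - 1)
        serp = TrajectorySpec(kind="serpentine", n_frames=n_serp,
                              frame_size=spec.frame_size,
                              overlap_target=spec.overlap_target,
                              scale=spec.scale)
        pts = _waypoints(serp, scene, rng)
        end, end_heading = pts[-1]
        # place the orbit circle on whichever side of the end point has room
        best = None
        for u in (np.array([1.0, 0]), np.array([-1.0, 0]),
                  np.array([0, 1.0]), np.array([0, -1.0])):
            lo = np.array([margin, margin])
            hi = np.array([W - margin, H - margin])
            r_axis = np.where(u != 0,
                              (np.where(u > 0, hi - end, end - lo)) / 2.0,
                              np.minimum(end - lo, hi - end))
            r = float(np.min(r_axis))
            if best is None or r > best[1]:
                best = (u, r)
        u, radius = best
        if radius <= half_diag:
            raise ConfigurationError("no room for the orbit section")
        center = end + radius * u
        theta0 = float(np.rad2deg(np.arctan2(-u[1], -u[0])))
        pts = pts + _orbit_points(center, radius, theta0_deg=theta0,
                                  heading0_deg=end_heading, n=n - n_serp,
                                  spec=spec, step=step, skip_first=True)
        pts = pts[:n]
    return pts


def _orbit_points(center: np.ndarray, radius: float, theta0_deg: float,
                  heading0_deg: float, n: int, spec: TrajectorySpec,
                  step: float, skip_first: bool = False
                  ) -> list[tuple[np.ndarray, float]]:
    """Waypoints on a circle; the camera heading turns with the position
    angle starting from ``heading0_deg``. The angular step is solved so
    consecutive footprints keep the overlap target."""
    s = spec.scale
    dtheta = step / radius          # chord ~ arc for small steps
    th0 = np.deg2rad(theta0_deg)

    def at(th):
        c = center + radius * np.array([np.cos(th), np.sin(th)])
        return c, heading0_deg + np.rad2deg(th - th0)

    while dtheta > 1e-4:
        (c0, a0), (c1, a1) = at(th0), at(th0 + dtheta)
        if polygon_iou(_footprint(tuple(c0), a0, s, spec.frame_size),
                       _footprint(tuple(c1), a1, s, spec.frame_size)
                       ) >= spec.overlap_target:
            break
        dtheta *= 0.9
    start = 1 if skip_first else 0
    return [at(th0 + i * dtheta) for i in range(start, start + n)]


def make_trajectory(scene: SyntheticScene, spec: TrajectorySpec,
                    seed: int = 0) -> GroundTruth:
    """Simulate a camera path and return exact per-frame homographies.

    Consecutive footprints overlap by at least ``spec.overlap_target``
    (validated against a polygon-clipping oracle at build time), except at
    ``shot_breaks`` where a large instantaneous translation plus rotation
    forces the overlap below 0.1 — emulating abrupt changes in vehicle
    position or camera view. Raises :class:`ConfigurationError` when the
    path cannot fit inside the texture.
    """
    rng = np.random.default_rng(seed)
    pts = _waypoints(spec, scene, rng)
    w, h = spec.frame_size
    s = spec.scale
    half_diag = 0.5 * s * float(np.hypot(w, h))
    W, H = scene.width, scene.height

    # shot-break state: downstream waypoints are rotated by the accumulated
    # jump rotation about the break point, so within-shot step geometry (and
    # hence the overlap contract) is preserved exactly after each jump.
    phi = 0.0                       # accumulated jump rotation (deg)
    c_ref = np.zeros(2)             # ideal center at the last break
    c_actual_ref = np.zeros(2)      # its actual (jumped) position
    homs, feet = [], []
    breaks = set(spec.shot_breaks)

    def rot(v: np.ndarray, deg: float) -> np.ndarray:
        a = np.deg2rad(deg)
        return np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]]) @ v

    for i, (c, ang) in enumerate(pts, start=1):
        would_be = rot(c - c_ref, phi) + c_actual_ref
        if i - 1 in breaks:
            # jump far enough that footprint IoU with the previous frame < 0.1
            prev_fp = feet[-1]
            room_up = would_be[1] - half_diag
            room_down = H - would_be[1] - half_diag
            direction = np.array([0.0, 1.0]) if room_down > room_up \
                else np.array([0.0, -1.0])
            jump = 1.8 * s * h       # well clear of the overlap region
            for _ in range(30):
                cand = would_be + jump * direction
                fp = _footprint(tuple(cand), ang + phi + 20.0, s,
                                spec.frame_size)
                if polygon_iou(prev_fp, fp) < 0.08:
                    break
                jump *= 1.15
            c_ref = c.copy()
            c_actual_ref = would_be + jump * direction
            phi += 20.0
            would_be = c_actual_ref
        center = would_be
        angle = ang + phi
        if spec.jitter > 0:
            center = center + rng.normal(scale=spec.jitter, size=2)
            angle = angle + rng.normal(scale=0.02 * spec.jitter)
        H_i = _placement(tuple(center), angle, s, spec.frame_size)
        fp = footprint_polygon(H_i, w, h)
        if (fp[:, 0].min() < 0 or fp[:, 1].min() < 0
                or fp[:, 0].max() > W - 1 or fp[:, 1].max() > H - 1):
            raise ConfigurationError(
                f"frame {i} footprint leaves the texture; enlarge the "
                f"texture or shrink the trajectory")
        homs.append(H_i)
        feet.append(fp)
        prev_center = center
    return GroundTruth(homographies=np.array(homs), footprints=np.array(feet),
                       frame_size=spec.frame_size,
                       shot_breaks=list(spec.shot_breaks))


def render_frames(scene: SyntheticScene, gt: GroundTruth,
                  noise_sigma: float = 0.0, illum_drift: float = 0.0,
                  seed: int = 0) -> list[Frame]:
    """Render each frame by inverse-warping the texture (bilinear).

    Identity or integer-translation homographies reproduce texture crops
    exactly. Optional additive Gaussian noise (``noise_sigma``, 0-255 units)
    and a linear multiplicative illumination ramp reaching ``1 +
    illum_drift`` at the last frame are applied after warping and recorded
    in frame metadata.
    """
    rng = np.random.default_rng(seed)
    w, h = gt.frame_size
    tex = scene.texture.astype(float)
    frames = []
    n = gt.n_frames
    for i in range(n):
        fp = gt.footprints[i]
        if (fp[:, 0].min() < 0 or fp[:, 1].min() < 0
                or fp[:, 0].max() > scene.width - 1
                or fp[:, 1].max() > scene.height - 1):
            raise ValueError(f"frame {i + 1} footprint outside texture bounds")
        tf = ProjectiveTransform(matrix=gt.homographies[i])
        img = warp(tex, inverse_map=tf, output_shape=(h, w), order=1,
                   mode="constant", cval=0.0, preserve_range=True)
        gain = 1.0 + illum_drift * (i / (n - 1) if n > 1 else 0.0)
        img = img * gain
        if noise_sigma > 0:
            img = img + rng.normal(scale=noise_sigma, size=img.shape)
        meta = {"gain": gain, "noise_sigma": noise_sigma}
        frames.append(Frame(index=i + 1,
                            image=np.clip(np.rint(img), 0, 255).astype(np.uint8),
                            timestamp=i / 24.0, metadata=meta))
    return frames


def true_orthomosaic(scene: SyntheticScene, gt: GroundTruth
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Crop of the texture covering all footprints, plus the scene->crop
    translation (as a 3x3 homography)."""
    fp = gt.footprints.reshape(-1, 2)
    x0 = int(np.floor(fp[:, 0].min()))
    y0 = int(np.floor(fp[:, 1].min()))
    x1 = int(np.ceil(fp[:, 0].max()))
    y1 = int(np.ceil(fp[:, 1].max()))
    crop = scene.texture[y0:y1 + 1, x0:x1 + 1]
    T = np.array([[1.0, 0.0, -x0], [0.0, 1.0, -y0], [0.0, 0.0, 1.0]])
    return crop, T


def save_dataset(out_dir: str | Path, scene: SyntheticScene, gt: GroundTruth,
                 frames: list[Frame]) -> Path:
    """Write numbered frame PNGs, a ground-truth JSON and the true
    orthomosaic PNG; returns the dataset directory."""
    out = Path(out_dir)
    fdir = out / "frames"
    fdir.mkdir(parents=True, exist_ok=True)
    for fr in frames:
        iio.imwrite(fdir / f"frame_{fr.index:05d}.png", fr.image)
    ortho, T = true_orthomosaic(scene, gt)
    iio.imwrite(out / "true_orthomosaic.png", ortho)
    manifest = {
        "frame_size": list(gt.frame_size),
        "n_frames": gt.n_frames,
        "shot_breaks": gt.shot_breaks,
        "scene_to_ortho": T.ravel().tolist(),
        "homographies": [Hm.ravel().tolist() for Hm in gt.homographies],
        "footprints": [f.tolist() for f in gt.footprints],
    }
    (out / "ground_truth.json").write_text(json.dumps(manifest, indent=1))
    return out


def load_ground_truth(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    homs = np.array([np.array(hm).reshape(3, 3) for hm in d["homographies"]])
    return GroundTruth(homographies=homs,
                       footprints=np.array(d["footprints"]),
                       frame_size=tuple(d["frame_size"]),
                       shot_breaks=list(d["shot_breaks"]))
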