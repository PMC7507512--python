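"""Frame container, lens undistortion and downsampling.

Undistortion applies a supplied Brown-Conrady calibration (radial k1..k3,
tangential p1, p2); estimating the calibration itself is out of scope — the
coefficients are consumed from a config file. Both steps run before
registration; the default order is undistort then downsample, because
distortion coefficients are defined for the native sensor geometry, but the
order is configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage.transform import resize_local_mean

logger = logging.getLogger(__name__)

__all__ = ["Frame", "CameraModel", "undistort", "distort", "downsample",
           "load_frames"]


@dataclass
class Frame:
    """One timestamped RGB video frame.

    ``image`` is an ``(H, W, 3)`` uint8 array; ``index`` is 1-based and
    strictly increasing within a sequence.
    """

    index: int
    image: np.ndarray
    timestamp: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"frame index must be >= 1, got {self.index}")
        self.image = np.asarray(self.image)
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError("frame image must be (H, W, 3) RGB")

    @property
    def height(self) -> int:
        return self.image.shape[0]

    @property
    def width(self) -> int:
        return self.image.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape[:2]


@dataclass(frozen=True)
class CameraModel:
    """Pinhole intrinsics plus Brown-Conrady distortion coefficients.

    Focal lengths and principal point are in pixels; distortion coefficients
    are dimensionless and act on normalized image coordinates.
    """

    fx: float
    fy: float
    cx: float
    cy: float
    k1: float = 0.0
    k2: float = 0.0
    k3: float = 0.0
    p1: float = 0.0
    p2: float = 0.0

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "CameraModel":
        return cls(**{k: float(v) for k, v in d.items()})

    def distort_normalized(self, xn: np.ndarray, yn: np.ndarray
                           ) -> tuple[np.ndarray, np.ndarray]:
        """Forward distortion model on normalized coordinates."""
        r2 = xn * xn + yn * yn
        radial = 1.0 + self.k1 * r2 + self.k2 * r2 ** 2 + self.k3 * r2 ** 3
        xd = xn * radial + 2 * self.p1 * xn * yn + self.p2 * (r2 + 2 * xn * xn)
        yd = yn * radial + self.p1 * (r2 + 2 * yn * yn) + 2 * self.p2 * xn * yn
        return xd, yd


def _remap(image: np.ndarray, map_x: np.ndarray, map_y: np.ndarray) -> np.ndarray:
    """Bilinear sampling of ``image`` at (map_x, map_y) pixel locations."""
    out = np.empty_like(image, dtype=float)
    coords = np.stack([map_y.ravel(), map_x.ravel()])
    for c in range(image.shape[2]):
        out[..., c] = ndimage.map_coordinates(
            image[..., c].astype(float), coords, order=1, mode="constant",
            cval=0.0).reshape(map_x.shape)
    return out


def undistort(frame: Frame, camera: CameraModel | None) -> Frame:
    """Remove lens distortion using the supplied calibration.

    For each undistorted output pixel the forward distortion model gives the
    source location in the raw frame, which is sampled bilinearly. With a
    missing camera model the frame passes through unchanged (two of the three
    flight videos motivating this pipeline were mosaicked without
    undistortion) and a warning is logged.
    """
    if camera is None:
        logger.warning("no camera model supplied; frame %d passed through "
                       "without undistortion", frame.index)
        return frame
    h, w = frame.shape
    if not (0 <= camera.cx < w and 0 <= camera.cy < h):
        raise ValueError("principal point lies outside the frame")
    x, y = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    xn = (x - camera.cx) / camera.fx
    yn = (y - camera.cy) / camera.fy
    xd, yd = camera.distort_normalized(xn, yn)
    map_x = xd * camera.fx + camera.cx
    map_y = yd * camera.fy + camera.cy
    out = _remap(frame.image, map_x, map_y)
    return Frame(index=frame.index,
                 image=np.clip(np.rint(out), 0, 255).astype(np.uint8),
                 timestamp=frame.timestamp,
                 metadata={**frame.metadata, "undistorted": True})


def distort(frame: Frame, camera: CameraModel) -> Frame:
    """Apply lens distortion synthetically (the inverse use of the model).

    Each distorted output pixel is filled from the undistorted location,
    found by Newton iteration on the forward model. Used to fabricate
    distorted inputs with known coefficients.
    """
    h, w = frame.shape
    x, y = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    xd = (x - camera.cx) / camera.fx
    yd = (y - camera.cy) / camera.fy
    # invert the forward model: find (xn, yn) with distort(xn, yn) = (xd, yd)
    xn, yn = xd.copy(), yd.copy()
    for _ in range(10):
        fx_, fy_ = camera.distort_normalized(xn, yn)
        xn += xd - fx_
        yn += yd - fy_
    map_x = xn * camera.fx + camera.cx
    map_y = yn * camera.fy + camera.cy
    out = _remap(frame.image, map_x, map_y)
    return Frame(index=frame.index,
                 image=np.clip(np.rint(out), 0, 255).astype(np.uint8),
                 timestamp=frame.timestamp,
                 metadata={**frame.metadata, "distorted": True})


def downsample(frame: Frame, target_width: int | None = None,
               target_height: int | None = None) -> Frame:
    """Area-based downsampling to the target size.

    When only one target dimension is given the aspect ratio is preserved.
    Upsampling requests are rejected. Local-mean (area) resampling is used so
    smooth images keep their mean intensity.
    """
    h, w = frame.shape
    if target_width is None and target_height is None:
        raise ValueError("at least one target dimension is required")
    if target_width is None:
        target_width = int(round(w * target_height / h))
    if target_height is None:
        target_height = int(round(h * target_width / w))
    if target_width > w or target_height > h:
        raise ValueError(
            f"upsampling requested: target {target_width}x{target_height} "
            f"exceeds source {w}x{h}")
    if (target_width, target_height) == (w, h):
        return frame
    out = resize_local_mean(frame.image.astype(float),
                            (target_height, target_width, 3))
    return Frame(index=frame.index,
                 image=np.clip(np.rint(out), 0, 255).astype(np.uint8),
                 timestamp=frame.timestamp,
                 metadata={**frame.metadata,
                           "downsampled_from": (w, h)})


def load_frames(path: str | Path, stride: int = 1) -> list[Frame]:
    """Read an ordered frame sequence from a directory or video file.

    A directory is read as lexicographically ordered PNG/JPEG files; any
    other path is decoded as a video container via imageio. ``stride``
    subsamples the sequence (every ``stride``-th frame), mirroring the
    frame-sampling used for slow trajectories.
    """
    path = Path(path)
    images: list[np.ndarray] = []
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in {".png", ".jpg", ".jpeg", ".tif"})
        if not files:
            raise FileNotFoundError(f"no image files found in {path}")
        images = [iio.imread(f) for f in files[::stride]]
    else:
        if not path.exists():
            raise FileNotFoundError(path)
        images = list(iio.imiter(path))[::stride]
    frames = []
    for i, img in enumerate(images, start=1):
        if img.ndim == 2:
            img = np.stack([img] * 3, axis=-1)
        frames.append(Frame(index=i, image=img[..., :3].astype(np.uint8)))
    return frames
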