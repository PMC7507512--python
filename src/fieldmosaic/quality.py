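"""Mosaic quality metrics: SSIM, SSIM_f, SSIM_p and scene integrity.

``SSIM_f`` measures how structurally similar the warped frame at time t is
to the overlapping region of the initial mosaic (the state after frame 1);
``SSIM_p`` measures similarity to the mosaic accumulated from frames 1..t-1,
immediately before frame t is blended. Scene integrity is the fraction of
frames whose content is recognizably and correctly placed in the final
mosaic. All SSIM values lie in [-1, 1]; scene integrity lies in [0, 1].

The SSIM variant is the standard Gaussian-weighted formulation of Wang et
al. (sigma 1.5, 11x11 effective window, K1=0.01, K2=0.03, population
covariance), computed on grayscale; color inputs are converted internally.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.color import rgb2gray

from .geometry import invert, normalize_homography, translation
from .mosaic import HomographyChain, MosaicCanvas, warp_image
from .preprocess import Frame

__all__ = ["QualityReport", "ssim", "ssim_masked", "ssim_f", "ssim_p",
           "scene_integrity", "evaluate_mosaic"]

_SIGMA = 1.5
_TRUNCATE = 3.5
_K1, _K2 = 0.01, 0.03
_PAD = int(_TRUNCATE * _SIGMA + 0.5)      # 5 -> 11-tap window


def _as_gray(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim == 3:
        img = rgb2gray(img)
        return img * 255.0 if img.max() <= 1.0 else img
    return img.astype(float)


def _filt(x: np.ndarray) -> np.ndarray:
    return ndimage.gaussian_filter(x, sigma=_SIGMA, truncate=_TRUNCATE,
                                   mode="reflect")


def _ssim_map(a: np.ndarray, b: np.ndarray, data_range: float = 255.0
              ) -> np.ndarray:
    ux, uy = _filt(a), _filt(b)
    vx = _filt(a * a) - ux * ux
    vy = _filt(b * b) - uy * uy
    vxy = _filt(a * b) - ux * uy
    C1 = (_K1 * data_range) ** 2
    C2 = (_K2 * data_range) ** 2
    return ((2 * ux * uy + C1) * (2 * vxy + C2)) \
        / ((ux * ux + uy * uy + C1) * (vx + vy + C2))


def ssim(image_a: np.ndarray, image_b: np.ndarray,
         data_range: float = 255.0) -> float:
    """Mean structural similarity between two images, in [-1, 1].

    Symmetric in its arguments; 1.0 for identical images; negative when the
    local structure is anti-correlated (e.g. an image vs its negative).
    """
    a, b = _as_gray(image_a), _as_gray(image_b)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    if min(a.shape) < 2 * _PAD + 1:
        raise ValueError("images smaller than the SSIM window")
    S = _ssim_map(a, b, data_range)
    return float(S[_PAD:-_PAD, _PAD:-_PAD].mean())


def ssim_masked(image_a: np.ndarray, image_b: np.ndarray,
                mask: np.ndarray, data_range: float = 255.0) -> float | None:
    """Mean SSIM over a pixel mask; ``None`` when the mask is empty.

    The mask is eroded by the window radius so that no window mixes valid
    and invalid pixels; if erosion empties it, the raw mask is used.
    """
    a, b = _as_gray(image_a), _as_gray(image_b)
    if a.shape != b.shape or a.shape != mask.shape:
        raise ValueError("images and mask must share a shape")
    if not mask.any():
        return None
    S = _ssim_map(a, b, data_range)
    eroded = ndimage.binary_erosion(mask, iterations=_PAD)
    region = eroded if eroded.any() else mask
    return float(S[region].mean())


def _warp_full(frame: Frame, h_cb: np.ndarray, offset: tuple[int, int],
               shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Warp a frame (and its validity mask) into full canvas coordinates."""
    H_total = normalize_homography(translation(*offset) @ h_cb)
    return warp_image(frame.image, invert(H_total), shape)


def ssim_f(warped_frame: np.ndarray, frame_mask: np.ndarray,
           mosaic_t1: MosaicCanvas) -> float | None:
    """SSIM of a warped frame against the initial (t = 1) mosaic state,
    over the region where both are filled. ``None`` if they do not overlap."""
    overlap = frame_mask & mosaic_t1.filled_mask
    return ssim_masked(warped_frame, mosaic_t1.image, overlap)


def ssim_p(warped_frame: np.ndarray, frame_mask: np.ndarray,
           mosaic_prev: MosaicCanvas) -> float | None:
    """SSIM of a warped frame against the mosaic of frames 1..t-1, over
    the region where both are filled. ``None`` if they do not overlap."""
    overlap = frame_mask & mosaic_prev.filled_mask
    return ssim_masked(warped_frame, mosaic_prev.image, overlap)


def scene_integrity(mosaic: MosaicCanvas, frames: list[Frame],
                    chain: HomographyChain,
                    match_threshold: float = 0.8) -> float:
    """Fraction of frames whose warped content matches the final mosaic.

    A frame matches when the SSIM between its warped image and the mosaic
    reaches ``match_threshold`` over the *independent* part of its
    footprint — mosaic pixels supplied by other frames (a frame trivially
    agrees with its own contribution, so those pixels carry no evidence).
    A frame whose footprint holds no independently-filled pixels (e.g. a
    single-frame video) is counted as matched: nothing contradicts it.
    0 is complete failure, 1 complete success.
    """
    if not frames:
        raise ValueError("no frames")
    shape = mosaic.image.shape[:2]
    matched = 0
    for frame in frames:
        img, mask = _warp_full(frame, chain.h_cb[frame.index],
                               mosaic.offset, shape)
        evidence = (mask & mosaic.filled_mask
                    & (mosaic.provenance != frame.index))
        value = ssim_masked(img, mosaic.image, evidence)
        if value is None or value >= match_threshold:
            matched += 1
    return matched / len(frames)


@dataclass
class QualityReport:
    """Per-frame quality traces plus aggregates.

    ``ssim_f``/``ssim_p`` map frame index -> value; frames without overlap
    are recorded as ``None`` and excluded from the means.
    """

    ssim_f: dict[int, float | None] = field(default_factory=dict)
    ssim_p: dict[int, float | None] = field(default_factory=dict)
    scene_integrity: float | None = None
    match_threshold: float = 0.8

    @property
    def mean_ssim_f(self) -> float | None:
        vals = [v for v in self.ssim_f.values() if v is not None]
        return float(np.mean(vals)) if vals else None

    @property
    def mean_ssim_p(self) -> float | None:
        vals = [v for v in self.ssim_p.values() if v is not None]
        return float(np.mean(vals)) if vals else None

    @property
    def frames_evaluated(self) -> int:
        return sum(v is not None for v in self.ssim_p.values())

    def to_dict(self) -> dict:
        return {"mean_ssim_f": self.mean_ssim_f,
                "mean_ssim_p": self.mean_ssim_p,
                "scene_integrity": self.scene_integrity,
                "match_threshold": self.match_threshold,
                "frames_evaluated": self.frames_evaluated,
                "ssim_f": {str(k): v for k, v in self.ssim_f.items()},
                "ssim_p": {str(k): v for k, v in self.ssim_p.items()}}

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["frame", "ssim_f", "ssim_p"])
            for idx in sorted(self.ssim_p):
                f = self.ssim_f.get(idx)
                p = self.ssim_p.get(idx)
                writer.writerow([idx,
                                 "" if f is None else f"{f:.6f}",
                                 "" if p is None else f"{p:.6f}"])


def evaluate_mosaic(frames: list[Frame], chain: HomographyChain,
                    canvas_template: MosaicCanvas,
                    match_threshold: float = 0.8,
                    final_mosaic: MosaicCanvas | None = None
                    ) -> QualityReport:
    """Replay blending frame by frame and record SSIM_f / SSIM_p traces.

    ``canvas_template`` supplies the canvas geometry (it is not modified);
    blending is replayed internally so each frame t is compared against the
    true incremental mosaic state before it is added. Scene integrity is
    computed against ``final_mosaic`` (or the replayed final state).
    """
    from .mosaic import CanvasSpec, warp_and_blend  # avoid import cycle

    shape = canvas_template.image.shape[:2]
    spec = CanvasSpec(width=shape[1], height=shape[0],
                      offset=canvas_template.offset)
    state = MosaicCanvas.empty(spec)
    report = QualityReport(match_threshold=match_threshold)

    mosaic_t1: MosaicCanvas | None = None
    for t, frame in enumerate(frames, start=1):
        h_cb = chain.h_cb[frame.index]
        if t > 1:
            img, mask = _warp_full(frame, h_cb, state.offset, shape)
            report.ssim_f[frame.index] = ssim_f(img, mask, mosaic_t1)
            report.ssim_p[frame.index] = ssim_p(img, mask, state)
        warp_and_blend(state, frame, h_cb)
        if t == 1:
            mosaic_t1 = MosaicCanvas(image=state.image.copy(),
                                     provenance=state.provenance.copy(),
                                     offset=state.offset)
            report.ssim_f[frame.index] = 1.0
            report.ssim_p[frame.index] = 1.0
    final = final_mosaic if final_mosaic is not None else state
    report.scene_integrity = scene_integrity(final, frames, chain,
                                             match_threshold)
    return report
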