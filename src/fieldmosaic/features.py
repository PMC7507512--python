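"""Feature detection and matching behind a pluggable descriptor interface.

Three descriptor families form the escalation ladder used by adaptive
registration, ordered from fastest to most robust:

``st``
    Structure-tensor block features: the smaller eigenvalue of the gradient
    outer-product tensor summed over micro-blocks of pixels, with a
    mean/variance-normalized intensity patch as descriptor. Fast, semi-local,
    not rotation invariant — suited to large-overlap, translation-dominant
    frame pairs.
``fast_local``
    ORB (FAST keypoints + rotated BRIEF binary descriptors): a fast local
    descriptor robust to rotation and illumination.
``affine_robust``
    SIFT keypoints and descriptors: scale/rotation invariant and partially
    affine invariant, the most robust (and slowest) rung.

All detectors return the ``max_keep`` strongest keypoints by detector
response, with a deterministic (y, x) tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2gray
from skimage.feature import ORB, SIFT, corner_shi_tomasi, match_descriptors
from skimage.util import img_as_float

from .preprocess import Frame

__all__ = ["DESCRIPTOR_KINDS", "FeatureSet", "MatchSet", "LowTextureError",
           "detect_features", "match_features"]

DESCRIPTOR_KINDS = ("st", "fast_local", "affine_robust")


class LowTextureError(RuntimeError):
    """Fewer than 4 features found; the caller should escalate descriptors."""


@dataclass
class FeatureSet:
    frame_index: int
    keypoints: np.ndarray         # (N, 2) of (x, y)
    strengths: np.ndarray         # (N,) detector responses, descending
    descriptors: np.ndarray       # (N, D); float or bool rows
    kind: str

    def __len__(self) -> int:
        return len(self.keypoints)


@dataclass
class MatchSet:
    """Putative correspondences between two frames, plus the RANSAC verdict.

    ``inlier_mask`` is ``None`` until :func:`fieldmosaic.ransac.ransac_filter`
    has run.
    """

    source_frame: int
    target_frame: int
    src: np.ndarray               # (M, 2) points in the source frame
    dst: np.ndarray               # (M, 2) points in the target frame
    scores: np.ndarray            # (M,) descriptor distances
    kind: str
    inlier_mask: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.src)

    @property
    def n_inliers(self) -> int:
        return 0 if self.inlier_mask is None else int(self.inlier_mask.sum())

    @property
    def inlier_ratio(self) -> float:
        if len(self) == 0:
            return 0.0
        return self.n_inliers / len(self)


def _to_gray(frame: Frame | np.ndarray) -> np.ndarray:
    img = frame.image if isinstance(frame, Frame) else np.asarray(frame)
    if img.ndim == 3:
        return rgb2gray(img_as_float(img))
    return img_as_float(img)


def _order_strongest(keypoints: np.ndarray, strengths: np.ndarray,
                     max_keep: int) -> np.ndarray:
    """Indices of the ``max_keep`` strongest features; ties break on (y, x)."""
    order = np.lexsort((keypoints[:, 0], keypoints[:, 1], -strengths))
    return order[:max_keep]


def _st_features(gray: np.ndarray, block_size: int
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Structure-tensor block detector + normalized-patch descriptors.

    The per-pixel Shi-Tomasi response (smaller eigenvalue of the local
    gradient tensor) is maximized within each micro-block; the keypoint is
    the response peak, so it anchors to image content rather than to the
    block grid.
    """
    h, w = gray.shape
    response = corner_shi_tomasi(gray, sigma=2.0)
    # derivative filters produce spurious responses at the image border
    m = 10
    response[:m] = response[-m:] = 0.0
    response[:, :m] = response[:, -m:] = 0.0
    bh, bw = h // block_size, w // block_size
    if bh == 0 or bw == 0:
        return np.empty((0, 2)), np.empty(0), np.empty((0, 0))

    blocks = response[:bh * block_size, :bw * block_size] \
        .reshape(bh, block_size, bw, block_size).swapaxes(1, 2) \
        .reshape(bh, bw, -1)
    flat_peak = blocks.argmax(axis=2)
    strengths_grid = blocks.max(axis=2)
    py, px = np.unravel_index(flat_peak, (block_size, block_size))
    by, bx = np.meshgrid(np.arange(bh), np.arange(bw), indexing="ij")
    ys = (by * block_size + py).ravel()
    xs = (bx * block_size + px).ravel()
    strengths = strengths_grid.ravel()

    keep = strengths > max(1e-12, 1e-3 * float(strengths.max(initial=0.0)))
    xs, ys, strengths = xs[keep], ys[keep], strengths[keep]

    # sub-pixel peak: 1D quadratic interpolation of the response in x and y
    def refine(coord, other, axis_len, get):
        inner = (coord > 0) & (coord < axis_len - 1)
        r0 = get(coord, other)
        rm = get(np.where(inner, coord - 1, coord), other)
        rp = get(np.where(inner, coord + 1, coord), other)
        denom = rm - 2 * r0 + rp
        shift = np.where((np.abs(denom) > 1e-12) & inner,
                         0.5 * (rm - rp) / np.where(denom == 0, 1, denom), 0.0)
        return coord + np.clip(shift, -0.5, 0.5)

    fx = refine(xs, ys, w, lambda c, o: response[o, c])
    fy = refine(ys, xs, h, lambda c, o: response[c, o])
    keypoints = np.column_stack([fx, fy]).astype(float)
    xs_i, ys_i = xs, ys   # integer anchors for patch extraction

    half = 8            # 17x17 patch descriptor around each response peak
    padded = np.pad(gray, half + 1, mode="reflect")
    descs = np.empty((len(keypoints), (2 * half + 1) ** 2))
    for i, (x, y) in enumerate(zip(xs_i, ys_i)):
        r, c = int(y) + half + 1, int(x) + half + 1
        patch = padded[r - half:r + half + 1, c - half:c + half + 1]
        v = patch.ravel() - patch.mean()
        norm = np.linalg.norm(v)
        descs[i] = v / norm if norm > 1e-12 else v
    return keypoints, strengths, descs


def detect_features(frame: Frame | np.ndarray, kind: str = "st",
                    max_keep: int = 5000, block_size: int = 8) -> FeatureSet:
    """Detect keypoints and return the ``max_keep`` strongest.

    Raises :class:`LowTextureError` when fewer than 4 features are found
    (e.g. a constant-color frame), signalling the caller to escalate to a
    more robust descriptor.
    """
    if kind not in DESCRIPTOR_KINDS:
        raise ValueError(f"unknown descriptor kind {kind!r}")
    if max_keep < 4:
        raise ValueError("max_keep must be >= 4")
    gray = _to_gray(frame)
    index = frame.index if isinstance(frame, Frame) else 0

    if kind == "st":
        keypoints, strengths, descriptors = _st_features(gray, block_size)
    elif kind == "fast_local":
        orb = ORB(n_keypoints=max_keep)
        try:
            orb.detect_and_extract(gray)
        except (RuntimeError, ValueError) as exc:
            raise LowTextureError(f"ORB failed on frame {index}: {exc}") from exc
        keypoints = orb.keypoints[:, ::-1].astype(float)    # (row,col)->(x,y)
        strengths = orb.responses
        descriptors = orb.descriptors
    else:  # affine_robust
        sift = SIFT()
        try:
            sift.detect_and_extract(gray)
        except (RuntimeError, ValueError) as exc:
            raise LowTextureError(f"SIFT failed on frame {index}: {exc}") from exc
        keypoints = sift.keypoints[:, ::-1].astype(float)
        # SIFT exposes no response; rank by the corner measure at the keypoint
        corner_map = corner_shi_tomasi(gray)
        rr = np.clip(sift.keypoints[:, 0], 0, gray.shape[0] - 1).astype(int)
        cc = np.clip(sift.keypoints[:, 1], 0, gray.shape[1] - 1).astype(int)
        strengths = corner_map[rr, cc]
        descriptors = sift.descriptors.astype(float)

    if len(keypoints) < 4:
        raise LowTextureError(
            f"only {len(keypoints)} {kind} features on frame {index}")
    sel = _order_strongest(np.asarray(keypoints), np.asarray(strengths),
                           max_keep)
    return FeatureSet(frame_index=index,
                      keypoints=np.asarray(keypoints)[sel],
                      strengths=np.asarray(strengths)[sel],
                      descriptors=np.asarray(descriptors)[sel],
                      kind=kind)


def match_features(set_a: FeatureSet, set_b: FeatureSet,
                   max_ratio: float = 0.75) -> MatchSet:
    """Nearest-neighbour matching with Lowe-style ratio test and cross-check.

    Matches are one-to-one. An empty :class:`MatchSet` (no exception) is
    returned when nothing matches, so the caller can escalate.
    """
    if set_a.kind != set_b.kind:
        raise ValueError(
            f"descriptor kinds differ: {set_a.kind} vs {set_b.kind}")
    idx = match_descriptors(set_a.descriptors, set_b.descriptors,
                            cross_check=True, max_ratio=max_ratio)
    src = set_a.keypoints[idx[:, 0]] if len(idx) else np.empty((0, 2))
    dst = set_b.keypoints[idx[:, 1]] if len(idx) else np.empty((0, 2))
    if set_a.descriptors.dtype == bool:
        dists = np.array([np.count_nonzero(set_a.descriptors[i]
                                           != set_b.descriptors[j])
                          for i, j in idx], dtype=float)
    else:
        dists = np.linalg.norm(set_a.descriptors[idx[:, 0]]
                               - set_b.descriptors[idx[:, 1]], axis=1) \
            if len(idx) else np.empty(0)
    return MatchSet(source_frame=set_a.frame_index,
                    target_frame=set_b.frame_index,
                    src=src, dst=dst, scores=dists, kind=set_a.kind)
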