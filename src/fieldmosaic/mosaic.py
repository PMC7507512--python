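"""Mini-mosaic construction: grouping, homography chaining, canvas
estimation, warping and pixel-fill blending; plus meta-mosaicking.

Frames within a shot are divided into groups; every member registers
directly to its group's *reference* frame (H_CR), each reference registers
directly to the previous reference (H_RR), and chaining

    H_RB(g) = H_RB(g-1) . H_RR(g),      H_RB(1) = I
    H_CB(i) = H_RB(group of i) . H_CR(i)

ties every frame to the shot's *base* frame (the first frame), in whose
coordinates the mini-mosaic is built. Grouping caps the number of
compositions any frame's transform passes through, which bounds drift
accumulation compared with a naive frame-to-frame chain.

Blending is by pixel filling: a canvas pixel is written by the first frame
that covers it and never overwritten, so every mosaic pixel has exactly one
source frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .geometry import (DegenerateTransformError, apply_homography,
                       footprint_polygon, invert, normalize_homography,
                       translation)
from .preprocess import Frame
from .ransac import RegistrationFailureError
from .register import FeatureCache, RegistrationPolicy, adaptive_register

__all__ = ["FrameGroup", "HomographyChain", "CanvasSpec", "MosaicCanvas",
           "MiniMosaic", "ChainBreakError", "CanvasOverflowError",
           "UnmergeableShotsError", "assign_groups", "chain_homographies",
           "estimate_canvas", "warp_image", "warp_and_blend",
           "build_mini_mosaic", "meta_mosaic", "naive_chain"]

MAX_GROUP_SIZE = 40
DISPLACEMENT_FRACTION = 1.0 / 3.0
MAX_CANVAS_DIM = 16384


class ChainBreakError(RuntimeError):
    """A required pairwise transform is missing from the chain."""


class CanvasOverflowError(RuntimeError):
    """A warped footprint falls outside (or would explode) the canvas."""


class UnmergeableShotsError(RuntimeError):
    """Adjacent mini-mosaics share no usable overlap.

    Carries the individual mini-mosaics so they can still be emitted.
    """

    def __init__(self, msg: str, minis: list["MiniMosaic"]):
        super().__init__(msg)
        self.minis = minis


@dataclass
class FrameGroup:
    """A run of consecutive frames all registered to one reference frame."""

    index: int
    reference_frame: int
    members: list[int]                       # ordered, reference first
    h_cr: dict[int, np.ndarray]              # member -> reference transform
    h_rr: np.ndarray                         # this ref -> previous group's ref

    def __post_init__(self) -> None:
        if self.members[0] != self.reference_frame:
            raise ValueError("reference must be the first group member")


@dataclass
class HomographyChain:
    """All transforms tying a shot's frames to its base frame."""

    h_cr: dict[int, np.ndarray]              # per frame
    h_rb: dict[int, np.ndarray]              # per group index
    h_cb: dict[int, np.ndarray]              # per frame
    group_of: dict[int, int]                 # frame -> group index
    base_frame: int


@dataclass(frozen=True)
class CanvasSpec:
    width: int
    height: int
    offset: tuple[int, int]                  # shift into non-negative indices


@dataclass
class MosaicCanvas:
    """Growing mosaic image with per-pixel provenance.

    ``provenance[y, x]`` is the 1-based index of the frame that supplied the
    pixel, or 0 while unfilled. ``offset`` translates base-frame coordinates
    into canvas indices.
    """

    image: np.ndarray                        # (H, W, 3) uint8
    provenance: np.ndarray                   # (H, W) int32
    offset: tuple[int, int]
    footprints: dict[int, np.ndarray] = dc_field(default_factory=dict)

    @classmethod
    def empty(cls, spec: CanvasSpec) -> "MosaicCanvas":
        return cls(image=np.zeros((spec.height, spec.width, 3), np.uint8),
                   provenance=np.zeros((spec.height, spec.width), np.int32),
                   offset=spec.offset)

    @property
    def filled_mask(self) -> np.ndarray:
        return self.provenance > 0

    @property
    def n_filled(self) -> int:
        return int(np.count_nonzero(self.provenance))


@dataclass
class MiniMosaic:
    """One shot's mosaic plus everything used to build it."""

    shot_index: int
    canvas: MosaicCanvas
    chain: HomographyChain
    groups: list[FrameGroup]
    registration_log: list[dict]


def assign_groups(frames: list[Frame], register,
                  max_group_size: int = MAX_GROUP_SIZE,
                  displacement_fraction: float = DISPLACEMENT_FRACTION
                  ) -> tuple[list[FrameGroup], list[dict]]:
    """Scan frames in order and split them into reference groups.

    ``register(frame, reference)`` must return an object with a ``matrix``
    attribute (frame -> reference homography); each frame is registered to
    the currently open group's reference. A new group starts when the open
    group already holds ``max_group_size`` members (the 41st candidate under
    the default) or when the frame-center displacement under H_CR exceeds
    ``displacement_fraction`` of the frame width (|dx|) or height (|dy|);
    the splitting frame becomes the new reference, and its just-computed
    transform to the previous reference is the new group's H_RR.

    Returns the groups plus a per-pair registration log.
    """
    if not frames:
        raise ValueError("no frames to group")
    w, h = frames[0].width, frames[0].height
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    log: list[dict] = []

    first = frames[0]
    groups = [FrameGroup(index=1, reference_frame=first.index,
                         members=[first.index],
                         h_cr={first.index: np.eye(3)}, h_rr=np.eye(3))]
    ref = first
    for frame in frames[1:]:
        result = register(frame, ref)
        H = normalize_homography(result.matrix)
        log.append(_log_record(result, frame.index, ref.index))
        d = apply_homography(H, center)[0] - center
        open_group = groups[-1]
        split = (len(open_group.members) >= max_group_size
                 or abs(d[0]) > displacement_fraction * w
                 or abs(d[1]) > displacement_fraction * h)
        if split:
            groups.append(FrameGroup(index=len(groups) + 1,
                                     reference_frame=frame.index,
                                     members=[frame.index],
                                     h_cr={frame.index: np.eye(3)},
                                     h_rr=H))
            ref = frame
        else:
            open_group.members.append(frame.index)
            open_group.h_cr[frame.index] = H
    return groups, log


def _log_record(result, src: int, dst: int) -> dict:
    """Registration bookkeeping; tolerates bare matrix-only providers."""
    hom = getattr(result, "homography", None)
    return {"source_frame": src, "target_frame": dst,
            "descriptor": getattr(result, "descriptor_used", "injected"),
            "n_features_src": getattr(result, "n_features_src", ""),
            "n_features_dst": getattr(result, "n_features_dst", ""),
            "n_matches": getattr(result, "n_matches", ""),
            "n_inliers": hom.n_inliers if hom else "",
            "inlier_ratio": round(getattr(result, "inlier_ratio", 0.0), 4),
            "rms_error": round(hom.rms_error, 4) if hom else "",
            "low_confidence": getattr(result, "low_confidence", False)}


def chain_homographies(groups: list[FrameGroup]) -> HomographyChain:
    """Compose group transforms into per-frame current-to-base transforms.

    Every output is normalized so element (2, 2) equals 1. Raises
    :class:`ChainBreakError` when a group's H_RR is missing or singular.
    """
    if not groups:
        raise ValueError("no groups to chain")
    h_cr: dict[int, np.ndarray] = {}
    h_rb: dict[int, np.ndarray] = {}
    h_cb: dict[int, np.ndarray] = {}
    group_of: dict[int, int] = {}

    running_rb = np.eye(3)
    for g in groups:
        if g.index > 1:
            if g.h_rr is None:
                raise ChainBreakError(
                    f"missing reference-to-reference transform for group "
                    f"{g.index} (reference frame {g.reference_frame})")
            try:
                running_rb = normalize_homography(running_rb @ g.h_rr)
            except DegenerateTransformError as exc:
                raise ChainBreakError(
                    f"degenerate H_RR at group {g.index}: {exc}") from exc
        h_rb[g.index] = running_rb
        for m in g.members:
            if m not in g.h_cr:
                raise ChainBreakError(
                    f"missing H_CR for frame {m} in group {g.index}")
            h_cr[m] = normalize_homography(g.h_cr[m])
            h_cb[m] = normalize_homography(running_rb @ g.h_cr[m])
            group_of[m] = g.index
    return HomographyChain(h_cr=h_cr, h_rb=h_rb, h_cb=h_cb,
                           group_of=group_of,
                           base_frame=groups[0].reference_frame)


def estimate_canvas(chain: HomographyChain,
                    frame_size: tuple[int, int]) -> CanvasSpec:
    """Bounding box of all frame corners warped by their H_CB.

    The canvas is the axis-aligned box containing every warped corner; the
    offset shifts base-frame coordinates into non-negative canvas indices.
    """
    w, h = frame_size
    pts = []
    for idx, H in chain.h_cb.items():
        corners = footprint_polygon(H, w, h)
        if not np.all(np.isfinite(corners)):
            raise DegenerateTransformError(
                f"frame {idx} has a degenerate current-to-base transform")
        pts.append(corners)
    allpts = np.vstack(pts)
    x0, y0 = np.floor(allpts.min(axis=0)).astype(int)
    x1, y1 = np.ceil(allpts.max(axis=0)).astype(int)
    width, height = x1 - x0 + 1, y1 - y0 + 1
    if width > MAX_CANVAS_DIM or height > MAX_CANVAS_DIM:
        raise CanvasOverflowError(
            f"estimated canvas {width}x{height} exceeds the "
            f"{MAX_CANVAS_DIM}px limit; the chain is likely degenerate")
    return CanvasSpec(width=int(width), height=int(height),
                      offset=(int(-x0), int(-y0)))


def warp_image(image: np.ndarray, out_to_src: np.ndarray,
               out_shape: tuple[int, int],
               source_mask: np.ndarray | None = None
               ) -> tuple[np.ndarray, np.ndarray]:
    """Inverse-warp ``image`` (bilinear) onto an output grid.

    ``out_to_src`` maps output pixel coordinates to source coordinates. A
    pixel is valid only when its sample point lies geometrically inside the
    source pixel-center extent (no edge extension — samples outside would
    otherwise be silently clamped to the border) and, if ``source_mask`` is
    given, when the sample's whole bilinear support is masked valid.
    Returns ``(warped float image, valid bool mask)``.
    """
    h, w = image.shape[:2]
    oh, ow = out_shape
    ys, xs = np.mgrid[0:oh, 0:ow]
    pts = np.stack([xs.ravel(), ys.ravel(), np.ones(oh * ow)])
    mapped = np.asarray(out_to_src, dtype=float) @ pts
    u = mapped[0] / mapped[2]
    v = mapped[1] / mapped[2]
    eps = 1e-9
    valid = ((u >= -eps) & (u <= w - 1 + eps)
             & (v >= -eps) & (v <= h - 1 + eps))
    coords = np.stack([v, u])
    if image.ndim == 3:
        warped = np.stack([ndimage.map_coordinates(
            image[..., c].astype(float), coords, order=1, mode="constant",
            cval=0.0).reshape(oh, ow) for c in range(image.shape[2])], axis=-1)
    else:
        warped = ndimage.map_coordinates(
            image.astype(float), coords, order=1, mode="constant",
            cval=0.0).reshape(oh, ow)
    valid = valid.reshape(oh, ow)
    if source_mask is not None:
        m = ndimage.map_coordinates(source_mask.astype(float), coords,
                                    order=1, mode="constant",
                                    cval=0.0).reshape(oh, ow)
        valid &= m >= 0.999
    return warped, valid


def warp_and_blend(canvas: MosaicCanvas, frame: Frame, h_cb: np.ndarray,
                   source_mask: np.ndarray | None = None) -> MosaicCanvas:
    """Warp one frame into canvas coordinates and pixel-fill it.

    Only canvas pixels that are still unfilled receive values; previously
    filled pixels are never touched, so re-blending the same frame is a
    no-op and every filled pixel keeps the provenance of the earliest frame
    that covered it. ``source_mask`` restricts the valid source region (used
    when blending mini-mosaics, whose own unfilled pixels must not
    propagate).
    """
    ox, oy = canvas.offset
    H_total = normalize_homography(translation(ox, oy) @ h_cb)
    h, w = frame.shape
    corners = footprint_polygon(H_total, w, h)
    ch, cw = canvas.image.shape[:2]
    if (corners[:, 0].min() < -0.5 or corners[:, 1].min() < -0.5
            or corners[:, 0].max() > cw - 0.5 or corners[:, 1].max() > ch - 0.5):
        raise CanvasOverflowError(
            f"frame {frame.index} footprint exceeds the canvas bounds")

    # restrict warping to the footprint's bounding box
    x0 = max(int(np.floor(corners[:, 0].min())), 0)
    y0 = max(int(np.floor(corners[:, 1].min())), 0)
    x1 = min(int(np.ceil(corners[:, 0].max())), cw - 1)
    y1 = min(int(np.ceil(corners[:, 1].max())), ch - 1)
    M = invert(normalize_homography(translation(-x0, -y0) @ H_total))
    out_shape = (y1 - y0 + 1, x1 - x0 + 1)
    warped, valid = warp_image(frame.image, M, out_shape,
                               source_mask=source_mask)

    prov_roi = canvas.provenance[y0:y1 + 1, x0:x1 + 1]
    img_roi = canvas.image[y0:y1 + 1, x0:x1 + 1]
    fresh = valid & (prov_roi == 0)
    img_roi[fresh] = np.clip(np.rint(warped[fresh]), 0, 255).astype(np.uint8)
    prov_roi[fresh] = frame.index
    canvas.footprints[frame.index] = corners
    return canvas


def build_mini_mosaic(frames: list[Frame],
                      policy: RegistrationPolicy | None = None,
                      seed: int = 0, register=None,
                      shot_index: int = 1) -> MiniMosaic:
    """Run the full mini-mosaic pipeline on one shot's frames.

    Frames are registered to their group references (and references to the
    previous reference) with adaptive escalation, grouped, chained to the
    base frame, placed on an estimated canvas and blended in frame order by
    pixel filling. A single-frame shot returns that frame as its mosaic.
    ``register(frame, reference)`` may be injected (e.g. ground-truth
    transforms in validation experiments).
    """
    if not frames:
        raise ValueError("shot contains no frames")
    policy = policy or RegistrationPolicy()
    if register is None:
        cache = FeatureCache(policy)

        def register(frame, reference, _cache=cache):
            return adaptive_register(frame, reference, policy, seed=seed,
                                     cache=_cache)

    groups, log = assign_groups(frames, register)
    chain = chain_homographies(groups)
    spec = estimate_canvas(chain, (frames[0].width, frames[0].height))
    canvas = MosaicCanvas.empty(spec)
    for frame in frames:
        warp_and_blend(canvas, frame, chain.h_cb[frame.index])
    return MiniMosaic(shot_index=shot_index, canvas=canvas, chain=chain,
                      groups=groups, registration_log=log)


def naive_chain(frames: list[Frame], register) -> dict[int, np.ndarray]:
    """Frame(i) -> frame(i-1) registrations composed all the way to frame 1.

    The drift baseline that grouping is designed to beat: every frame's
    transform to the base passes through i-1 compositions.
    """
    h_cb = {frames[0].index: np.eye(3)}
    running = np.eye(3)
    for prev, cur in zip(frames, frames[1:]):
        H = normalize_homography(register(cur, prev).matrix)
        running = normalize_homography(running @ H)
        h_cb[cur.index] = running
    return h_cb


def meta_mosaic(minis: list[MiniMosaic],
                policy: RegistrationPolicy | None = None,
                seed: int = 0) -> MosaicCanvas:
    """Merge per-shot mini-mosaics into one meta-mosaic.

    Each mini-mosaic is registered to the previous one (treated as frames,
    with adaptive descriptor escalation), chained to the first shot's base
    and blended by pixel filling. A single mini-mosaic passes through
    unchanged. Raises :class:`UnmergeableShotsError` (carrying the inputs)
    when adjacent mini-mosaics cannot be registered.
    """
    if not minis:
        raise ValueError("no mini-mosaics to merge")
    if len(minis) == 1:
        return minis[0].canvas
    policy = policy or RegistrationPolicy()

    pseudo = [Frame(index=m.shot_index, image=m.canvas.image) for m in minis]
    chains = {pseudo[0].index: np.eye(3)}
    running = np.eye(3)
    for prev, cur, mini in zip(pseudo, pseudo[1:], minis[1:]):
        try:
            res = adaptive_register(cur, prev, policy, seed=seed)
        except RegistrationFailureError as exc:
            raise UnmergeableShotsError(
                f"mini-mosaics {prev.index} and {cur.index} share no usable "
                f"overlap: {exc}", minis) from exc
        running = normalize_homography(running @ res.matrix)
        chains[cur.index] = running

    # canvas over all mini footprints
    pts = []
    for p in pseudo:
        pts.append(footprint_polygon(chains[p.index], p.width, p.height))
    allpts = np.vstack(pts)
    if not np.all(np.isfinite(allpts)):
        raise DegenerateTransformError("degenerate meta-chain")
    x0, y0 = np.floor(allpts.min(axis=0)).astype(int)
    x1, y1 = np.ceil(allpts.max(axis=0)).astype(int)
    if x1 - x0 + 1 > MAX_CANVAS_DIM or y1 - y0 + 1 > MAX_CANVAS_DIM:
        raise CanvasOverflowError("meta-canvas exceeds the size limit")
    meta = MosaicCanvas.empty(CanvasSpec(width=int(x1 - x0 + 1),
                                         height=int(y1 - y0 + 1),
                                         offset=(int(-x0), int(-y0))))
    for p, mini in zip(pseudo, minis):
        warp_and_blend(meta, p, chains[p.index],
                       source_mask=mini.canvas.filled_mask)
    return meta


def save_chain_json(chain: HomographyChain, path: str | Path) -> None:
    data = {str(i): {"H_CR": chain.h_cr[i].ravel().tolist(),
                     "H_CB": chain.h_cb[i].ravel().tolist(),
                     "group": chain.group_of[i]}
            for i in sorted(chain.h_cb)}
    Path(path).write_text(json.dumps(data, indent=1))


def save_footprints_json(canvas: MosaicCanvas, path: str | Path) -> None:
    data = {str(i): fp.tolist() for i, fp in sorted(canvas.footprints.items())}
    Path(path).write_text(json.dumps(data, indent=1))
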