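"""Planar homography utilities.

Convention used throughout the package: a homography ``H`` is a 3x3 array
mapping homogeneous *source* pixel coordinates ``(x, y, 1)`` to *destination*
coordinates, with 0-based pixel centers and ``H[2, 2]`` normalized to 1.
Points are stored as ``(N, 2)`` arrays of ``(x, y)``.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import Polygon

__all__ = [
    "normalize_homography",
    "apply_homography",
    "compose",
    "invert",
    "fit_homography_dlt",
    "frame_corners",
    "footprint_polygon",
    "polygon_iou",
    "symmetric_transfer_error",
    "corner_error",
    "translation",
    "similarity",
]


class DegenerateTransformError(ValueError):
    """Raised when a homography is singular or maps points to infinity."""


def normalize_homography(H: np.ndarray) -> np.ndarray:
    """Scale ``H`` so its (2, 2) element equals 1."""
    H = np.asarray(H, dtype=float)
    if H.shape != (3, 3):
        raise ValueError(f"homography must be 3x3, got {H.shape}")
    denom = H[2, 2]
    if not np.isfinite(denom) or abs(denom) < 1e-15:
        raise DegenerateTransformError("homography cannot be normalized: H[2,2] ~ 0")
    return H / denom


def apply_homography(H: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Map ``(N, 2)`` points through ``H``; returns ``(N, 2)``."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    ones = np.ones((pts.shape[0], 1))
    hom = np.hstack([pts, ones]) @ np.asarray(H, dtype=float).T
    w = hom[:, 2]
    if np.any(np.abs(w) < 1e-12):
        raise DegenerateTransformError("point mapped to infinity")
    return hom[:, :2] / w[:, None]


def compose(*homographies: np.ndarray) -> np.ndarray:
    """Matrix product ``A @ B @ ...`` normalized so element (2, 2) is 1.

    As with plain matrix products, the rightmost transform acts first on a
    point.
    """
    out = np.eye(3)
    for H in homographies:
        out = out @ np.asarray(H, dtype=float)
    return normalize_homography(out)


def invert(H: np.ndarray) -> np.ndarray:
    H = np.asarray(H, dtype=float)
    det = np.linalg.det(H)
    if not np.isfinite(det) or abs(det) < 1e-15:
        raise DegenerateTransformError("homography is singular")
    return normalize_homography(np.linalg.inv(H))


def translation(tx: float, ty: float) -> np.ndarray:
    return np.array([[1.0, 0.0, tx], [0.0, 1.0, ty], [0.0, 0.0, 1.0]])


def similarity(scale: float = 1.0, angle_deg: float = 0.0,
               tx: float = 0.0, ty: float = 0.0,
               center: tuple[float, float] | None = None) -> np.ndarray:
    """Similarity transform (rotation about ``center``, then scale + shift)."""
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    M = np.array([[scale * c, -scale * s, tx],
                  [scale * s, scale * c, ty],
                  [0.0, 0.0, 1.0]])
    if center is not None:
        cx, cy = center
        M = translation(cx, cy) @ M @ translation(-cx, -cy)
        M = normalize_homography(M)
    return M


def frame_corners(width: int, height: int) -> np.ndarray:
    """Corners of a ``width x height`` frame (0-based pixel centers), CCW."""
    w, h = width - 1.0, height - 1.0
    return np.array([[0.0, 0.0], [w, 0.0], [w, h], [0.0, h]])


def footprint_polygon(H: np.ndarray, width: int, height: int) -> np.ndarray:
    """Frame corners mapped into destination coordinates: the footprint."""
    return apply_homography(H, frame_corners(width, height))


def polygon_iou(poly_a: np.ndarray, poly_b: np.ndarray) -> float:
    """Intersection-over-union of two quadrilaterals given as (4, 2) corners."""
    a = Polygon(poly_a).buffer(0)
    b = Polygon(poly_b).buffer(0)
    union = a.union(b).area
    if union == 0:
        return 0.0
    return a.intersection(b).area / union


def _hartley_normalization(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Translate centroid to origin, scale mean distance to sqrt(2)."""
    centroid = points.mean(axis=0)
    shifted = points - centroid
    mean_dist = np.mean(np.linalg.norm(shifted, axis=1))
    scale = np.sqrt(2.0) / mean_dist if mean_dist > 1e-12 else 1.0
    T = np.array([[scale, 0.0, -scale * centroid[0]],
                  [0.0, scale, -scale * centroid[1]],
                  [0.0, 0.0, 1.0]])
    return shifted * scale, T


def fit_homography_dlt(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Least-squares homography from >= 4 correspondences (normalized DLT).

    Solves for H minimizing the algebraic error of ``dst ~ H src`` via SVD,
    with Hartley pre-normalization of both point sets for conditioning.
    Raises :class:`DegenerateTransformError` for rank-deficient (e.g.
    collinear) configurations.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ValueError("src and dst must both be (N, 2)")
    n = src.shape[0]
    if n < 4:
        raise ValueError(f"need >= 4 correspondences, got {n}")

    src_n, T_src = _hartley_normalization(src)
    dst_n, T_dst = _hartley_normalization(dst)

    A = np.zeros((2 * n, 9))
    x, y = src_n[:, 0], src_n[:, 1]
    u, v = dst_n[:, 0], dst_n[:, 1]
    A[0::2, 0] = x
    A[0::2, 1] = y
    A[0::2, 2] = 1.0
    A[0::2, 6] = -u * x
    A[0::2, 7] = -u * y
    A[0::2, 8] = -u
    A[1::2, 3] = x
    A[1::2, 4] = y
    A[1::2, 5] = 1.0
    A[1::2, 6] = -v * x
    A[1::2, 7] = -v * y
    A[1::2, 8] = -v

    _, s, Vt = np.linalg.svd(A)
    if n == 4 and s[-2] < 1e-10 * max(s[0], 1.0):
        # two vanishing singular values: degenerate (collinear) sample
        raise DegenerateTransformError("degenerate correspondence configuration")
    Hn = Vt[-1].reshape(3, 3)
    H = np.linalg.inv(T_dst) @ Hn @ T_src
    if abs(H[2, 2]) < 1e-12 or abs(np.linalg.det(H)) < 1e-12:
        raise DegenerateTransformError("fitted homography is degenerate")
    return normalize_homography(H)


def symmetric_transfer_error(H: np.ndarray, src: np.ndarray,
                             dst: np.ndarray) -> np.ndarray:
    """Per-correspondence mean of forward and backward transfer distances."""
    H_inv = invert(H)
    fwd = np.linalg.norm(apply_homography(H, src) - dst, axis=1)
    bwd = np.linalg.norm(apply_homography(H_inv, dst) - src, axis=1)
    return 0.5 * (fwd + bwd)


def corner_error(H_a: np.ndarray, H_b: np.ndarray, width: int,
                 height: int) -> float:
    """Maximum displacement of frame corners mapped through H_a vs H_b."""
    ca = footprint_polygon(H_a, width, height)
    cb = footprint_polygon(H_b, width, height)
    return float(np.max(np.linalg.norm(ca - cb, axis=1)))
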