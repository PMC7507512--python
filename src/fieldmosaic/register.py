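"""Adaptive pairwise registration: a ladder of descriptors, escalated on
low inlier ratios.

Fast descriptors handle the common large-overlap case; when the
post-RANSAC inlier ratio of a rung falls below the threshold (default 40%)
the next, more robust rung is tried. If every rung falls short, the
best-ratio result is returned flagged as low-confidence rather than
discarded — a mosaic with one weak link beats no mosaic.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .features import (DESCRIPTOR_KINDS, FeatureSet, LowTextureError,
                       detect_features, match_features)
from .preprocess import Frame
from .ransac import Homography, RegistrationFailureError, ransac_filter
from .refine import photometric_refine

__all__ = ["RegistrationPolicy", "RegistrationResult", "FeatureCache",
           "adaptive_register", "write_registration_log"]


@dataclass(frozen=True)
class RegistrationPolicy:
    """Knobs of the adaptive descriptor ladder.

    Defaults follow the pipeline's stated operating point: up to 5000
    strongest keypoints, escalation when the inlier ratio falls below 40%,
    0.75 Lowe ratio test, 2 px RANSAC tolerance with at most 2000 iterations.
    """

    ladder: tuple[str, ...] = DESCRIPTOR_KINDS
    inlier_threshold: float = 0.40
    max_keep: int = 5000
    ratio_test: float = 0.75
    ransac_tol_px: float = 2.0
    ransac_max_iters: int = 2000
    st_block_size: int = 8
    # a rung with fewer putative matches than this cannot support a
    # trustworthy consensus (RANSAC's own 4-point sample always "fits") and
    # is treated as failed, so the ladder escalates
    min_matches: int = 10
    # a consensus smaller than twice the 4-point minimal sample is not
    # evidence of a real model; such rungs fail and the ladder escalates
    min_inliers: int = 8
    # Gauss-Newton photometric polish of the RANSAC estimate; keypoint
    # localization noise otherwise random-walks into drift over long chains
    photometric_refine: bool = True

    def __post_init__(self) -> None:
        if not self.ladder:
            raise ValueError("descriptor ladder must be non-empty")
        unknown = set(self.ladder) - set(DESCRIPTOR_KINDS)
        if unknown:
            raise ValueError(f"unknown descriptors in ladder: {unknown}")


@dataclass
class RegistrationResult:
    """Outcome of registering one frame pair."""

    homography: Homography
    descriptor_used: str
    inlier_ratio: float
    n_features_src: int
    n_features_dst: int
    n_matches: int
    low_confidence: bool = False

    @property
    def matrix(self) -> np.ndarray:
        return self.homography.matrix


class FeatureCache:
    """Per-(frame, descriptor) feature memo so references are detected once."""

    def __init__(self, policy: RegistrationPolicy):
        self.policy = policy
        self._store: dict[tuple[int, str], FeatureSet] = {}

    def get(self, frame: Frame, kind: str) -> FeatureSet:
        key = (frame.index, kind)
        if key not in self._store:
            self._store[key] = detect_features(
                frame, kind=kind, max_keep=self.policy.max_keep,
                block_size=self.policy.st_block_size)
        return self._store[key]


def _default_backend(frame: Frame, reference: Frame, kind: str,
                     policy: RegistrationPolicy, seed: int,
                     cache: FeatureCache | None) -> RegistrationResult:
    """One rung: detect, match, RANSAC-filter. Raises on hard failure."""
    if cache is not None:
        fs_a = cache.get(frame, kind)
        fs_b = cache.get(reference, kind)
    else:
        fs_a = detect_features(frame, kind=kind, max_keep=policy.max_keep,
                               block_size=policy.st_block_size)
        fs_b = detect_features(reference, kind=kind, max_keep=policy.max_keep,
                               block_size=policy.st_block_size)
    matches = match_features(fs_a, fs_b, max_ratio=policy.ratio_test)
    if len(matches) < max(4, policy.min_matches):
        raise RegistrationFailureError(
            f"only {len(matches)} {kind} matches between frames "
            f"{frame.index} and {reference.index}")
    matches, hom = ransac_filter(matches, reproj_tol_px=policy.ransac_tol_px,
                                 max_iters=policy.ransac_max_iters, seed=seed)
    if hom.n_inliers < policy.min_inliers:
        raise RegistrationFailureError(
            f"{kind} consensus of {hom.n_inliers} inliers (< "
            f"{policy.min_inliers}) between frames {frame.index} and "
            f"{reference.index}")
    if policy.photometric_refine:
        from .features import _to_gray
        from .geometry import normalize_homography, symmetric_transfer_error
        refined = photometric_refine(hom.matrix, _to_gray(frame) * 255.0,
                                     _to_gray(reference) * 255.0)
        hom.matrix = normalize_homography(refined)
        inl = matches.inlier_mask
        err = symmetric_transfer_error(hom.matrix, matches.src[inl],
                                       matches.dst[inl])
        hom.rms_error = float(np.sqrt(np.mean(err ** 2)))
    return RegistrationResult(homography=hom, descriptor_used=kind,
                              inlier_ratio=matches.inlier_ratio,
                              n_features_src=len(fs_a),
                              n_features_dst=len(fs_b),
                              n_matches=len(matches))


def adaptive_register(frame: Frame, reference: Frame,
                      policy: RegistrationPolicy | None = None,
                      seed: int = 0, backend=None,
                      cache: FeatureCache | None = None
                      ) -> RegistrationResult:
    """Register ``frame`` onto ``reference`` with descriptor escalation.

    Tries the ladder in order and accepts the first rung whose post-RANSAC
    inlier ratio reaches ``policy.inlier_threshold``. If no rung reaches it,
    the best-ratio result is returned with ``low_confidence=True``. Raises
    :class:`RegistrationFailureError` naming the pair when every rung fails
    outright.

    ``backend(frame, reference, kind, policy, seed, cache)`` may be injected
    to replace the detect/match/RANSAC machinery (used for planted-ratio
    policy tests and by meta-mosaicking).
    """
    policy = policy or RegistrationPolicy()
    backend = backend or _default_backend
    best: RegistrationResult | None = None
    failures: list[str] = []
    for kind in policy.ladder:
        try:
            result = backend(frame, reference, kind, policy, seed, cache)
        except (LowTextureError, RegistrationFailureError) as exc:
            failures.append(f"{kind}: {exc}")
            continue
        if result.inlier_ratio >= policy.inlier_threshold:
            return result
        if best is None or result.inlier_ratio > best.inlier_ratio:
            best = result
    if best is not None:
        return replace(best, low_confidence=True)
    raise RegistrationFailureError(
        f"registration failed at every descriptor rung for frames "
        f"{frame.index} -> {reference.index}: {'; '.join(failures)}")


def write_registration_log(records: list[dict], path: str | Path) -> None:
    """Per-pair bookkeeping CSV: the features -> strongest-K -> matches ->
    inliers funnel plus the descriptor used and reprojection RMS."""
    fields = ["source_frame", "target_frame", "descriptor", "n_features_src",
              "n_features_dst", "n_matches", "n_inliers", "inlier_ratio",
              "rms_error", "low_confidence"]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        for rec in records:
            writer.writerow({k: rec.get(k, "") for k in fields})
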