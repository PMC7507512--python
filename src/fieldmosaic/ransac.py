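"""Seeded RANSAC homography fitting over putative feature matches.

Random 4-point subsets are fit by normalized DLT, scored by symmetric
transfer error, and the largest consensus set wins; the final model is a
least-squares DLT refit on that consensus set. The iteration count adapts
to the observed inlier ratio (99.9% confidence of an outlier-free sample)
and everything is driven by an explicit seed, so results are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import MatchSet
from .geometry import (DegenerateTransformError, fit_homography_dlt,
                       symmetric_transfer_error)

__all__ = ["Homography", "RegistrationFailureError", "ransac_filter"]


class RegistrationFailureError(RuntimeError):
    """No homography with a minimal consensus could be found."""


@dataclass
class Homography:
    """A fitted 3x3 projective transform between two frames.

    ``matrix`` maps source-frame points into target-frame coordinates,
    element (2, 2) normalized to 1. ``rms_error`` is the root-mean-square
    symmetric transfer error over the inliers only.
    """

    matrix: np.ndarray
    source_frame: int
    target_frame: int
    rms_error: float
    n_inliers: int


def ransac_filter(matches: MatchSet, reproj_tol_px: float = 2.0,
                  max_iters: int = 2000, seed: int = 0
                  ) -> tuple[MatchSet, Homography]:
    """Robustly fit a homography and mark the consensus inliers.

    Degenerate (collinear) minimal samples are rejected and iteration
    continues. Raises ``ValueError`` for fewer than 4 correspondences and
    :class:`RegistrationFailureError` when no model reaches 4 inliers.
    Returns the same :class:`MatchSet` with ``inlier_mask`` filled, plus the
    refit :class:`Homography`.
    """
    n = len(matches)
    if n < 4:
        raise ValueError(f"RANSAC needs >= 4 correspondences, got {n}")
    src, dst = matches.src, matches.dst
    rng = np.random.default_rng(seed)

    best_mask: np.ndarray | None = None
    best_count = 0
    best_mean_err = np.inf
    needed = max_iters
    it = 0
    while it < min(needed, max_iters):
        it += 1
        sample = rng.choice(n, size=4, replace=False)
        try:
            H = fit_homography_dlt(src[sample], dst[sample])
            err = symmetric_transfer_error(H, src, dst)
        except DegenerateTransformError:
            continue
        mask = err <= reproj_tol_px
        count = int(mask.sum())
        mean_err = float(err[mask].mean()) if count else np.inf
        if count > best_count or (count == best_count
                                  and mean_err < best_mean_err):
            best_count, best_mask, best_mean_err = count, mask, mean_err
            w = count / n
            if w > 0:
                denom = np.log1p(-min(w ** 4, 1 - 1e-12))
                needed = int(np.ceil(np.log(1e-3) / denom)) if denom < 0 \
                    else max_iters
    if best_mask is None or best_count < 4:
        raise RegistrationFailureError(
            f"no homography with >= 4 inliers between frames "
            f"{matches.source_frame} and {matches.target_frame}")

    H = fit_homography_dlt(src[best_mask], dst[best_mask])
    err = symmetric_transfer_error(H, src[best_mask], dst[best_mask])
    rms = float(np.sqrt(np.mean(err ** 2)))
    matches.inlier_mask = best_mask
    return matches, Homography(matrix=H,
                               source_frame=matches.source_frame,
                               target_frame=matches.target_frame,
                               rms_error=rms, n_inliers=best_count)
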