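"""Shot detection: temporal segmentation by histogram-difference energy.

A shot is a temporally contiguous, scene-consistent run of frames. Abrupt
viewpoint or scene changes produce a spike in the cumulative-histogram
difference between consecutive frames; within-shot pairs produce small
energies. The energies therefore form two clusters (within-shot vs
boundary), which a 1D two-means split separates.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .preprocess import Frame

__all__ = ["Shot", "pair_energy", "sequence_energies", "detect_shots",
           "write_shots_manifest", "write_energy_csv"]


@dataclass(frozen=True)
class Shot:
    """Inclusive 1-based frame range; the base frame is the first frame."""

    start_frame: int
    end_frame: int

    @property
    def base_frame(self) -> int:
        return self.start_frame

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


def pair_energy(frame_a: Frame | np.ndarray, frame_b: Frame | np.ndarray,
                n_bins: int = 64) -> float:
    """Cumulative-histogram L1 difference between two frames.

    Per channel: a normalized ``n_bins``-bin intensity histogram is
    accumulated into a CDF, and the L1 distance between the two frames' CDFs
    is summed over bins and channels. Symmetric, non-negative and zero iff
    the intensity distributions coincide. Maximal (``3 * (n_bins - 1)``) for
    an all-black vs all-white pair.
    """
    img_a = frame_a.image if isinstance(frame_a, Frame) else np.asarray(frame_a)
    img_b = frame_b.image if isinstance(frame_b, Frame) else np.asarray(frame_b)
    if img_a.shape != img_b.shape:
        raise ValueError(f"frame shapes differ: {img_a.shape} vs {img_b.shape}")
    energy = 0.0
    for c in range(img_a.shape[2]):
        ha, _ = np.histogram(img_a[..., c], bins=n_bins, range=(0, 256))
        hb, _ = np.histogram(img_b[..., c], bins=n_bins, range=(0, 256))
        cdf_a = np.cumsum(ha / ha.sum())
        cdf_b = np.cumsum(hb / hb.sum())
        energy += float(np.abs(cdf_a - cdf_b).sum())
    return energy


def sequence_energies(frames: list[Frame], n_bins: int = 64) -> np.ndarray:
    """Pair energies for all n-1 consecutive pairs of a sequence."""
    return np.array([pair_energy(frames[i], frames[i + 1], n_bins)
                     for i in range(len(frames) - 1)])


def _two_means_1d(values: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Exact 1D 2-means: minimizes within-cluster sum of squares over all
    sorted split points. Returns (boolean high-cluster mask, mu_low, mu_high)."""
    order = np.argsort(values, kind="stable")
    v = values[order]
    n = len(v)
    csum = np.concatenate([[0.0], np.cumsum(v)])
    csq = np.concatenate([[0.0], np.cumsum(v * v)])
    best_k, best_cost = n, np.inf
    for k in range(1, n):          # low cluster = v[:k], high = v[k:]
        s1, q1 = csum[k], csq[k]
        s2, q2 = csum[n] - s1, csq[n] - q1
        cost = (q1 - s1 * s1 / k) + (q2 - s2 * s2 / (n - k))
        if cost < best_cost - 1e-15:
            best_cost, best_k = cost, k
    mask = np.zeros(n, dtype=bool)
    mask[order[best_k:]] = True
    mu_low = float(values[~mask].mean()) if best_k > 0 else 0.0
    mu_high = float(values[mask].mean()) if best_k < n else mu_low
    return mask, mu_low, mu_high


def detect_shots(energies: np.ndarray, min_shot_len: int = 3,
                 separation_factor: float = 7.0,
                 mean_ratio: float = 3.0) -> list[Shot]:
    """Split a sequence into shots from consecutive-pair energies.

    ``energies[t-1]`` is the energy between frames ``t`` and ``t+1``
    (1-based), so ``n = len(energies) + 1`` frames. The energies are split
    into low (within-shot) and high (boundary) clusters by exact 1D
    two-means; each high pair becomes a shot boundary. When the
    between-cluster separation is below ``separation_factor`` times the
    low-cluster standard deviation, or the high-cluster mean is below
    ``mean_ratio`` times the low-cluster mean, the sequence is treated as
    boundary-free. Both guards are scale-invariant and needed: an exact
    2-means split of *unimodal* energies always manufactures a separation
    of about four low-cluster standard deviations, and smooth trajectory
    features (e.g. a turn) can stand a couple of standard deviations above
    very quiet within-shot energies without being viewpoint jumps — while
    a genuine jump moves the histogram by many times the within-shot mean.
    Shots shorter than ``min_shot_len`` are merged into the preceding shot.
    The result always partitions ``[1, n]`` contiguously.

    Scale-invariant: multiplying all energies by a positive constant leaves
    the boundaries unchanged.
    """
    energies = np.asarray(energies, dtype=float)
    if energies.size < 1:
        raise ValueError("need at least one pair energy")
    n_frames = len(energies) + 1
    if energies.size == 1:
        return [Shot(1, n_frames)]

    mask, mu_low, mu_high = _two_means_1d(energies)
    std_low = float(energies[~mask].std()) if (~mask).any() else 0.0
    if (mu_high - mu_low <= separation_factor * std_low
            or mu_high <= mean_ratio * mu_low):
        return [Shot(1, n_frames)]

    boundaries = np.flatnonzero(mask) + 1       # frame index ending a shot
    shots: list[Shot] = []
    start = 1
    for b in boundaries:
        if b >= start:                           # merge consecutive boundaries
            shots.append(Shot(start, int(b)))
            start = int(b) + 1
    if start <= n_frames:
        shots.append(Shot(start, n_frames))
    else:                                        # boundary at the last pair
        shots[-1] = Shot(shots[-1].start_frame, n_frames)

    # enforce the minimum shot length: short shots merge into the preceding
    # shot (a short leading shot merges into its successor)
    while len(shots) > 1:
        short = next((i for i, s in enumerate(shots)
                      if s.n_frames < min_shot_len), None)
        if short is None:
            break
        if short == 0:
            shots[1] = Shot(shots[0].start_frame, shots[1].end_frame)
            del shots[0]
        else:
            shots[short - 1] = Shot(shots[short - 1].start_frame,
                                    shots[short].end_frame)
            del shots[short]
    return shots


def write_shots_manifest(shots: list[Shot], path: str | Path) -> None:
    data = [{"shot": i + 1, "start": s.start_frame, "end": s.end_frame}
            for i, s in enumerate(shots)]
    Path(path).write_text(json.dumps(data, indent=1))


def write_energy_csv(energies: np.ndarray, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["pair_index", "energy"])
        for t, e in enumerate(energies, start=1):
            writer.writerow([t, f"{e:.6f}"])
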