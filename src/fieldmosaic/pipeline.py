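"""End-to-end pipeline: preprocess -> shot detection -> mini-mosaics ->
meta-mosaic -> quality report; plus the synthetic-flight driver."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .features import DESCRIPTOR_KINDS
from .mosaic import (MiniMosaic, MosaicCanvas, UnmergeableShotsError,
                     build_mini_mosaic, meta_mosaic, save_chain_json,
                     save_footprints_json)
from .preprocess import CameraModel, Frame, downsample, load_frames, undistort
from .quality import QualityReport, evaluate_mosaic
from .register import RegistrationPolicy, write_registration_log
from .shots import (detect_shots, sequence_energies, write_energy_csv,
                    write_shots_manifest)
from .synthetic import (TrajectorySpec, make_field_texture,
                        make_trajectory, render_frames, save_dataset)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "run_simulate"]


@dataclass
class PipelineConfig:
    """Everything the pipeline needs, with the stated operating defaults:
    5000 strongest keypoints, 40% inlier-ratio escalation, groups capped at
    40 frames or one-third-of-frame displacement."""

    input_path: str = ""
    output_dir: str = "fieldmosaic_out"
    camera: CameraModel | None = None
    downsample_to: tuple[int, int] | None = None     # (width, height)
    undistort_first: bool = True
    ladder: tuple[str, ...] = DESCRIPTOR_KINDS
    inlier_threshold: float = 0.40
    max_keep: int = 5000
    ratio_test: float = 0.75
    ransac_tol_px: float = 2.0
    ransac_max_iters: int = 2000
    max_group_size: int = 40
    displacement_fraction: float = 1.0 / 3.0
    shot_bins: int = 64
    min_shot_len: int = 3
    shot_separation_factor: float = 7.0
    frame_stride: int = 1
    match_threshold: float = 0.8
    evaluate: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.ladder:
            raise ValueError("descriptor ladder must be non-empty")
        for name, val in [("ratio_test", self.ratio_test),
                          ("ransac_tol_px", self.ransac_tol_px),
                          ("max_group_size", self.max_group_size),
                          ("displacement_fraction", self.displacement_fraction),
                          ("frame_stride", self.frame_stride)]:
            if val <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def policy(self) -> RegistrationPolicy:
        return RegistrationPolicy(ladder=tuple(self.ladder),
                                  inlier_threshold=self.inlier_threshold,
                                  max_keep=self.max_keep,
                                  ratio_test=self.ratio_test,
                                  ransac_tol_px=self.ransac_tol_px,
                                  ransac_max_iters=self.ransac_max_iters)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cam = data.pop("camera", None)
        if cam is not None:
            cam = CameraModel.from_dict(cam)
        if "ladder" in data:
            data["ladder"] = tuple(data["ladder"])
        if "downsample_to" in data and data["downsample_to"] is not None:
            data["downsample_to"] = tuple(data["downsample_to"])
        data.update(overrides)
        return cls(camera=cam, **data)


@dataclass
class PipelineResult:
    shots: list
    minis: list[MiniMosaic]
    meta: MosaicCanvas | None
    reports: list[QualityReport]
    merged: bool
    timings: dict[str, float] = field(default_factory=dict)

    @property
    def mean_ssim_p(self) -> float | None:
        vals = [r.mean_ssim_p for r in self.reports
                if r.mean_ssim_p is not None]
        return float(np.mean(vals)) if vals else None


def _write_provenance_png(canvas: MosaicCanvas, path: Path) -> None:
    iio.imwrite(path, canvas.provenance.astype(np.uint16))


def run_pipeline(config: PipelineConfig,
                 frames: list[Frame] | None = None) -> PipelineResult:
    """Run the whole mosaicking pipeline and write all artifacts.

    ``frames`` may be passed directly (e.g. from the synthetic generator);
    otherwise they are read from ``config.input_path``. Raises on unreadable
    input or an unbuildable mosaic; an unmergeable meta-stage is downgraded
    to per-shot outputs with ``merged=False``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    if frames is None:
        frames = load_frames(config.input_path, stride=config.frame_stride)
    if not frames:
        raise FileNotFoundError(f"no frames found at {config.input_path}")

    if config.camera is not None or config.downsample_to is not None:
        processed = []
        for fr in frames:
            if config.undistort_first and config.camera is not None:
                fr = undistort(fr, config.camera)
            if config.downsample_to is not None:
                fr = downsample(fr, *config.downsample_to)
            if not config.undistort_first and config.camera is not None:
                fr = undistort(fr, config.camera)
            processed.append(fr)
        frames = processed
    timings["preprocess"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    energies = sequence_energies(frames, n_bins=config.shot_bins)
    shots = detect_shots(energies, min_shot_len=config.min_shot_len,
                         separation_factor=config.shot_separation_factor)
    write_energy_csv(energies, out / "pair_energies.csv")
    write_shots_manifest(shots, out / "shots.json")
    timings["shot_detection"] = time.perf_counter() - t0
    logger.info("detected %d shot(s)", len(shots))

    t0 = time.perf_counter()
    minis: list[MiniMosaic] = []
    all_log: list[dict] = []
    for s_idx, shot in enumerate(shots, start=1):
        shot_frames = [f for f in frames
                       if shot.start_frame <= f.index <= shot.end_frame]
        mini = build_mini_mosaic(shot_frames, policy=config.policy,
                                 seed=config.seed, shot_index=s_idx)
        minis.append(mini)
        all_log.extend(mini.registration_log)
        iio.imwrite(out / f"mini_mosaic_{s_idx:02d}.png", mini.canvas.image)
        save_chain_json(mini.chain, out / f"chain_{s_idx:02d}.json")
        save_footprints_json(mini.canvas, out / f"footprints_{s_idx:02d}.json")
        _write_provenance_png(mini.canvas, out / f"provenance_{s_idx:02d}.png")
    write_registration_log(all_log, out / "registration_log.csv")
    timings["mini_mosaics"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    merged = True
    meta: MosaicCanvas | None = None
    try:
        meta = meta_mosaic(minis, policy=config.policy, seed=config.seed)
        iio.imwrite(out / "meta_mosaic.png", meta.image)
    except UnmergeableShotsError as exc:
        logger.warning("meta-mosaicking failed: %s; per-shot mosaics kept",
                       exc)
        merged = False
    timings["meta_mosaic"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    reports: list[QualityReport] = []
    if config.evaluate:
        for s_idx, (shot, mini) in enumerate(zip(shots, minis), start=1):
            shot_frames = [f for f in frames
                           if shot.start_frame <= f.index <= shot.end_frame]
            rep = evaluate_mosaic(shot_frames, mini.chain, mini.canvas,
                                  match_threshold=config.match_threshold)
            rep.write_json(out / f"quality_{s_idx:02d}.json")
            rep.write_csv(out / f"quality_{s_idx:02d}.csv")
            reports.append(rep)
    timings["quality"] = time.perf_counter() - t0

    (out / "timings.json").write_text(json.dumps(
        {k: round(v, 3) for k, v in timings.items()}, indent=1))
    summary = {
        "n_frames": len(frames),
        "n_shots": len(shots),
        "merged": merged,
        "mean_ssim_p": (float(np.mean([r.mean_ssim_p for r in reports]))
                        if reports and all(r.mean_ssim_p is not None
                                           for r in reports) else None),
        "mean_ssim_f": (float(np.mean([r.mean_ssim_f for r in reports]))
                        if reports and all(r.mean_ssim_f is not None
                                           for r in reports) else None),
        "scene_integrity": (float(np.mean([r.scene_integrity
                                           for r in reports]))
                            if reports else None),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return PipelineResult(shots=shots, minis=minis, meta=meta,
                          reports=reports, merged=merged, timings=timings)


def run_simulate(out_dir: str | Path, spec: TrajectorySpec,
                 texture_size: tuple[int, int] = (2400, 1600),
                 row_period: int = 48, alley_period: int = 64,
                 noise_sigma: float = 0.0, illum_drift: float = 0.0,
                 seed: int = 0) -> Path:
    """Generate a synthetic flight dataset on disk (frames, ground truth,
    true orthomosaic). Deterministic per seed."""
    scene = make_field_texture(texture_size[0], texture_size[1],
                               row_period=row_period,
                               alley_period=alley_period, seed=seed)
    gt = make_trajectory(scene, spec, seed=seed)
    frames = render_frames(scene, gt, noise_sigma=noise_sigma,
                           illum_drift=illum_drift, seed=seed)
    return save_dataset(out_dir, scene, gt, frames)
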