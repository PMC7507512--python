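"""Build a mini-mosaic from a synthetic shot and check it against truth.

Runs grouping, homography chaining, canvas estimation and pixel-fill
blending, then compares the chained current-to-base transforms and the
final mosaic against the simulator's exact ground truth.
"""

import numpy as np

from fieldmosaic import (TrajectorySpec, build_mini_mosaic, corner_error,
                         invert, make_field_texture, make_trajectory,
                         normalize_homography, render_frames, ssim_masked,
                         warp_image)
from fieldmosaic.geometry import translation

scene = make_field_texture(2000, 1200, seed=2)
spec = TrajectorySpec(kind="out_and_back", n_frames=40,
                      frame_size=(256, 192), overlap_target=0.9)
gt = make_trajectory(scene, spec, seed=2)
frames = render_frames(scene, gt, seed=2)

mini = build_mini_mosaic(frames, seed=0)
print(f"{len(frames)} frames -> {len(mini.groups)} groups "
      f"(sizes {[len(g.members) for g in mini.groups]})")
# groups split when the frame center drifts a third of the frame from its
# reference, or after 40 members, bounding how many transforms compose

errs = [corner_error(mini.chain.h_cb[i], gt.relative(i, 1), 256, 192)
        for i in range(1, 41)]
print(f"chained transform error vs truth: max {max(errs):.3f} px")

ox, oy = mini.canvas.offset
canvas_to_scene = normalize_homography(
    gt.homographies[0] @ invert(translation(ox, oy)))
truth_img, truth_ok = warp_image(scene.texture, canvas_to_scene,
                                 mini.canvas.image.shape[:2])
score = ssim_masked(mini.canvas.image, truth_img,
                    mini.canvas.filled_mask & truth_ok)
print(f"mosaic vs true orthophoto SSIM over filled pixels: {score:.4f}")
# values near 1 mean the assembled mosaic is essentially the true scene

import imageio.v3 as iio
iio.imwrite("scratch/example_mosaic.png", mini.canvas.image)
print("mosaic written to scratch/example_mosaic.png")
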