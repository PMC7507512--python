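"""Register one frame pair and inspect the feature funnel.

Shows the stages behind every pairwise registration: detected keypoints,
the strongest-K cut, ratio-test matches, RANSAC inliers, and the recovered
homography compared against the simulator's exact ground truth.
"""

from fieldmosaic import (TrajectorySpec, adaptive_register, corner_error,
                         detect_features, make_field_texture,
                         make_trajectory, match_features, ransac_filter,
                         render_frames)

scene = make_field_texture(1600, 1200, seed=1)
spec = TrajectorySpec(kind="out_and_back", n_frames=8,
                      frame_size=(256, 192), overlap_target=0.9)
gt = make_trajectory(scene, spec, seed=1)
frames = render_frames(scene, gt, seed=1)
current, reference = frames[4], frames[0]

fa = detect_features(current, "st", max_keep=5000)
fb = detect_features(reference, "st", max_keep=5000)
matches = match_features(fa, fb)
matches, hom = ransac_filter(matches, reproj_tol_px=2.0, seed=0)
print(f"features: {len(fa)} / {len(fb)}  ->  matches: {len(matches)}  "
      f"->  inliers: {hom.n_inliers}  (ratio {matches.inlier_ratio:.2f})")
# the funnel narrows at each stage; the inlier ratio drives the adaptive
# descriptor ladder (below 40% the pipeline escalates to a sturdier rung)

result = adaptive_register(current, reference, seed=0)
truth = gt.relative(current.index, reference.index)
err = corner_error(result.matrix, truth, current.width, current.height)
print(f"adaptive registration used '{result.descriptor_used}'; "
      f"corner error vs ground truth: {err:.3f} px")
# sub-0.1 px errors are typical on clean imagery after photometric polish
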