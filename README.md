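# rgbmocap

Marker-based optical motion capture with ordinary RGB cameras.

Infrared motion-capture systems track retro-reflective markers automatically
but are expensive; plain RGB video is cheap but traditionally requires
manual digitization of every marker in every frame.  `rgbmocap` implements
the surrounding machinery of an RGB marker-based pipeline in which a
fine-tuned object-detection network replaces manual digitization:

* **Training-data synthesis** — annotated 640×640 training images are
  generated by compositing randomized *virtual markers* (deformed coloured
  discs, optionally backed by a simulated strip of white fixing tape) onto
  background frames recorded without markers.  Sphere colours are drawn in
  HSL (H 140–160, S 240–255, L 140–170 on byte scales), diameters land in
  8–24 px, 7–12 markers are inserted per image, and a per-marker Gaussian
  blur (σ ∈ [0.5, 3.0]) smooths the pasted boundary while every pixel
  outside the marker regions stays bit-identical to the background.
* **Detector plumbing** — the detector itself is a pluggable contract (any
  callable image → boxes; a GPU-free HSL blob detector is bundled for
  tests), with bicubic 2× pre-detection upscaling, coordinate mapping back
  to native resolution, and a square-bounding-box filter that discards
  partially occluded markers.
* **Wand calibration** — all camera projection matrices `P` (3×4 DLT form,
  `x ~ P [X; 1]`) are estimated from synchronized views of a rigid
  two-marker wand of known length swept through the volume, via incremental
  structure-from-motion initialisation and sparse bundle adjustment that
  includes the known inter-marker distance in the objective.
* **Reconstruction** — marker correspondences across cameras are unknown;
  combinations of per-camera detections are accepted only when the
  triangulated point lies within 5 mm of *every* contributing camera's
  back-projected ray and at least 3 cameras contribute.  Accepted points
  are assembled into labelled trajectories by gated nearest-neighbour
  tracking, exportable as CSV or TRC.
* **Evaluation** — Bland–Altman agreement per coordinate (fixed bias via
  one-sample t-test, proportional bias via difference-on-mean regression),
  resultant-error statistics (mean, 95th/99th percentile), and a
  reprojection-noise Monte Carlo that measures reconstruction robustness as
  a function of the number of contributing cameras.
* **Scene simulator** — a ground-truth generator (8-camera ring around a
  2 × 4 × 2 m volume, 25 gait-like marker trajectories at 240 fps, wand
  sweeps, exact/noisy projections, rendered frames) so the whole pipeline
  is testable without recordings or a GPU.

## Worked example

```python
import numpy as np
from rgbmocap import (
    RigParams, WandSpec, make_rig, simulate_wand, calibrate_from_wand,
    make_scene, project_scene, match_and_triangulate, resultant_error_stats,
)
from rgbmocap.wand_calibration import wand_observations_from_track
from rgbmocap.detection_io import detections_from_dataframe

# 1. calibrate an 8-camera rig from a 200-frame wand sweep (0.3 px noise)
rig = make_rig(RigParams())
track = simulate_wand(length_mm=500.0, n_frames=200, seed=3)
obs = wand_observations_from_track(track, rig, noise_sigma_px=0.3, seed=11)
cal = calibrate_from_wand(obs, WandSpec(distance=500.0))
print(f"wand length error:    {cal.length_error_mean:.2f} mm")
print(f"reconstruction error: {cal.reconstruction_error_mean:.2f} mm")
print(f"reprojection RMS:     {cal.reprojection_rms:.2f} px")

# 2. reconstruct a 25-marker walking sequence from noisy detections
scene = make_scene(seed=0, wand_frames=10)
cameras = {c.id: c for c in scene.cameras}
detections = project_scene(scene, noise_sigma_px=0.5, dropout_p=0.0, seed=5)
proposed, gold = [], []
for frame in range(20):
    pts = match_and_triangulate(
        detections_from_dataframe(detections[detections.frame == frame]), cameras
    )
    gt = scene.trajectories[:, frame, :]
    for p in pts:
        d = np.linalg.norm(gt - p.position, axis=1)
        if d.min() < 20:
            proposed.append(p.position)
            gold.append(gt[np.argmin(d)])
stats = resultant_error_stats(np.array(proposed) - np.array(gold))
print(f"markers reconstructed: {len(proposed)} / {20 * 25}")
print(f"mean resultant error:  {stats.mean:.2f} mm (p95 {stats.p95:.2f} mm)")
```

Output:

```
wand length error:    0.50 mm
reconstruction error: 1.04 mm
reprojection RMS:     0.27 px
markers reconstructed: 499 / 500
mean resultant error:  1.35 mm (p95 2.38 mm)
```

The wand length error is the mean absolute deviation of the reconstructed
inter-marker distance from the known 500 mm; the reconstruction error is
the mean distance between each reconstructed wand marker and the camera
rays used to triangulate it.  In the second part, 0.5 px of detection noise
at this rig geometry (~3 mm per ray) leaves a mean 3D resultant error of
about 1.4 mm across 25 simultaneously tracked markers.

A `rgbmocap` command-line tool exposes the same pipeline
(`simulate`, `make-dataset`, `calibrate-wand`, `detect`, `reconstruct`,
`evaluate`, `robustness`); run `rgbmocap --help`.

## Layout

```
src/rgbmocap/
  geometry.py         # DLT cameras, rays, triangulation, resection, camera I/O
  wand_calibration.py # SfM init + bundle adjustment with wand-length residuals
  marker_synthesis.py # virtual sphere/tape compositing, dataset writer
  detection_io.py     # detector contract, upscaling, filters, CSV tables
  reconstruction.py   # correspondence search, gating, tracking, TRC export
  evaluation.py       # Bland-Altman, resultant error, robustness Monte Carlo
  scene_simulator.py  # rigs, gait markers, wand sweeps, rendering
  cli.py
docs/methods.md       # models, parameters, numerical choices, limitations
```
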