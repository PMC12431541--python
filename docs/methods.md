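# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `rgbmocap`.  Everything stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is quoted from external data.

## Camera model and triangulation

A camera is a single real 3×4 projection matrix `P` acting on homogeneous
lab coordinates in millimetres (`x ~ P [X; 1]`), i.e. the 11-parameter DLT
form.  We deliberately do not factor `P` into intrinsics and extrinsics in
the pipeline itself (a factorisation helper exists for gauge fixing), and
we model no lens distortion: at 1080p with machine-vision-class lenses the
pinhole residual is far below the other error sources handled here.
Pixels are 0-based, origin top-left, `u` rightward, `v` downward.  `P` is
defined up to scale; stored cameras are normalised to unit Frobenius norm
with a positive determinant of the left 3×3 block, which also gives a
well-defined cheirality (sign of depth).

A pixel back-projects to a **camera ray**, the half-line from the camera
centre (null space of `P`) through the directions of positive depth.  The
distance from a point to a ray is the perpendicular line distance; if the
foot of the perpendicular falls behind the camera centre the distance to
the centre itself is used and the condition is exposed through the foot
parameter (`ray_foot_parameter`), so callers can flag behind-camera
geometry.  In normal operation reconstructed points are always in front.

**Triangulation** minimises the sum of squared point-to-ray distances over
all observing cameras — a 3×3 linear solve (`A = Σ (I − d dᵀ)`).  The
objective is ray-space rather than image-space on purpose: the acceptance
gate and the reported reconstruction error are both defined as
point-to-ray distances in millimetres, so the estimator optimises exactly
the quantity being gated.  Degeneracy (fewer than two rays, all rays
near-parallel, coincident camera centres) is detected via the spectrum of
`A` (relative eigenvalue threshold 1e-10) and raised as an error.
DLT resection (`dlt_calibrate`) uses Hartley-normalised linear least
squares, requires ≥ 6 non-coplanar points, and reproduces noiseless
cameras to machine precision.

## Training-image synthesis

Real spherical markers are imperfect, taped to the skin, and seen from
arbitrary orientations.  The generator composites, per marker:

1. **Virtual sphere.**  A disc of base diameter 96 px is divided into nine
   regions by two vertical and two horizontal boundary lines; each
   boundary is drawn uniformly (first from [0.25, 0.42], second from
   [0.58, 0.75] of the diameter) and the regions are resized to the drawn
   positions by nearest-neighbour remapping, yielding blob-like shapes
   that still approximate circles.  One axis is then scaled by a factor in
   [0.80, 1.00] (ellipsoidal markers).  The fill colour is uniform, drawn
   in HSL with H ∈ [140, 160], S ∈ [240, 255], L ∈ [140, 170] (all byte
   scales; hue maps 360° onto 256 steps).
2. **Virtual tape**, rendered with probability 0.5: a rectangle of length
   1.5–3.0 and width 0.8–1.6 sphere diameters, centre offset up to 0.5
   diameters, rotated uniformly in [0°, 360°), then compressed vertically
   by an aspect ratio in [0.10, 1.00] (a tape seen edge-on flattens);
   colour H ∈ [0, 30], S ∈ [0, 20], L ∈ [200, 255] (near-white).  The
   rectangle mask is evaluated analytically on pixel centres, so rotation
   introduces no resampling artefacts.
3. **Composition.**  The tape is drawn under the sphere with its image
   centre at the anchor `v1 = v2·r + v3·(1−r)`, where `v2` is the sphere
   centroid, `v3` the sphere's bottom-edge point and `r` the tape aspect
   ratio: a face-on tape (r = 1) is centred behind the sphere, an edge-on
   tape (r = 0) appears at the sphere's base, matching how a taped marker
   projects at different camera elevations.  The composite is resized
   (nearest neighbour) until the sphere's bounding-box diameter lies in
   [8, 24] px and rotated by a uniform angle; because rotation can stretch
   the axis-aligned extent slightly, a final corrective resize re-imposes
   the bound.

A training image is a random 320×320 crop of a background frame upscaled
bicubically to 640×640, into which 7–12 composed markers are inserted at
rejection-sampled positions whose blur-dilated footprints do not overlap
(overlapping insertions would corrupt the annotations; the boundary-line
and tape geometry ranges above are package defaults chosen to look like
taped markers, and are all configurable in `SynthesisConfig`).  Each
marker's neighbourhood is filtered with a Gaussian of σ ∈ [0.5, 3.0] and
the background is restored outside the marker mask dilated by ⌈3σ⌉ —
boundaries are smoothed while every pixel outside the recorded
`marker_region_mask` stays bit-identical to the plain upscaled crop.
Annotations are the tight bounding boxes of the sphere masks (class 0,
darknet-normalised `cx cy w h`).  The dataset writer spawns one child RNG
per image from the master seed, so any image regenerates bit-identically
in isolation.

## Wand calibration

Input: synchronized digitized coordinates of the two coloured markers of a
rigid wand of known length `d` swept through the volume (CSV: frame,
camera, marker a|b, u, v).  Output: all cameras in one lab frame.

1. *Pair initialisation.*  The reference camera (most observations) is
   paired with its best-overlapping partner; the fundamental matrix comes
   from the normalised 8-point method over all shared wand points.  The
   pair's focal length (principal point assumed at the image centre,
   square pixels — an initialisation device only) is chosen by **wand-length
   self-consistency**: for each candidate focal, the essential matrix is
   decomposed, cheirality resolved, the shared points triangulated, and
   the candidate scored by the spread (SD/mean) of the reconstructed
   inter-marker distances.  A wrong focal bends the two-view
   reconstruction projectively, so the rigid wand stops having constant
   length; the score is minimised over a log grid with golden-section
   refinement.  (The classical alternative — equality of the essential
   matrix's singular values — is degenerate whenever the optical axes
   intersect, which is exactly the geometry of a converging ring rig.)
2. *Incremental growth.*  Remaining cameras are added by DLT resection
   against the triangulated cloud, in order of overlap; structure is
   re-triangulated after each addition.  Insufficient overlap raises a
   connectivity error.
3. *Bundle adjustment* over all 12 entries of every `P` and all 3D wand
   points, minimising squared reprojection residuals **plus** per-frame
   wand-length residuals `w·(‖Xa − Xb‖ − d)`.  The length residuals are
   essential, not a refinement: with unconstrained projective cameras the
   zero-reprojection manifold contains every projective warp of the
   scene, and only the known rigid length pins the metric structure (up
   to a global similarity).  The weight `w` defaults to 1 px/mm; results
   are insensitive to it within an order of magnitude because the
   constraint is exact in the data.  Optimisation uses
   `scipy.optimize.least_squares` (TRF, LSMR, analytic sparse Jacobian,
   Huber loss with scale 2 px to absorb occasional misdetections; frames
   where a camera misses a marker contribute no residual).  The robust
   cost recorded at each accepted iterate is non-increasing by
   construction of the trust-region method.
4. *Gauge and scale.*  The solution is transformed so the first camera's
   centre is at the origin with canonical orientation, and scaled so the
   mean reconstructed inter-marker distance equals `d` exactly.

Quality metrics, recomputed from re-triangulated wand points with the
final cameras: the **wand length error** (mean absolute deviation of the
pair distance from `d`) and the **reconstruction error** (mean
point-to-ray distance).  On noiseless synthetic sweeps both reach machine
precision (reprojection RMS ~1e-13 px); at 0.3 px detection noise on the
default rig the length error is ≈0.5 mm — the triangulation noise floor of
re-measuring the wand, not a calibration bias — and marker positions are
recovered to ≈0.8 mm RMS after rigid alignment to ground truth.

## Correspondence search and reconstruction

Which detection belongs to which marker is unknown, so candidate 3D
points are grown combinatorially under a hard rule: every contributing
camera's ray must pass within `gate_mm` (default 5 mm) of the current
triangulated point, and at least `min_cameras` (default 3) must
contribute.  Seeding iterates over camera pairs in decreasing baseline
order; each available detection pair is triangulated (with a cheap
midpoint pre-filter), then every remaining camera's best in-gate
detection is added greedily with re-triangulation after each addition, so
the gate always refers to the updated point.  Candidates sharing a
detection are resolved in favour of more cameras, then lower mean ray
distance; each detection contributes to at most one point.  Two accepted
points may not lie within `merge_radius_mm` (default 24 mm, the physical
marker diameter — two spheres cannot overlap): without this suppression a
marker's detections can split into two disjoint camera subsets under
noise and be reported twice.  All orderings are deterministic given
sorted camera and detection ids.

Count-vs-gate behaviour: a gate below the ray-noise scale starves
reconstruction, the default gate recovers essentially everything, and a
gate approaching the projected inter-marker spacing starts absorbing
neighbours' detections — in that regime the accepted-point count is no
longer exactly monotone in the gate (an inherent property of exclusive
greedy matching, not a defect of a particular gate value).

Labelled trajectories are produced by Hungarian nearest-neighbour
association between consecutive frames, gated at `max_jump_mm` (scaled by
the gap length when a label was occluded).  When two candidate points fall
inside one label's gate the frame is flagged ambiguous rather than
silently swapped, and gaps are recorded.  Export: CSV
(frame, label, x, y, z, n_cameras, mean_ray_distance) and minimal TRC.

## Evaluation

*Bland–Altman*, per coordinate: difference = proposed − gold; fixed bias
via one-sample t-test of the mean difference (95% CI reported);
proportional bias via OLS of the difference on the pairwise mean with a
t-test on the slope; limits of agreement mean ± 1.96 SD.  Parametric
tests are used throughout — the pipeline produces tens of thousands of
paired samples with unimodal error distributions.  Zero-variance
differences are flagged degenerate instead of producing meaningless test
statistics.  *Resultant error*: Euclidean norms summarised by the mean
and the empirical 95th/99th percentiles with the linear-interpolation
convention of `numpy.percentile`.

*Robustness Monte Carlo*: each iteration samples a reconstructed point
uniformly within its camera-count stratum, perturbs the stored digitized
coordinate of **every** contributing camera by a uniform draw over the
disc obtained by reprojecting a 12 mm-diameter sphere (half the marker)
centred at the point, re-triangulates, and records the displacement from
the unperturbed reconstruction; per-stratum mean and maximum are
reported.  Perturbing all cameras (rather than one) is the conservative
reading of simultaneous detection noise; a `noise_mode="one"` switch
provides the alternative, which yields strictly smaller displacements.
Disc sampling is uniform over area (`r ∝ √u`); the disc radius is
computed per camera from the projected sphere radius at the point's
depth.  Displacement means decrease strictly from 3 to 8 cameras on a
symmetric rig and scale linearly with the noise-sphere diameter, as the
linearised triangulation model predicts.

## Scene simulator

The simulator exists to give every module a ground truth, not to model
biomechanics.  Defaults: 8 cameras on a 10 m-radius ring around a
2.0 × 4.0 × 2.0 m volume, heights 800–1200 mm, focal 3200 px at
1920×1080 (every volume corner verified inside every image at
construction; a 24 mm marker subtends ≈8 px at the volume centre, which
is why detection runs on 2× upscaled frames); 25 markers on a spread grid
walking at 1.3 m/s with sinusoidal 2 Hz limb-like oscillation of 10–40 mm
amplitude at 240 fps (pairwise separations stay above 50 mm; frame-to-
frame steps below 10 mm); wand sweeps follow a Lissajous path spanning
≈96% of each volume dimension with smoothly varying orientation and
exactly constant marker separation.  Rendered frames draw visible markers
as perspective-sized HSL-coloured discs on a uniform background — adequate
for the bundled colour detector, with rasterisation (not sensor noise) as
the only error source.  What the simulator does **not** emulate: skin
motion and soft-tissue artefact, occlusion by the body, motion blur,
rolling shutter, lighting variation, lens distortion, or detector
confusion from clothing textures.  Green tests therefore demonstrate
algorithmic correctness and noise propagation, not field accuracy on real
recordings.

## Problem sizes and numerical choices

The test suite and acceptance script run on one CPU in a few minutes; the
sizes are chosen to keep statistical margins wide at that budget:
triangulation oracle 300–500 random 2–8-ray instances; wand calibration
200–500 frames; synthesis contract 1000 images in the suite (200 in the
script); robustness 10⁴ iterations per camera-count stratum; end-to-end
rendering 4–6 frames × 8 cameras.  Bundle-adjustment tolerances default
to 1e-12 (relative); the triangulation degeneracy threshold is 1e-10
relative; percentile and RNG conventions are NumPy's (`default_rng`,
`SeedSequence` spawning for per-image streams).  Ties in candidate
selection are broken by sorted ids, making every pipeline stage
deterministic under a fixed seed.

## Known limitations

* The detector contract ships only the naive colour detector; plugging in
  a trained network is the user's responsibility (dataset layout and
  label format are provided).
* Wand calibration assumes roughly shared intrinsics only for the initial
  pair's focal search; severely heterogeneous rigs may need a manual
  focal guess (`WandCalibConfig.focal_guess_factor`).
* The correspondence search is greedy; pathological geometries (markers
  within the merge radius, gates comparable to marker spacing) can drop
  or merge points, and ghost points can appear under heavy noise when
  leftover detections of different markers align within the gate.
* Hue thresholding does not handle wrap-around ranges; marker colour
  ranges here do not cross the hue origin.
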