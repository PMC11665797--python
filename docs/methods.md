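# Methods

This note records the models, conventions, numerical choices and known
limitations of `surgipose`, in the order the pipeline uses them.

## Conventions

All 3D quantities are millimetres; ADD and translation error are therefore
directly in mm. Pixel coordinates are 0-based with pixel centres on integer
coordinates, x = column, y = row; projected keypoints are continuous
(sub-pixel). A pose is the rigid transform from the instrument frame to the
camera frame, camera looking down +z. The camera is an undistorted pinhole
(calibration matrix K only); if real footage with distortion is used it must
be undistorted upstream.

## Keypoint selection

Keypoints are chosen by greedy farthest-point sampling (FPS) of the surface
cloud: each new point maximises its minimum distance to those already chosen.
The start point is the surface point farthest from the centroid, which makes
the selection deterministic; ties break toward the lower index. n = 10
keypoints by default — comfortably above the 4-point PnP minimum, so several
keypoints can be lost to occlusion before the pose becomes under-determined.
On a rotationally symmetric shaft the azimuthal placement of an FPS pick is
inherently degenerate (many azimuths tie to within sampling noise); the
axial positions are the stable, pose-relevant part of the selection.

## Label rendering

The silhouette is rendered by projecting the dense surface cloud
(default 20 000 points), splatting each point to its nearest pixel and
morphologically closing with a 3×3 element to fill sampling gaps. This
slightly dilates the outline (about half a pixel around the perimeter),
which is negligible for voting but visible when comparing mask areas against
continuous geometry. Vector-field labels store (dx, dy) unit vectors toward
each keypoint at every instrument pixel; a pixel exactly coincident with a
keypoint stores (0, 0) — the limit direction is undefined — and is excluded
from ray casting. Keypoints outside the image still generate valid vector
fields: a direction toward an off-image point is perfectly well defined,
which is what lets the pipeline handle partial visibility.

## Voting

For each keypoint, `num_hypotheses` = 128 random pixel pairs are drawn
without replacement (all pairs enumerated when the instrument has ≤ 64
pixels); each pair's rays are intersected (pairs parallel to within 1e-8
cross-product are skipped) and every candidate is weighted by the consensus
rule with cosine threshold θ = 0.99 over *all* filtered pixels. The keypoint
is the weight-weighted average of candidates; the plain candidate mean is
also kept in the result for diagnostic comparison, since the two aggregation
rules coincide on clean fields but can differ under noise. The per-keypoint
RNG is seeded `seed + keypoint_index`, making results independent of
keypoint order and reproducible. A keypoint with no positively weighted
candidate is flagged not-localizable and excluded from PnP.

## PnP

The solver is a pure-NumPy EPnP: four control points from the centroid and
PCA directions (three in near-planar configurations), nullspace beta cases
N = 1 and N = 2 with a 10-iteration Gauss–Newton polish on the control-point
distances, and absolute orientation by the Kabsch algorithm. Each candidate
is refined by Levenberg–Marquardt (scipy `least_squares`, method `lm`) on
(rotation vector, translation). RANSAC draws minimal 4-point samples, scores
hypotheses by inlier count at a 3 px reprojection threshold (tie-break on
mean inlier error), terminates adaptively at 0.999 confidence, and refits on
the consensus set. Fewer than 4 usable correspondences, or a collinear 3D
configuration, raises an error. Voting confidences are exposed but not used
as weights in the least squares — the unweighted solution is the default and
the hook exists for future use.

## Synthetic scenes

The simulator emulates the structure of an endoscopic pose-estimation
recording: a rigid cylindrical instrument (80 mm shaft, 4 mm radius, 12 mm
tapered tip by default) posed 90–160 mm in front of the camera with free
tilt, roll and spin; a procedurally textured tissue-hued background; a light
intensity factor drawn from [0.4, 1.0] matching the 40%–100% illumination
levels used in real recordings; and optional opaque occluders (bar, disk,
random convex polygon) sized by bisection to cover a target fraction of
instrument pixels. Frames showing less than 20% of the tip (distal 20% of
the instrument's length; visibility = visible tip pixels / unoccluded tip
pixels) are excluded from generated datasets, and every retained frame
carries its pose, keypoints, mask, vector fields and intrinsics in the
dataset manifest. Default image size is 960×540 (half of 1920×1080); the
test-suite studies run at 480×270 with 8 000 surface points, and the
learning study at 96×96 with 3 000 points — scales chosen so the full study
remains cheap on a single core while leaving every algorithmic path
identical.

What the simulator does *not* emulate: photorealistic shading (rendering is
point-splat with depth attenuation and a specular streak, not ray tracing),
articulated jaws/wrists, smoke or fluids, motion blur, lens distortion, or
the appearance statistics of real tissue. Tests passing on synthetic scenes
therefore validate the geometry, the voting/PnP estimators, the label
machinery and the augmentation statistics — not transfer to real video.

## Augmentation

Regular augmentation applies one similarity transform (translation ≤ 20 px,
rotation ≤ 15°, scale 0.9–1.1) to image, mask and keypoints in tandem, plus
multiplicative brightness/contrast/saturation jitter in [0.7, 1.3] on the
image alone. The vector field is re-rendered from the transformed keypoints
and warped mask rather than warped and re-rotated: for a similarity
transform the two are mathematically identical, and re-rendering keeps the
unit-norm invariant exact. A drawn pure translation is rounded to integer
pixels, since only integer shifts translate a raster exactly. If the
transform empties the mask the draw is retried (10 attempts) before the
sample is passed through unaugmented with a flag.

Grid occlusion covers the instrument bounding box with an 8×8 grid; each
cell is independently replaced with probability p_occlusion drawn per sample
from [0.15, 0.5]. A replaced cell becomes per-channel uniform noise in
[0, 255] with probability 0.4, otherwise an image patch copied from a
same-size window fully outside the bounding box containing no instrument
pixels (50 rejection-sampling attempts, then noise fallback, logged).
Replaced cells are erased from the segmentation and vector-field labels.
Occlusion is applied to 60% of samples and background blackout (image zeroed
outside the bounding box; labels already zero there) to 20%. All of these
probabilities are the training conditions of the method and are the
package defaults.

## Losses and the toy network

Segmentation uses binary cross-entropy with probabilities clamped at 1e-7;
the formal convention is a sum over pixels, with a mean-per-pixel option
used for scale-stable training. The vector branch uses Smooth-L1
(0.5x² below |x| = 1, |x| − 0.5 above — continuous with matching slope at
the joint) on instrument pixels only, averaged over keypoints. The keypoint
Smooth-L1 loss is defined on voted 2D keypoints; since RANSAC voting is not
differentiable, training backpropagates through the dense seg + vector
losses and the keypoint loss serves as a monitored metric. Loss weighting is
1:1.

The trainable stand-in is a deliberately small (≈ 7.7k parameter) pure-NumPy
CNN with hand-written backprop and Adam (β₁ = 0.9, β₂ = 0.999): four
branches at scales 1, ½, ¼, ⅛ whose outputs are bilinearly upsampled to full
resolution, concatenated and fused by two pointwise 1×1 convolutions before
the two heads — the same multi-resolution fusion contract as a full-scale
high-resolution backbone, testable without GPU training. Two normalised
coordinate channels are appended to the input so the vector branch can
express position-dependent fields. The learning rate starts at 1e-3 and
halves every 20 epochs. Training is deterministic given the seed up to
floating-point reduction order. At reference scale (300 frames of 96×96,
20 epochs, single core) training takes about six minutes, halves the
combined validation loss comfortably, and the full predict → vote → PnP path
on held-out noise-free frames lands a median ADD well below the instrument
diameter — a smoke-level bar: the toy network shows the pipeline learns and
closes end to end, not that it reaches the accuracy a full-scale trained
backbone would.

## Metrics

ADD is the mean distance between surface points under the two poses;
rotation error is the geodesic angle arccos((trace(R_rel) − 1)/2) in
degrees (the standard choice; the metric is not defined elsewhere);
translation error is the norm of the translation difference. The
accuracy-threshold curve uses strict `<` and a 0–10 mm grid in 0.1 mm steps
by default; the scalar AUC is the trapezoidal integral normalised by the
grid span. IoU of two empty masks is defined as 1.

## Known limitations

* Single instrument per frame; no data association for multiple tools.
* No temporal filtering or kinematic fusion across frames.
* The rasteriser's half-pixel silhouette dilation biases mask areas slightly
  high; irrelevant to voting, visible in area-level comparisons.
* EPnP minimal samples can converge to a mirror local minimum; RANSAC's
  consensus scoring discards these, but pathological 4-point configurations
  waste iterations.
* The toy network's receptive field is far too small for real imagery; it
  exists to exercise the losses, fusion contract and end-to-end path.
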