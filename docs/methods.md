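# Methods

This note documents the models behind `otoar`, the synthetic bench it is
validated on, the numerical choices, and what the validation does and does
not demonstrate.

## Scene model and conventions

Pixel coordinates are 0-based, origin top-left, x rightward, y downward.
Camera-frame 3D coordinates are in millimetres with +z toward the scene.
The camera is an ideal pinhole (focal length in pixels, principal point);
lens distortion is not modelled — the bench cameras are long-focal-length
microscope adapters for which distortion is negligible relative to the
sub-millimetre error budget, and no distortion coefficients are available.

The tympanic membrane is treated as a strict plane, so any two views of it
are related by a 3×3 homography. Homographies are stored normalized
((3,3) entry = 1, or unit Frobenius norm in the degenerate case); the
chained update is a left multiplication `H ← H_T H` — the inter-frame
transform maps the previous frame to the current one and is applied to the
cumulative reference-to-previous map. Surrounding the membrane disc the
simulator places an ear-canal wall plane 1.5 mm nearer the camera, which
produces genuine parallax for off-membrane features and is what the
elliptical planarity mask exists to exclude.

## Registration

CT-side fiducials: percentile contrast stretch → Otsu threshold →
connected-component analysis → area-band and circularity pruning →
intensity-weighted centroid. The area band defaults to [10, 1200] px²,
sized so a 0.5 mm-diameter marker is accepted at scales from ~40 to
~60 px/mm (a 0.5 mm disc at 60 px/mm covers ≈ 700 px²).

Video-side clicks are refined to the centroid of the dark blob inside a
window around the click (ties broken toward the click). The window must
exceed the blob: the library default is 11 px for small real-world
markers, and the simulator driver uses 45 px because the rendered 0.5 mm
discs span 30 px at the default scale. A window smaller than the blob
makes refinement a no-op, which is visible as registration residuals
inflating to the click noise.

RANSAC homography: inlier threshold 3 px, confidence 0.995, ≤ 2000
iterations, explicit seed; minimal samples with near-collinear triples are
rejected and the consensus model is refit by normalized DLT on all
inliers. Registration error is the fiducial RMS residual divided by the
image scale (px/mm); the scale is an explicit input (the simulator knows
it exactly; on real data it can be estimated from known inter-fiducial
distances via `px_per_mm_from_distances`).

The planarity mask is a direct least-squares ellipse through ≥ 5 video
fiducials, dilated 10 %; with exactly 4 points a circumscribed circle is
used. Under a homography the mask is transported exactly as a conic
(C → H⁻ᵀ C H⁻¹) rather than by refitting sampled boundary points — the
algebraic fit can reject exactly-conic inputs.

## Motion tracking

The detector is pluggable; the default is ORB (FAST corners over a
3-level pyramid, steered BRIEF descriptors) with a 0.05 FAST threshold and
a 400-keypoint budget concentrated on the mask's bounding box. ORB plays
the role a patented speeded-up blob detector played in the original
system: scale/rotation-repeatable keypoints with matchable descriptors.
Matching is mutual-best nearest neighbour with a 0.75 ratio test; exact
zero-distance descriptor ties, which a ratio cannot score, are treated as
maximally ambiguous and dropped.

Corner detectors localize to roughly 0.1 px. Chained over 1440 frames that
random-walks (and, worse, any systematic component integrates) into
visible drift, so the RANSAC inter-frame homography is refined densely:
the previous frame is warped by the current estimate, residual
translations of a 4×4 lattice of 64 px patches inside the mask are
measured by Hann-weighted symmetric-gradient Lucas–Kanade steps, and the
homography is refit on the corrected lattice; warp–measure–refit runs
three times so the linearization converges. (Phase correlation was
rejected for this role: on smooth, noisy microscope texture its shift
estimates shrink toward zero by tens of percent, which leaves a
systematic per-frame bias of ~0.002 px — ≈ 3 px after 1440 frames.) The
refined chain shows a per-frame error of ~0.006 px and a bias below
10⁻⁴ px/frame on the simulator, i.e. well under 0.5 px at two minutes.
Patches disagreeing with the consensus correction by > 0.75 px (occluding
instrument, ink) are excluded.

Tracking failure is declared at < 8 inliers or a median residual > 5 px;
the chain then freezes and the caller re-registers. Losses within one
second are counted as a single episode, because the first frames after an
abrupt jerk are motion-blurred and re-acquisition may need a frame or two.
Chaining is pure (no keyframe correction), so the measured drift
characterizes the chain itself.

## Instrument localization

Background subtraction runs in RGB with per-channel gain normalization:
illumination changes rescale channels, whereas the instrument changes
chroma, so a grey shaft crossing equally-bright membrane is still
detected. The reference (first) frame is warped with edge extrapolation so
the thin border strip remains comparable and a tool entering at the frame
edge is not clipped. The region is opened morphologically and blobs
< 64 px are pruned; presence requires ≥ 0.5 % of the frame area. All
surviving components are kept — the shaft may split where its luminance
matches the scene. The first frame is assumed instrument-free; a violation
is detectable only as persistent presence.

Colour markers are segmented by circular hue bands (tolerance 0.09) with
saturation > 0.45 and value > 0.5 — the value floor separates bright
painted markers from dark ink pools of similar hue — and localized by
saturation-weighted centroids. Independent per-marker constant-velocity
Kalman filters (white-acceleration σ_a = 1500 px/s², measurement
σ = 0.5 px, Joseph-form updates) bridge dropouts and smooth the centroids.
σ_a is deliberately large: with the microscope itself oscillating, apparent
marker accelerations reach hundreds of px/s², and a sluggish filter lags by
several pixels, which is far worse than the sub-pixel centroid noise it
would remove.

The 2D tip extrapolation from collinear cross-ratios is exact under any
affine (ratio-preserving) camera; under perspective its deviation from
the projected metric tip grows with the tool's pitch out of the image
plane (0 at fronto-parallel, ≈ 0.5 px at 3°, ≈ 1.4 px at 9° on the bench
camera analog). The solver logs this discrepancy per pose; the metric tip
is always taken from the 3D fit.

The metric solver first computes the closed-form solution of the
collinearity system — with unit rays r_b, r_c, r_d and t = BC/BD, the
depths are the nullspace of λ_c r_c = (1−t) λ_b r_b + t λ_d r_d, scaled so
|B − D| = BD, signs chosen positive — and then refines it by a
reprojection least-squares fit of the rigid collinear triple (5 free
parameters: B and the tool direction). The closed form is exact on
noiseless input but ill-conditioned under noise: it absorbs all of marker
c's along-line measurement error into a depth-tilt mode. The refit is the
actual estimator; the closed form is its initializer.

### Depth accuracy is estimation-limited

A Cramér–Rao analysis of the collinear triple at the bench configuration
(f = 5000 px, 115 mm working distance, 3 mm spacings, 0.25 px centroid
noise) shows lateral (X/Y) tip floors of ~0.02 mm but a depth floor that
depends sharply on the tool's pitch out of the image plane: ≈ 1.1 mm at
0° (sign degeneracy), ≈ 0.23 mm at the ~5° sweet spot, 2.5 mm at 20° and
> 7 mm at 45°. No estimator can beat these numbers at that focal length —
depth accuracy is limited by information, not implementation. The pose
Monte-Carlo therefore confines tool pitch to 0–10°, the band the
microscope's shallow depth of field enforces anyway (a 6 mm marker
segment must stay within roughly ±1 mm of the focal plane to keep all
three colour blobs extractable), with azimuth free and positions spread
across the manipulator workspace. Even so, the measured mean 3D tip error
(≈ 0.6 mm, dominated by Z) sits above the sub-0.35 mm figures achievable
only at severalfold longer effective focal lengths — a zoomed surgical
microscope easily exceeds 5000 px — or with temporal averaging, which the
end-to-end procedure run does get (and where the target error drops to
≈ 0.05 mm). The anisotropy itself — depth error far exceeding lateral
error — is a robust property of the geometry and holds in every
configuration tested.

## The synthetic bench

The simulator renders a layered membrane texture (large-scale sheen, soft
blob field, fine speckle tuned to feed corner detectors), grey 0.5 mm
fiducial discs drawn into the membrane plane on a peripheral ring (no
three collinear, centroid within 5 % of the membrane radius of the
centre), a darker canal-wall plane outside the membrane disc, and an
instrument as an anti-aliased shaft capsule with three colour discs at the
modelled 3D positions. Degradations: additive Gaussian noise (σ = 2 grey
levels), instrument-layer defocus (σ = 1 px), optional sinusoidal
illumination gain, and semi-transparent dark-red ink blobs appearing at
scheduled times. All edges are soft (1 px coverage ramps) so centroids
are meaningful at sub-pixel precision. Everything is deterministic given
the scene seed; frames render lazily so two-minute sequences do not hold
a gigabyte of pixels.

Microscope motion presets use incommensurate per-axis sinusoids whose peak
translational speed stays inside the declared class (slow < 5 mm/s, rapid
5–10 mm/s), with in-plane rotation (4–8° amplitude) and a small pitch for
perspective variation. The jerk preset adds one instantaneous 1.4 mm pose
jump whose frame is rendered as an integrated (motion-blurred) exposure —
without the blur a global feature matcher shrugs off a pure jump, which is
not what happens on a real camera. The guided-procedure preset drives the
tool tip (at ~7° pitch, for the depth-of-field reason above) to three
fixed targets at 1.2–3.2 mm behind the membrane plane — stand-ins for the
umbo, the incus tip and the round-window niche — with one-second dwells.

Problem sizes: tracking scenes render at 384×384 px (60 px/mm scale,
2.5 mm membrane radius) and the procedure at 640×512 px (43.5 px/mm, the
f = 5000 px camera), sizes at which the full two-minute protocol and the
complete test suite run on a laptop-class single core in minutes. The
geometry is a scaled-down membrane; all accuracies are reported in mm at
the simulated scale.

What passing on this bench does **not** show: robustness to non-rigid
membrane deformation, specular highlights, real multi-modal CT-to-video
appearance gaps (the CT analog is a tone-remapped sibling of the video
texture, so automatic CT marker extraction is easier than on true virtual
endoscopy), motion blur during continuous fast motion, or rolling-shutter
effects. Drift numbers in particular should be read as a floor: real
texture is less ideal than the simulator's.

## Evaluation protocol

"Real" marker positions are recovered by normalized cross-correlation of
the landmark neighbourhood over a ±20 px translation window and a discrete
scale {0.9, 1.0, 1.1} × rotation (−10°…10°, 2° steps) grid, with quadratic
sub-pixel peak interpolation; scores < 0.6 mark a point untrackable
(ink-covered). Drift is the mean distance between chain-predicted and
template-matched positions at 30 s intervals, minus the interval-0 offset,
in mm. Because the simulator knows the truth, a truth-based drift series
is reported alongside, which makes the template matcher's own error
visible (typically ~0.2 px). Displacement trials apply rigid 2/4/6 mm
moves per optical axis (50 samples each) and tabulate mean ± sd per axis
and magnitude; target localization reports per-target Euclidean tip
errors averaged over the one-second contact dwell.

## Known limitations

* Tool roll about its own axis is unobservable with collinear markers.
* Single-view depth is estimation-limited (see above); clinical-accuracy
  depth requires the real microscope's longer effective focal length
  and/or temporal averaging.
* The entry-point search assumes the tool crosses the frame border.
* Re-registration in the headless pipeline reuses simulated clicks; on
  real systems it is an operator action.
* The simulator's membrane is strictly planar; mild real-world curvature
  appears in the registration residual, not as a modelled effect.
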