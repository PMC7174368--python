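# otoar

Video-based augmented-reality guidance for transtympanic (keyhole) middle-ear
procedures. A preoperative CT virtual-endoscopy render of the middle-ear
cleft is registered onto live microscope video of the intact tympanic
membrane and kept registered while the microscope moves, and a
micro-instrument working behind the membrane is localized in metric 3D from
three collinear colour markers painted on its shaft — all from plain video,
with no optical or electromagnetic tracker.

The package is aimed at surgical-navigation researchers: it contains the
full guidance pipeline, a seeded synthetic-scene simulator that stands in
for the physical temporal-bone phantom bench (so every stage is testable
without hardware), and the bench evaluation protocol.

## The method

**Initial registration.** Fiducial markers glued around the membrane
periphery appear as bright protrusions on the CT render and grey dots on
video. CT-side centres are extracted automatically (contrast stretch, Otsu
threshold, contour analysis, blob pruning); video-side points are clicked by
the operator and refined to the local blob centroid within a small window.
A RANSAC homography maps CT points *P′ᵢ* to video points *Pᵢ*,

> *Pᵢ ≈ H_R P′ᵢ*

and the fiducial RMS residual of *H_R* is the registration error. An
ellipse fitted around the video fiducials masks the (planar) membrane.

**Microscope motion tracking.** Scale/rotation-invariant keypoints inside
the mask are matched between consecutive frames (mutual-best, ratio-test
ambiguity rejection), an inter-frame homography *H_T* is fit by RANSAC and
refined to sub-pixel precision by dense patchwise alignment, and the
cumulative map is chained:

> *H ← H_T H*

so the registered CT image can be warped onto every new frame and blended,
*I_AR = β I_M + (1 − β) I_CT*. Too few inliers or a large median residual
(e.g. after an abrupt jerk) flags a tracking loss and triggers
re-registration.

**Instrument localization.** The instrument region is found by background
subtraction against the *H*-warped first frame; its entry point is the
largest region run on the frame border. Colour markers *b, c, d* are
segmented in HSV, refined by per-marker constant-velocity Kalman filters,
and labeled by distance to the entry point (*D* nearest entry, *B* nearest
the hidden tip *A*). The 2D tip is extrapolated from the collinear
cross-ratios,

> *a = ⅓ [ b + c + d + (AB/CD)(c−d) + (AC/BD)(b−d) + (AD/BC)(b−c) ]*

and the metric 3D pose follows from fitting the known collinear geometry
(spacings AB, BC, CD in mm) onto the projection rays *Ob, Oc, Od* — a
collinear special case of three-point perspective, solved in closed form
and polished by a reprojection least-squares fit. The tip position is
reported in mm in the camera frame.

## Worked example

```python
from otoar import SceneSpec, simulate_dataset
from otoar.pipeline import PipelineConfig, evaluate_tracking_drift

ds = simulate_dataset(SceneSpec.preset_2min(7))   # 2 min, 12 fps, 1440 frames
series, truth_series, log, reg = evaluate_tracking_drift(ds, PipelineConfig(seed=7))
print(f"registration RMSE: {reg.rmse_mm:.4f} mm")
for t, v in series:
    print(f"drift at {t:4.0f} s: {v:.4f} mm")
```

prints (machine-dependent runtime aside):

```
registration RMSE: 0.0004 mm
drift at   30 s: 0.0020 mm
drift at   60 s: 0.0020 mm
drift at   90 s: 0.0038 mm
drift at  120 s: 0.0044 mm
```

i.e. the fiducial registration residual is sub-micron at the simulated
60 px/mm scale (clean synthetic blobs make this an upper bound on
algorithmic error, not a clinical claim) and the chained homography
accumulates well under a hundredth of a millimetre of drift over two
minutes of rapid (5–10 mm/s) simulated microscope motion. (Values come from a run of the snippet above;
your exact numbers depend only on the seeds.)

The guided procedure works the same way:

```python
from otoar.pipeline import evaluate_procedure
summary, result = evaluate_procedure(simulate_dataset(SceneSpec.preset_procedure(11)),
                                     PipelineConfig(seed=11))
print(summary["distances_mm"], summary["mean_mm"])
```

A command-line interface mirrors the library: `otoar simulate`,
`otoar register`, `otoar run`, `otoar evaluate` (see `otoar --help`).

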