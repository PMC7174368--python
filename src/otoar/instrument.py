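"""Micro-instrument detection and metric 3D localization.

The surgical needle carries three collinear colour markers B, C, D with
known physical spacings; the tip A lies on the same line beyond B. Working
behind the intact membrane image, the pipeline is:

1. background subtraction against the homography-warped first frame to
   find the instrument region (the first frame is assumed instrument-free);
2. entry-point search on the frame boundary (the tool always protrudes
   from an image edge);
3. per-colour thresholding + blob centroiding for the marker centres,
   refined by constant-velocity Kalman filters;
4. labeling by distance to the entry point (D nearest the entry, B nearest
   the tip);
5. 2D tip extrapolation from the collinear cross-ratios, and
6. metric 3D recovery by fitting the known collinear geometry onto the
   projection rays O->b, O->c, O->d (a collinear special case of
   three-point perspective): depths are the nullspace of a 3x3 system
   expressing that the three back-projected points are collinear with the
   known internal ratio, scaled so the outer marker distance is metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.color import rgb2gray, rgb2hsv
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import disk, opening, remove_small_objects
from skimage.transform import ProjectiveTransform, warp

from .exceptions import (
    AmbiguousLabelingError,
    DegenerateGeometryError,
    InstrumentModelError,
    OtoARError,
)
from .geometry import CameraIntrinsics, Homography, project_point
from .kalman import MarkerFilterBank

__all__ = [
    "InstrumentModel",
    "MarkerObservation",
    "InstrumentPose3D",
    "detect_instrument_region",
    "find_entry_point",
    "detect_color_markers",
    "assign_labels",
    "kalman_step",
    "estimate_tip_2d",
    "solve_collinear_pose",
    "measure_displacement",
]

_DEFAULT_COLORS = ((0.85, 0.18, 0.18), (0.15, 0.72, 0.25), (0.2, 0.32, 0.9))


@dataclass(frozen=True)
class InstrumentModel:
    """Physical collinear tool geometry (mm) and marker reference colours.

    Distances are between tip A and markers B, C, D ordered outward from
    the tip, so consistency requires AC = AB + BC, AD = AC + CD and
    BD = BC + CD.
    """

    ab: float
    ac: float
    ad: float
    bc: float
    bd: float
    cd: float
    marker_colors: tuple[tuple[float, float, float], ...] = _DEFAULT_COLORS

    def __post_init__(self) -> None:
        for name in ("ab", "ac", "ad", "bc", "bd", "cd"):
            if getattr(self, name) <= 0:
                raise InstrumentModelError(f"distance {name.upper()} must be positive")
        checks = (
            ("AC = AB + BC", self.ac, self.ab + self.bc),
            ("AD = AB + BC + CD", self.ad, self.ab + self.bc + self.cd),
            ("BD = BC + CD", self.bd, self.bc + self.cd),
        )
        for label_, got, want in checks:
            if abs(got - want) > 1e-9:
                raise InstrumentModelError(
                    f"collinearity violated: {label_} ({got} vs {want})"
                )
        if len(self.marker_colors) != 3:
            raise InstrumentModelError("exactly three marker colours required")

    @classmethod
    def from_spacings(cls, ab: float, bc: float, cd: float,
                      marker_colors=_DEFAULT_COLORS) -> "InstrumentModel":
        return cls(ab=ab, ac=ab + bc, ad=ab + bc + cd,
                   bc=bc, bd=bc + cd, cd=cd, marker_colors=tuple(marker_colors))

    @classmethod
    def from_yaml(cls, path) -> "InstrumentModel":
        import yaml

        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        colors = tuple(tuple(float(v) for v in c) for c in cfg.get(
            "marker_colors", _DEFAULT_COLORS))
        d = cfg["distances_mm"]
        return cls(ab=float(d["ab"]), ac=float(d["ac"]), ad=float(d["ad"]),
                   bc=float(d["bc"]), bd=float(d["bd"]), cd=float(d["cd"]),
                   marker_colors=colors)


@dataclass
class MarkerObservation:
    """Labeled marker centres for one frame.

    D is the marker nearest the tool entry point, B the one nearest the
    (possibly hidden) tip A.
    """

    b_px: np.ndarray
    c_px: np.ndarray
    d_px: np.ndarray
    time_s: float = 0.0
    confidence: tuple[float, float, float] = (1.0, 1.0, 1.0)


@dataclass
class InstrumentPose3D:
    """Metric instrument pose in the camera frame (mm)."""

    tip_mm: np.ndarray  # A
    markers_mm: dict[str, np.ndarray]  # B, C, D
    tip_px: np.ndarray  # projection of A
    eq_tip_px: np.ndarray | None = None  # 2D cross-ratio extrapolation
    tip_px_discrepancy: float | None = None


# ---------------------------------------------------------------------- #
# Detection
# ---------------------------------------------------------------------- #


def detect_instrument_region(
    frame: np.ndarray,
    first_frame: np.ndarray,
    H_cum: Homography,
    area_threshold_frac: float = 0.005,
    diff_threshold: float = 0.12,
) -> tuple[bool, np.ndarray]:
    """Background-subtraction instrument detection.

    The (instrument-free) first frame is warped by the cumulative
    homography into the current view and subtracted; both images are gain
    normalized first so pure illumination changes do not masquerade as an
    instrument. Small residual blobs (homography discrepancy, noise) are
    pruned morphologically; the instrument is declared present only when
    the remaining area reaches ``area_threshold_frac`` of the frame.
    """
    cur = _to_float_rgb(frame)
    ref = _to_float_rgb(first_frame)
    h, w = cur.shape[:2]
    tform = ProjectiveTransform(np.linalg.inv(H_cum.matrix))
    # edge extrapolation keeps the thin border strip comparable, so a tool
    # entering at the frame edge is not clipped off the region
    warped = warp(ref, tform, output_shape=(h, w), order=1, mode="edge")
    # per-channel gain normalization: illumination changes scale channels,
    # the instrument changes chroma
    scale = np.array([
        np.median(cur[:, :, k]) / max(np.median(warped[:, :, k]), 1e-6)
        for k in range(cur.shape[2])
    ])
    diff = np.abs(cur - warped * scale[None, None, :]).max(axis=2)
    mask = diff > diff_threshold
    mask = opening(mask, disk(2))
    # prune small residual blobs (homography discrepancy, noise); the tool
    # may split into several runs where its luminance matches the scene
    mask = remove_small_objects(mask, max_size=63)
    present = mask.sum() >= area_threshold_frac * h * w
    return bool(present), mask if present else np.zeros((h, w), dtype=bool)


def find_entry_point(region_mask: np.ndarray, border_depth: int = 6) -> np.ndarray:
    """Tool entry point: centroid of the largest border run of the region.

    The border pixels are walked in perimeter order; the longest contiguous
    (circularly wrapped) run of region pixels is the tool cross-section at
    the frame edge. A region pixel within ``border_depth`` of the border
    counts as touching it (background subtraction is blind in the thin
    margin the warped reference does not cover).
    """
    mask = np.asarray(region_mask, dtype=bool)
    h, w = mask.shape
    k = max(1, int(border_depth))
    coords = []
    coords += [(x, 0) for x in range(w)]  # top, left->right
    coords += [(w - 1, y) for y in range(1, h)]  # right, down
    coords += [(x, h - 1) for x in range(w - 2, -1, -1)]  # bottom, right->left
    coords += [(0, y) for y in range(h - 2, 0, -1)]  # left, up

    def _touch(x: int, y: int) -> bool:
        x0, x1 = max(x - 0, 0), min(x + 1, w)
        if x < k:
            x0, x1 = 0, k
        elif x >= w - k:
            x0, x1 = w - k, w
        y0, y1 = y, y + 1
        if y < k:
            y0, y1 = 0, k
        elif y >= h - k:
            y0, y1 = h - k, h
        return bool(mask[y0:y1, x0:x1].any())

    on = np.array([_touch(x, y) for x, y in coords])
    if not on.any():
        raise OtoARError("instrument region does not touch the frame boundary")
    # longest circular run of True
    n = len(on)
    ext = np.concatenate([on, on])
    best_len, best_start, run, start = 0, 0, 0, 0
    for i in range(2 * n):
        if ext[i]:
            if run == 0:
                start = i
            run += 1
            if run > best_len and start < n:
                best_len, best_start = run, start
        else:
            run = 0
    best_len = min(best_len, n)
    pts = np.array([coords[(best_start + k) % n] for k in range(best_len)], dtype=float)
    return pts.mean(axis=0)


def detect_color_markers(
    frame: np.ndarray,
    region_mask: np.ndarray,
    colors=_DEFAULT_COLORS,
    hue_tol: float = 0.09,
    min_saturation: float = 0.45,
    min_value: float = 0.5,
    min_area_px: int = 6,
    region_dilate_px: int = 6,
) -> tuple[list[np.ndarray], list[int]]:
    """Colour-thresholded marker candidates inside the instrument region.

    For each configured reference colour the frame is thresholded in
    hue-saturation-value space (circular hue band around the reference
    hue), blobs are pruned by area, and the best blob per colour keeps its
    saturation-weighted centroid. Returns (candidate centres, colour
    indices); fewer than three entries signals a partial observation that
    downstream Kalman prediction must fill.
    """
    img = np.asarray(frame, dtype=float)
    if img.max() > 1.5:
        img = img / 255.0
    hsv = rgb2hsv(img)
    region = np.asarray(region_mask, dtype=bool)
    if region_dilate_px > 0:
        region = ndimage.binary_dilation(region, disk(region_dilate_px))
    centres: list[np.ndarray] = []
    found_colors: list[int] = []
    for ci, ref in enumerate(colors):
        ref_hue = rgb2hsv(np.asarray(ref, dtype=float).reshape(1, 1, 3))[0, 0, 0]
        dh = np.abs(hsv[:, :, 0] - ref_hue)
        dh = np.minimum(dh, 1.0 - dh)  # circular hue distance
        # value floor separates bright painted markers from dark ink pools
        cand = (dh < hue_tol) & (hsv[:, :, 1] > min_saturation) \
            & (hsv[:, :, 2] > min_value) & region
        lab = cc_label(cand)
        best = None
        for prop in regionprops(lab):
            if prop.area < min_area_px:
                continue
            if best is None or prop.area > best.area:
                best = prop
        if best is None:
            continue
        blob = lab == best.label
        wgt = hsv[:, :, 1] * blob
        total = wgt.sum()
        ys, xs = np.nonzero(blob)
        cy = (ys * wgt[ys, xs]).sum() / total
        cx = (xs * wgt[ys, xs]).sum() / total
        centres.append(np.array([cx, cy]))
        found_colors.append(ci)
    return centres, found_colors


def assign_labels(candidates, entry_point, time_s: float = 0.0,
                  tie_tol_px: float = 1e-6) -> MarkerObservation:
    """Order three candidate centres by distance to the entry point:
    nearest -> d, middle -> c, farthest -> b."""
    pts = [np.asarray(p, dtype=float) for p in candidates]
    if len(pts) != 3:
        raise OtoARError(f"need exactly 3 candidates to label, got {len(pts)}")
    entry = np.asarray(entry_point, dtype=float)
    dists = np.array([np.linalg.norm(p - entry) for p in pts])
    order = np.argsort(dists)
    sorted_d = dists[order]
    if np.any(np.diff(sorted_d) <= tie_tol_px):
        raise AmbiguousLabelingError(
            f"marker distances to entry point tie within {tie_tol_px} px: {sorted_d}"
        )
    return MarkerObservation(
        b_px=pts[order[2]], c_px=pts[order[1]], d_px=pts[order[0]], time_s=time_s
    )


def kalman_step(bank: MarkerFilterBank, observations, dt: float):
    """Advance the per-marker filter bank one frame.

    ``observations`` maps colour index -> centre or None (missing marker);
    returns the refined (posterior, or pure prediction when unobserved)
    positions keyed the same way.
    """
    return bank.step(observations, dt)


# ---------------------------------------------------------------------- #
# Tip estimation
# ---------------------------------------------------------------------- #


def estimate_tip_2d(obs: MarkerObservation, model: InstrumentModel) -> np.ndarray:
    """2D tip extrapolation from the three collinear marker projections.

    a = (1/3) [ b + c + d + (AB/CD)(c-d) + (AC/BD)(b-d) + (AD/BC)(b-c) ]

    Exact under any ratio-preserving (affine) camera; under perspective at
    the working geometry (depth much larger than the tool span) the
    residual versus the metric solver's projected tip is far below a pixel.
    """
    for name, val in (("CD", model.cd), ("BD", model.bd), ("BC", model.bc)):
        if val == 0:
            raise InstrumentModelError(f"distance {name} must be nonzero")
    b, c, d = (np.asarray(v, dtype=float) for v in (obs.b_px, obs.c_px, obs.d_px))
    return (
        b + c + d
        + (model.ab / model.cd) * (c - d)
        + (model.ac / model.bd) * (b - d)
        + (model.ad / model.bc) * (b - c)
    ) / 3.0


def _nullspace_depths(intr: CameraIntrinsics, b, c, d, model: InstrumentModel):
    """Closed-form depths from the homogeneous collinearity system.

    With unit rays r_b, r_c, r_d and internal ratio t = BC/BD,
    collinearity forces ``lambda_c r_c = (1-t) lambda_b r_b +
    t lambda_d r_d``; the 3x3 system's one-dimensional nullspace gives the
    depths up to scale, fixed by |B - D| = BD with the sign chosen for
    positive depths. Exact on noiseless input, but it maps all of marker
    c's along-line measurement noise into a depth-tilt mode, so it serves
    as the initializer for the metric least-squares fit.
    """
    rays = intr.rays(np.stack([b, c, d]))
    r_b, r_c, r_d = rays
    t = model.bc / model.bd
    M = np.column_stack([(1.0 - t) * r_b, -r_c, t * r_d])
    _, s, vt = np.linalg.svd(M)
    if s[1] < 1e-9 * s[0]:
        raise DegenerateGeometryError(
            "nullspace dimension > 1: tool line passes through the camera centre"
        )
    lam = vt[-1]
    if np.all(lam < 0):
        lam = -lam
    if np.any(lam <= 0):
        raise DegenerateGeometryError("no positive-depth solution for the markers")
    B, C, D = lam[0] * r_b, lam[1] * r_c, lam[2] * r_d
    scale = model.bd / np.linalg.norm(B - D)
    return B * scale, C * scale, D * scale


def solve_collinear_pose(
    intr: CameraIntrinsics, obs: MarkerObservation, model: InstrumentModel
) -> InstrumentPose3D:
    """Metric 3D marker/tip positions from one view.

    The known rigid collinear geometry (B at the origin of the tool axis,
    C and D at the modelled spacings along a unit direction) is fitted
    onto the projection rays O->b, O->c, O->d by minimizing the image
    reprojection error over the 5 free parameters (marker B position and
    tool direction). The closed-form nullspace solution of the
    collinearity system provides the initial iterate and is already exact
    for noiseless input. The tip is A = B + (AB/BD)(B - D).
    """
    b, c, d = (np.asarray(v, dtype=float) for v in (obs.b_px, obs.c_px, obs.d_px))
    if np.linalg.norm(b - c) < 1e-9 or np.linalg.norm(c - d) < 1e-9 or np.linalg.norm(b - d) < 1e-9:
        raise DegenerateGeometryError("marker projections coincide")
    B, C, D = _nullspace_depths(intr, b, c, d, model)

    # metric least-squares refinement: fit the rigid triple to the rays
    v0 = (D - B) / np.linalg.norm(D - B)
    e1 = np.cross(v0, [0.0, 0.0, 1.0])
    if np.linalg.norm(e1) < 1e-8:
        e1 = np.cross(v0, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(v0, e1)
    obs_px = np.concatenate([b, c, d])

    def _markers(params):
        px, py, pz, a1, a2 = params
        v = v0 + a1 * e1 + a2 * e2
        v = v / np.linalg.norm(v)
        Bp = np.array([px, py, pz])
        return Bp, Bp + model.bc * v, Bp + model.bd * v

    def _residual(params):
        Bp, Cp, Dp = _markers(params)
        pts = np.stack([Bp, Cp, Dp])
        if np.any(pts[:, 2] <= 0):
            return np.full(6, 1e3)
        return np.concatenate([project_point(intr, p) for p in pts]) - obs_px

    from scipy.optimize import least_squares

    x0 = np.array([B[0], B[1], B[2], 0.0, 0.0])
    sol = least_squares(_residual, x0, method="lm", xtol=1e-12, ftol=1e-12)
    B, C, D = _markers(sol.x)
    A = B + (model.ab / model.bd) * (B - D)
    if A[2] <= 0:
        raise DegenerateGeometryError("recovered tip has non-positive depth")
    tip_px = project_point(intr, A)
    eq_tip = estimate_tip_2d(obs, model)
    return InstrumentPose3D(
        tip_mm=A,
        markers_mm={"b": B, "c": C, "d": D},
        tip_px=tip_px,
        eq_tip_px=eq_tip,
        tip_px_discrepancy=float(np.linalg.norm(tip_px - eq_tip)),
    )


def measure_displacement(pose_t1: InstrumentPose3D, pose_t0: InstrumentPose3D) -> np.ndarray:
    """Component-wise tip displacement (mm, camera frame) between poses."""
    return np.asarray(pose_t1.tip_mm, dtype=float) - np.asarray(pose_t0.tip_mm, dtype=float)


def _to_gray(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim == 3:
        arr = rgb2gray(arr)
        return arr.astype(float)
    arr = arr.astype(float)
    return arr / 255.0 if arr.max() > 1.5 else arr


def _to_float_rgb(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img, dtype=float)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    return arr / 255.0 if arr.max() > 1.5 else arr
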