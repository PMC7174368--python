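"""CT-to-video registration.

Fiducials are extracted automatically from the CT virtual-endoscopy render
(where they appear as bright protrusions); their video-side counterparts
are clicked by the user and refined to the local blob centroid inside a
small window. A RANSAC homography H_R then maps CT pixels onto the video
frame; the fiducial RMS residual is the registration error. An ellipse
fitted around the video fiducials becomes the planarity mask used by the
motion tracker, and a blend operator mixes the warped CT image over the
live video: I_AR = beta * I_M + (1 - beta) * I_CT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import exposure
from skimage.filters import threshold_otsu
from skimage.measure import EllipseModel, label as cc_label, regionprops
from skimage.transform import ProjectiveTransform, warp

from .exceptions import ConfigError, EstimationError, RegistrationError
from .geometry import Homography, estimate_homography_ransac

__all__ = [
    "FiducialMarker",
    "EllipseMask",
    "BlendConfig",
    "RegistrationResult",
    "extract_ct_markers",
    "refine_and_register",
    "fit_ellipse_mask",
    "blend",
    "registration_error_mm",
    "warp_to_frame",
    "px_per_mm_from_distances",
]


@dataclass(frozen=True)
class FiducialMarker:
    """A detected blob-like fiducial."""

    center_px: tuple[float, float]
    area_px2: float
    source: str  # "ct_render" | "video"


@dataclass(frozen=True)
class BlendConfig:
    beta: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta <= 1.0:
            raise ConfigError(f"blend factor beta must be in [0, 1], got {self.beta}")


@dataclass(frozen=True)
class EllipseMask:
    """Elliptical planarity mask over the membrane."""

    center_px: tuple[float, float]
    semi_axes_px: tuple[float, float]
    angle_rad: float

    def __post_init__(self) -> None:
        if min(self.semi_axes_px) <= 0:
            raise ConfigError("ellipse semi-axes must be positive")

    def contains(self, points_px: np.ndarray, margin: float = 0.0) -> np.ndarray:
        """Boolean test (vectorized) for points inside the ellipse."""
        p = np.atleast_2d(np.asarray(points_px, dtype=float))
        ca, sa = np.cos(self.angle_rad), np.sin(self.angle_rad)
        dx = p[:, 0] - self.center_px[0]
        dy = p[:, 1] - self.center_px[1]
        u = (ca * dx + sa * dy) / (self.semi_axes_px[0] + margin)
        v = (-sa * dx + ca * dy) / (self.semi_axes_px[1] + margin)
        out = u * u + v * v <= 1.0
        return out if np.asarray(points_px).ndim > 1 else bool(out[0])

    def boundary_points(self, n: int = 64) -> np.ndarray:
        th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        a, b = self.semi_axes_px
        ca, sa = np.cos(self.angle_rad), np.sin(self.angle_rad)
        x = a * np.cos(th)
        y = b * np.sin(th)
        return np.column_stack(
            [
                self.center_px[0] + ca * x - sa * y,
                self.center_px[1] + sa * x + ca * y,
            ]
        )

    def conic_matrix(self) -> np.ndarray:
        """Homogeneous conic matrix C with x^T C x = 0 on the boundary."""
        ca, sa = np.cos(self.angle_rad), np.sin(self.angle_rad)
        R = np.array([[ca, -sa], [sa, ca]])
        A = R @ np.diag([1.0 / self.semi_axes_px[0] ** 2,
                         1.0 / self.semi_axes_px[1] ** 2]) @ R.T
        c = np.asarray(self.center_px, dtype=float)
        C = np.zeros((3, 3))
        C[:2, :2] = A
        C[:2, 2] = -A @ c
        C[2, :2] = -A @ c
        C[2, 2] = c @ A @ c - 1.0
        return C

    def transform(self, H: Homography) -> "EllipseMask":
        """Exact image of the ellipse under a homography.

        A conic C maps to H^-T C H^-1; the result is converted back to
        center/axes/angle. Raises when the image is no longer an ellipse
        (the plane crossed the camera's principal plane).
        """
        Hinv = np.linalg.inv(H.matrix)
        C = Hinv.T @ self.conic_matrix() @ Hinv
        C = 0.5 * (C + C.T)
        A = C[:2, :2]
        if np.linalg.det(A) <= 0:
            raise EstimationError("ellipse mask degenerated under homography")
        if np.trace(A) < 0:
            C, A = -C, -A
        center = np.linalg.solve(A, -C[:2, 2])
        k = center @ A @ center - C[2, 2]
        if k <= 0:
            raise EstimationError("ellipse mask degenerated under homography")
        w_eig, v_eig = np.linalg.eigh(A / k)
        if np.any(w_eig <= 0):
            raise EstimationError("ellipse mask degenerated under homography")
        axes = 1.0 / np.sqrt(w_eig)  # eigh ascending -> axes descending
        angle = float(np.arctan2(v_eig[1, 0], v_eig[0, 0]) % np.pi)
        return EllipseMask((float(center[0]), float(center[1])),
                           (float(axes[0]), float(axes[1])), angle)


@dataclass
class RegistrationResult:
    H_R: Homography
    correspondences: tuple[list[FiducialMarker], list[FiducialMarker]]
    rmse_px: float
    rmse_mm: float
    mask: EllipseMask
    px_per_mm: float


# ---------------------------------------------------------------------- #


def extract_ct_markers(
    ct_render: np.ndarray,
    min_area_px2: float = 10.0,
    max_area_px2: float = 1200.0,
    min_circularity: float = 0.5,
) -> list[FiducialMarker]:
    """Detect bright blob-like fiducials on the CT virtual-endoscopy image.

    Pipeline: percentile contrast stretch -> Otsu global threshold ->
    connected-component (border-following equivalent) contour analysis ->
    area-band and circularity pruning -> intensity-weighted centroid.
    Returns an empty list (caller decides how to proceed) when nothing
    passes the filters.
    """
    img = np.asarray(ct_render, dtype=float)
    if img.ndim != 2:
        raise ConfigError("ct_render must be single-channel")
    if np.ptp(img) == 0:
        return []
    p2, p98 = np.percentile(img, (2, 98))
    stretched = exposure.rescale_intensity(img, in_range=(p2, p98))
    thr = threshold_otsu(stretched)
    binary = stretched > thr
    lab = cc_label(binary)
    markers: list[FiducialMarker] = []
    for prop in regionprops(lab, intensity_image=stretched):
        if not (min_area_px2 <= prop.area <= max_area_px2):
            continue
        circ = 4.0 * np.pi * prop.area / max(prop.perimeter, 1.0) ** 2
        if circ < min_circularity:
            continue
        cy, cx = prop.centroid_weighted
        markers.append(
            FiducialMarker(center_px=(float(cx), float(cy)),
                           area_px2=float(prop.area), source="ct_render")
        )
    return markers


def _refine_click(frame_gray: np.ndarray, click: np.ndarray, window_px: int) -> np.ndarray:
    """Refine a user click to the centroid of the dark blob in its window.

    The fiducials are grey (darker than the membrane) on video, so the
    window is inverted, background-suppressed and intensity-centroided;
    among multiple blobs the one nearest the click wins.
    """
    h, w = frame_gray.shape
    half = window_px // 2
    cx, cy = int(round(click[0])), int(round(click[1]))
    x0, x1 = max(cx - half, 0), min(cx + half + 1, w)
    y0, y1 = max(cy - half, 0), min(cy + half + 1, h)
    patch = frame_gray[y0:y1, x0:x1].astype(float)
    if patch.size == 0:
        return np.asarray(click, dtype=float)
    inv = patch.max() - patch
    bg = np.median(inv)
    wgt = np.clip(inv - bg, 0.0, None)
    if wgt.sum() <= 0:
        return np.asarray(click, dtype=float)
    try:
        thr = threshold_otsu(wgt)
    except ValueError:
        thr = 0.0
    mask = wgt > thr
    lab = cc_label(mask)
    best, best_d = None, np.inf
    for prop in regionprops(lab):
        cyx = np.array([prop.centroid[1] + x0, prop.centroid[0] + y0])
        d = np.linalg.norm(cyx - click)
        if d < best_d:
            best, best_d = prop, d
    if best is None:
        return np.asarray(click, dtype=float)
    blob = lab == best.label
    ww = wgt * blob
    ys, xs = np.nonzero(blob)
    total = ww[ys, xs].sum()
    return np.array(
        [(xs * ww[ys, xs]).sum() / total + x0, (ys * ww[ys, xs]).sum() / total + y0]
    )


def refine_and_register(
    ct_markers,
    user_clicks,
    frame: np.ndarray | None = None,
    window_px: int = 11,
    seed: int | None = None,
    px_per_mm: float = 60.0,
    inlier_threshold_px: float = 3.0,
) -> RegistrationResult:
    """Refine video-side clicks and fit the registration homography H_R.

    ``ct_markers`` may be FiducialMarker objects or raw (x, y) points.
    When ``frame`` is given, each click is refined to the local blob
    centroid within an ``window_px`` square window; refined pairs feed a
    RANSAC homography (CT -> video) and the registration RMSE is computed
    over all pairs.
    """
    ct_pts = np.array(
        [m.center_px if isinstance(m, FiducialMarker) else m for m in ct_markers],
        dtype=float,
    )
    clicks = np.asarray(user_clicks, dtype=float).reshape(-1, 2)
    if len(ct_pts) != len(clicks):
        raise RegistrationError(
            f"CT markers ({len(ct_pts)}) and clicks ({len(clicks)}) must pair up"
        )
    if len(ct_pts) < 4:
        raise RegistrationError(f"at least 4 correspondences required, got {len(ct_pts)}")
    if frame is not None:
        gray = _as_gray(frame)
        video_pts = np.array([_refine_click(gray, c, window_px) for c in clicks])
    else:
        video_pts = clicks.copy()
    try:
        H_R, _ = estimate_homography_ransac(
            ct_pts, video_pts, inlier_threshold_px=inlier_threshold_px, seed=seed
        )
    except EstimationError as exc:
        raise RegistrationError(f"registration homography failed: {exc}") from exc
    mapped = H_R.apply(ct_pts)
    rmse_px = float(np.sqrt(np.mean(np.sum((mapped - video_pts) ** 2, axis=1))))
    mask = fit_ellipse_mask(video_pts)
    corr = (
        [FiducialMarker(tuple(p), 0.0, "ct_render") for p in ct_pts],
        [FiducialMarker(tuple(p), 0.0, "video") for p in video_pts],
    )
    return RegistrationResult(
        H_R=H_R,
        correspondences=corr,
        rmse_px=rmse_px,
        rmse_mm=rmse_px / px_per_mm,
        mask=mask,
        px_per_mm=px_per_mm,
    )


def fit_ellipse_mask(video_markers, margin: float = 0.1) -> EllipseMask:
    """Least-squares ellipse around the video fiducials, dilated by
    ``margin`` so every marker is strictly inside.

    With exactly 4 points the conic is under-determined and a circumscribed
    circle (scaled by the margin) is used instead.
    """
    pts = np.asarray(
        [m.center_px if isinstance(m, FiducialMarker) else m for m in video_markers],
        dtype=float,
    ).reshape(-1, 2)
    if len(pts) < 4:
        raise EstimationError("ellipse mask needs at least 4 points")
    span = np.linalg.matrix_rank(pts - pts.mean(axis=0), tol=1e-6 * max(np.ptp(pts), 1.0))
    if span < 2:
        raise EstimationError("marker points are collinear; no ellipse exists")
    if len(pts) == 4:
        center = pts.mean(axis=0)
        r = float(np.linalg.norm(pts - center, axis=1).max()) * (1.0 + margin)
        return EllipseMask(tuple(center), (r, r), 0.0)
    model = EllipseModel.from_estimate(pts)
    if model:
        (xc, yc), (a, b), th = model.center, model.axis_lengths, model.theta
    else:
        # the direct fit can reject exactly-conic inputs; fall back to an
        # algebraic SVD conic fit
        xc, yc, a, b, th = _conic_lsq_ellipse(pts)
    if a < b:  # canonicalize: major axis first
        a, b = b, a
        th += np.pi / 2.0
    mask = EllipseMask((float(xc), float(yc)),
                       (float(a) * (1.0 + margin), float(b) * (1.0 + margin)),
                       float(th % np.pi))
    grow = 1.0
    tol = 1e-6 * max(a, b)
    while not np.all(mask.contains(pts, margin=tol)) and grow < 2.0:
        grow *= 1.05
        mask = EllipseMask(mask.center_px,
                           (mask.semi_axes_px[0] * 1.05, mask.semi_axes_px[1] * 1.05),
                           mask.angle_rad)
    return mask


def _conic_lsq_ellipse(pts: np.ndarray):
    """Algebraic least-squares ellipse through points (SVD nullspace of the
    general-conic design matrix). Assumes the points genuinely lie near an
    ellipse; raises otherwise."""
    x, y = pts[:, 0], pts[:, 1]
    mx, my = x.mean(), y.mean()
    s = max(x.std(), y.std(), 1e-9)
    xn, yn = (x - mx) / s, (y - my) / s
    D = np.column_stack([xn**2, xn * yn, yn**2, xn, yn, np.ones_like(xn)])
    _, _, vt = np.linalg.svd(D, full_matrices=False)
    A6, B6, C6, D6, E6, F6 = vt[-1]
    if B6**2 - 4 * A6 * C6 >= 0:
        raise EstimationError("conic fit is not an ellipse")
    C = np.array([[A6, B6 / 2, D6 / 2], [B6 / 2, C6, E6 / 2], [D6 / 2, E6 / 2, F6]])
    T = np.array([[1 / s, 0, -mx / s], [0, 1 / s, -my / s], [0, 0, 1.0]])
    C = T.T @ C @ T  # back to pixel coordinates
    A2 = C[:2, :2]
    if np.trace(A2) < 0:
        C, A2 = -C, -A2
    center = np.linalg.solve(A2, -C[:2, 2])
    k = center @ A2 @ center - C[2, 2]
    w_eig, v_eig = np.linalg.eigh(A2 / k)
    if k <= 0 or np.any(w_eig <= 0):
        raise EstimationError("conic fit is not an ellipse")
    axes = 1.0 / np.sqrt(w_eig)
    ang = float(np.arctan2(v_eig[1, 0], v_eig[0, 0]) % np.pi)
    return float(center[0]), float(center[1]), float(axes[0]), float(axes[1]), ang


def blend(microscope_img: np.ndarray, warped_ct_img: np.ndarray,
          cfg: BlendConfig = BlendConfig()) -> np.ndarray:
    """Per-pixel convex combination I_AR = beta*I_M + (1-beta)*I_CT."""
    m = np.asarray(microscope_img)
    c = np.asarray(warped_ct_img)
    if c.ndim == 2 and m.ndim == 3:
        c = np.repeat(c[:, :, None], m.shape[2], axis=2)
    if m.ndim == 2 and c.ndim == 3:
        m = np.repeat(m[:, :, None], c.shape[2], axis=2)
    if m.shape != c.shape:
        raise ConfigError(f"image shapes differ: {m.shape} vs {c.shape}")
    out = cfg.beta * m.astype(float) + (1.0 - cfg.beta) * c.astype(float)
    if np.issubdtype(np.asarray(microscope_img).dtype, np.integer):
        return np.clip(out, 0, 255).round().astype(np.uint8)
    return np.clip(out, 0.0, 1.0) if out.max() <= 1.0 else out


def registration_error_mm(result: RegistrationResult, px_per_mm: float) -> float:
    """RMS distance (mm) between video fiducials and H_R-mapped CT ones."""
    if px_per_mm <= 0:
        raise ConfigError("px_per_mm must be positive")
    ct_pts = np.array([m.center_px for m in result.correspondences[0]])
    vid_pts = np.array([m.center_px for m in result.correspondences[1]])
    if len(ct_pts) == 0:
        raise RegistrationError("no correspondences to score")
    mapped = result.H_R.apply(ct_pts)
    rmse_px = float(np.sqrt(np.mean(np.sum((mapped - vid_pts) ** 2, axis=1))))
    return rmse_px / px_per_mm


def warp_to_frame(image: np.ndarray, H: Homography,
                  output_shape: tuple[int, int]) -> np.ndarray:
    """Warp ``image`` by H into a (height, width) viewport (uint8-safe)."""
    arr = np.asarray(image)
    was_int = np.issubdtype(arr.dtype, np.integer)
    tform = ProjectiveTransform(np.linalg.inv(H.matrix))
    out = warp(arr.astype(float) / (255.0 if was_int else 1.0), tform,
               output_shape=output_shape, order=1, mode="constant", cval=0.0)
    return (out * 255.0).round().astype(np.uint8) if was_int else out


def px_per_mm_from_distances(video_points_px, distances_mm) -> float:
    """Image scale from known physical inter-fiducial distances.

    ``distances_mm[(i, j)]`` gives the physical separation of fiducial
    pair (i, j); the scale is the ratio of mean pixel to mean physical
    distance over the provided pairs.
    """
    pts = np.asarray(video_points_px, dtype=float)
    px, mm = [], []
    for (i, j), d in distances_mm.items():
        px.append(np.linalg.norm(pts[i] - pts[j]))
        mm.append(d)
    if not mm or np.mean(mm) <= 0:
        raise ConfigError("no valid fiducial distances supplied")
    return float(np.mean(px) / np.mean(mm))


def _as_gray(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img, dtype=float)
    if arr.ndim == 3:
        arr = arr @ np.array([0.2125, 0.7154, 0.0721])
    return arr / 255.0 if arr.max() > 1.5 else arr
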