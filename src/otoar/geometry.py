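"""Pinhole projection and homography algebra shared by all pipeline stages.

Conventions
-----------
* Pixel coordinates are ``(x, y)`` with the origin at the top-left corner,
  x growing rightward and y downward, 0-based, pixel centers at integer
  coordinates.
* 3D camera-frame coordinates are in millimetres with +z pointing from the
  camera toward the scene, so visible points have positive depth.
* Homographies act on homogeneous pixel coordinates and are stored
  normalized: the (3, 3) entry is scaled to 1 when nonzero, otherwise the
  matrix is scaled to unit Frobenius norm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from skimage.measure import ransac as _sk_ransac
from skimage.transform import ProjectiveTransform

from .exceptions import ConfigError, DegenerateGeometryError, EstimationError

__all__ = [
    "CameraIntrinsics",
    "Homography",
    "Pose3D",
    "project_point",
    "apply_homography",
    "compose_homography",
    "estimate_homography_ransac",
    "corner_deviation_px",
]

_EPS = 1e-12


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole camera model: focal length in pixels and principal point.

    The focal length doubles as the z coordinate of image points when
    projection rays ``O->b`` are built for instrument pose estimation.
    """

    focal_px: float
    principal_point: tuple[float, float]
    image_size: tuple[int, int]  # (width, height)

    def __post_init__(self) -> None:
        if not self.focal_px > 0:
            raise ConfigError(f"focal_px must be positive, got {self.focal_px}")
        cx, cy = self.principal_point
        w, h = self.image_size
        if not (0 <= cx < w and 0 <= cy < h):
            raise ConfigError(
                f"principal point {self.principal_point} outside image bounds {self.image_size}"
            )

    @property
    def matrix(self) -> np.ndarray:
        """3x3 calibration matrix K."""
        cx, cy = self.principal_point
        f = self.focal_px
        return np.array([[f, 0.0, cx], [0.0, f, cy], [0.0, 0.0, 1.0]])

    def rays(self, points_px: np.ndarray) -> np.ndarray:
        """Unit back-projection rays through pixel(s), shape (..., 3).

        Built as ``(x - cx, y - cy, f)`` then normalized: the focal length
        is used as the z coordinate of the image plane.
        """
        p = np.atleast_2d(np.asarray(points_px, dtype=float))
        cx, cy = self.principal_point
        d = np.column_stack([p[:, 0] - cx, p[:, 1] - cy, np.full(len(p), self.focal_px)])
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        return d if np.asarray(points_px).ndim > 1 else d[0]

    @classmethod
    def from_file(cls, path) -> "CameraIntrinsics":
        """Read a flat key-value config (focal_px, cx, cy, width, height)."""
        import yaml

        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        if not isinstance(cfg, dict):
            raise ConfigError(f"intrinsics file {path!s} is not a flat key-value map")
        try:
            return cls(
                focal_px=float(cfg["focal_px"]),
                principal_point=(float(cfg["cx"]), float(cfg["cy"])),
                image_size=(int(cfg["width"]), int(cfg["height"])),
            )
        except KeyError as exc:
            raise ConfigError(f"intrinsics file {path!s} missing key {exc}") from exc

    def to_file(self, path) -> None:
        cx, cy = self.principal_point
        w, h = self.image_size
        with open(path, "w") as fh:
            fh.write(
                f"focal_px: {self.focal_px}\ncx: {cx}\ncy: {cy}\nwidth: {w}\nheight: {h}\n"
            )


def _normalize_matrix(matrix: np.ndarray) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.shape != (3, 3):
        raise ConfigError(f"homography matrix must be 3x3, got {m.shape}")
    if abs(m[2, 2]) > _EPS:
        return m / m[2, 2]
    n = np.linalg.norm(m)
    if n < _EPS:
        raise DegenerateGeometryError("zero homography matrix")
    return m / n


@dataclass(frozen=True)
class Homography:
    """3x3 projective map between images of a plane.

    Instances are normalized on construction (idempotently) and checked
    for invertibility.
    """

    matrix: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        m = _normalize_matrix(self.matrix)
        if not np.all(np.isfinite(m)):
            raise DegenerateGeometryError("non-finite homography matrix")
        if abs(np.linalg.det(m)) < 1e-15 or np.linalg.cond(m) > 1e14:
            raise DegenerateGeometryError("homography matrix is singular")
        m.setflags(write=False)
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "Homography":
        return cls(np.eye(3))

    @classmethod
    def translation(cls, tx: float, ty: float) -> "Homography":
        return cls(np.array([[1.0, 0.0, tx], [0.0, 1.0, ty], [0.0, 0.0, 1.0]]))

    def apply(self, points_px: np.ndarray) -> np.ndarray:
        return apply_homography(self, points_px)

    def inverse(self) -> "Homography":
        return Homography(np.linalg.inv(self.matrix))

    def __matmul__(self, other: "Homography") -> "Homography":
        return compose_homography(self, other)

    def almost_equal(self, other: "Homography", tol: float = 1e-9) -> bool:
        return bool(np.allclose(self.matrix, other.matrix, atol=tol))


@dataclass(frozen=True)
class Pose3D:
    """Rigid camera pose: ``X_cam = rotation @ X_world + translation`` (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if r.shape != (3, 3):
            raise ConfigError("rotation must be 3x3")
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-8) or not np.isclose(
            np.linalg.det(r), 1.0, atol=1e-8
        ):
            raise ConfigError("rotation must be orthonormal with determinant +1")
        r.setflags(write=False)
        t.setflags(write=False)
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    def transform(self, points_world: np.ndarray) -> np.ndarray:
        p = np.asarray(points_world, dtype=float)
        return p @ self.rotation.T + self.translation


def project_point(intr: CameraIntrinsics, p: np.ndarray) -> np.ndarray:
    """Pinhole projection of camera-frame point(s) (mm) to pixels.

    Raises :class:`DegenerateGeometryError` for non-positive depth.
    """
    arr = np.asarray(p, dtype=float)
    single = arr.ndim == 1
    pts = np.atleast_2d(arr)
    if np.any(pts[:, 2] <= 0):
        raise DegenerateGeometryError("point has non-positive depth (behind camera)")
    cx, cy = intr.principal_point
    f = intr.focal_px
    out = np.column_stack(
        [f * pts[:, 0] / pts[:, 2] + cx, f * pts[:, 1] / pts[:, 2] + cy]
    )
    return out[0] if single else out


def apply_homography(H: Homography, points_px: np.ndarray) -> np.ndarray:
    """Dehomogenized action of H on pixel point(s)."""
    arr = np.asarray(points_px, dtype=float)
    single = arr.ndim == 1
    pts = np.atleast_2d(arr)
    hom = np.column_stack([pts, np.ones(len(pts))]) @ H.matrix.T
    w = hom[:, 2]
    if np.any(np.abs(w) < _EPS):
        raise DegenerateGeometryError("point maps to the line at infinity")
    out = hom[:, :2] / w[:, None]
    return out[0] if single else out


def compose_homography(H_T: Homography, H: Homography) -> Homography:
    """Chained-homography update ``H <- H_T @ H``.

    ``H_T`` is the inter-frame transform (previous frame to current frame)
    and ``H`` the cumulative transform (reference frame to previous frame);
    the product maps the reference frame to the current frame.
    """
    return Homography(H_T.matrix @ H.matrix)


def _min_triangle_area(points: np.ndarray) -> float:
    best = np.inf
    for i, j, k in combinations(range(len(points)), 3):
        a, b, c = points[i], points[j], points[k]
        u, v = b - a, c - a
        area = 0.5 * abs(u[0] * v[1] - u[1] * v[0])
        best = min(best, area)
    return best


def _sample_valid(src_s: np.ndarray, dst_s: np.ndarray) -> bool:
    """Reject 4-point RANSAC samples with any 3 (near-)collinear points."""
    scale = max(np.ptp(src_s, axis=0).max(), np.ptp(dst_s, axis=0).max(), 1.0)
    thresh = 1e-3 * scale**2
    return (
        _min_triangle_area(np.asarray(src_s, float)) > thresh
        and _min_triangle_area(np.asarray(dst_s, float)) > thresh
    )


def estimate_homography_ransac(
    src: np.ndarray,
    dst: np.ndarray,
    inlier_threshold_px: float = 3.0,
    max_iters: int = 2000,
    seed: int | None = None,
    confidence: float = 0.995,
) -> tuple[Homography, np.ndarray]:
    """RANSAC homography from point correspondences ``dst ~ H @ src``.

    Minimal 4-point samples with any near-collinear triple are rejected and
    resampled; the consensus model is refit by least squares (normalized
    DLT) on all inliers. Returns the homography and a boolean inlier mask.
    """
    src = np.asarray(src, dtype=float).reshape(-1, 2)
    dst = np.asarray(dst, dtype=float).reshape(-1, 2)
    if len(src) != len(dst):
        raise EstimationError("src and dst must have equal length")
    if len(src) < 4:
        raise EstimationError(f"need at least 4 correspondences, got {len(src)}")
    # A wholly (near-)collinear correspondence set admits no valid sample.
    for pts in (src, dst):
        sv = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
        if sv[1] < 1e-6 * max(sv[0], 1.0):
            raise EstimationError("correspondence set is (near-)collinear")
    model, inliers = _sk_ransac(
        (src, dst),
        ProjectiveTransform,
        min_samples=4,
        residual_threshold=float(inlier_threshold_px),
        max_trials=int(max_iters),
        stop_probability=float(confidence),
        is_data_valid=_sample_valid,
        rng=seed,
    )
    if model is None or inliers is None or inliers.sum() < 4:
        raise EstimationError("RANSAC failed to find a consistent homography")
    refit = ProjectiveTransform.from_estimate(src[inliers], dst[inliers])
    if not refit:
        raise EstimationError("least-squares refit on inliers failed")
    try:
        H = Homography(refit.params)
    except DegenerateGeometryError as exc:
        raise EstimationError(f"estimated homography is degenerate: {exc}") from exc
    return H, np.asarray(inliers, dtype=bool)


def corner_deviation_px(
    H_a: Homography, H_b: Homography, image_size: tuple[int, int]
) -> float:
    """Max displacement (px) between two homographies at the image corners.

    Standard scalar summary of how far apart two plane maps are over a
    (width, height) viewport.
    """
    w, h = image_size
    corners = np.array([[0.0, 0.0], [w - 1.0, 0.0], [0.0, h - 1.0], [w - 1.0, h - 1.0]])
    return float(
        np.linalg.norm(H_a.apply(corners) - H_b.apply(corners), axis=1).max()
    )
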