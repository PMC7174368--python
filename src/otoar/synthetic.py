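"""Seeded synthetic microscope scenes with exact per-frame ground truth.

The simulator emulates the phantom bench experiments the guidance system is
designed for: a textured, near-planar tympanic membrane viewed by an
operating microscope, 5-6 grey fiducial markers glued to the membrane
periphery, microscope motion at slow (<5 mm/s) or rapid (5-10 mm/s) speeds
with in-plane rotation and zoom, and a micro-instrument carrying three
collinear colour markers. Each frame comes with the true reference-to-frame
plane homography, the exact fiducial pixel positions, and the instrument's
3D pose in the camera frame, so every downstream stage can be scored
without physical hardware.

Geometry: the membrane is the world plane z = 0 (mm); the camera sits at
working distance ``Z0`` along -z, so the reference view is fronto-parallel
with scale ``px_per_mm = focal_px / Z0``. Structures behind the membrane
have z > 0; the ear-canal wall ring surrounding the membrane is modelled as
a second plane slightly closer to the camera, which gives genuine parallax
for off-membrane features (the reason the tracker masks them out).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import ProjectiveTransform, warp

from .exceptions import ConfigError
from .geometry import CameraIntrinsics, Homography, Pose3D, project_point
from .instrument import InstrumentModel

__all__ = [
    "TextureParams",
    "CameraTrajectory",
    "DegradationParams",
    "InkEvent",
    "InstrumentScenario",
    "SceneSpec",
    "FrameGroundTruth",
    "SyntheticDataset",
    "generate_membrane_texture",
    "place_fiducials",
    "render_frame",
    "simulate_dataset",
]

# Pinkish-grey tint applied to the grayscale membrane texture; markers and
# the canal wall stay darker so they read as grey/shadowed in RGB.
_MEMBRANE_TINT = np.array([1.0, 0.78, 0.72])
_MARKER_COLOR_TABLE = (
    (0.85, 0.18, 0.18),  # marker B (nearest tip)
    (0.15, 0.72, 0.25),  # marker C
    (0.2, 0.32, 0.9),  # marker D (nearest entry)
)


@dataclass(frozen=True)
class TextureParams:
    """Blob density (per mm^2), global contrast and fine speckle amount."""

    blob_density: float = 7.0
    contrast: float = 0.6
    speckle: float = 0.5


@dataclass(frozen=True)
class InkEvent:
    """Semi-transparent dark-red blob appearing on the membrane at a time."""

    time_s: float
    center_mm: tuple[float, float]
    radius_mm: float = 0.8
    opacity: float = 0.8


@dataclass(frozen=True)
class CameraTrajectory:
    """Microscope motion model.

    ``speed_class`` selects amplitude/frequency defaults so the peak
    translational speed lies in the declared band: "low" < 5 mm/s,
    "high" 5-10 mm/s, "static" no motion, "jerk" low motion plus one
    instantaneous pose jump (which, being a discontinuity, is outside any
    speed class). ``fixed_*`` fields offset the base pose and are used to
    pose single-frame registration scenes.
    """

    speed_class: str = "low"
    translate_xy: bool = True
    translate_z: bool = True
    rotate: bool = True
    amp_xy_mm: float | None = None
    amp_z_mm: float | None = None
    rot_amp_deg: float | None = None
    tilt_amp_deg: float = 1.5
    jerk_time_s: float | None = None
    jerk_offset_mm: tuple[float, float] = (1.2, 0.8)
    fixed_offset_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    fixed_rot_deg: float = 0.0
    fixed_tilt_deg: float = 0.0

    _CLASS_DEFAULTS = {
        # per-axis amplitude (mm), per-axis peak speed (mm/s), rotation amp (deg)
        "low": (0.6, 1.8, 4.0),
        "high": (0.7, 4.4, 8.0),
        "static": (0.0, 0.0, 0.0),
        "jerk": (0.5, 1.5, 3.0),
    }

    def __post_init__(self) -> None:
        if self.speed_class not in self._CLASS_DEFAULTS:
            raise ConfigError(f"unknown speed class {self.speed_class!r}")

    def _params(self):
        amp, peak, rot = self._CLASS_DEFAULTS[self.speed_class]
        amp_xy = amp if self.amp_xy_mm is None else self.amp_xy_mm
        amp_z = 2.5 * amp if self.amp_z_mm is None else self.amp_z_mm
        rot_amp = rot if self.rot_amp_deg is None else self.rot_amp_deg
        omega = peak / amp_xy if amp_xy > 0 else 0.0
        return amp_xy, amp_z, rot_amp, omega

    def translation_mm(self, t: float) -> np.ndarray:
        amp_xy, amp_z, _, om = self._params()
        tx = ty = tz = 0.0
        if self.translate_xy and amp_xy > 0:
            tx = amp_xy * math.sin(om * t)
            ty = amp_xy * math.sin(1.13 * om * t + 1.3)
        if self.translate_z and amp_z > 0:
            # z moves slower so its peak speed matches the class band too
            tz = amp_z * math.sin(0.4 * om * t + 2.1)
        out = np.array([tx, ty, tz]) + np.asarray(self.fixed_offset_mm)
        if (
            self.speed_class == "jerk"
            and self.jerk_time_s is not None
            and t >= self.jerk_time_s
        ):
            out[:2] += np.asarray(self.jerk_offset_mm)
        return out

    def angles_rad(self, t: float) -> tuple[float, float]:
        """(in-plane roll, out-of-plane pitch) at time t."""
        _, _, rot_amp, om = self._params()
        roll = math.radians(self.fixed_rot_deg)
        pitch = math.radians(self.fixed_tilt_deg)
        if self.rotate and rot_amp > 0:
            roll += math.radians(rot_amp) * math.sin(0.35 * om * t + 0.4)
            pitch += math.radians(self.tilt_amp_deg) * math.sin(0.27 * om * t + 1.1)
        return roll, pitch

    def pose(self, t: float, working_distance_mm: float) -> Pose3D:
        roll, pitch = self.angles_rad(t)
        cr, sr = math.cos(roll), math.sin(roll)
        cp, sp = math.cos(pitch), math.sin(pitch)
        rz = np.array([[cr, -sr, 0.0], [sr, cr, 0.0], [0.0, 0.0, 1.0]])
        rx = np.array([[1.0, 0.0, 0.0], [0.0, cp, -sp], [0.0, sp, cp]])
        trans = self.translation_mm(t) + np.array([0.0, 0.0, working_distance_mm])
        return Pose3D(rotation=rz @ rx, translation=trans)


@dataclass(frozen=True)
class DegradationParams:
    """Image degradations applied after the geometrically exact render."""

    noise_sigma: float = 2.0  # additive Gaussian, 8-bit grey levels
    marker_blur_sigma: float = 1.0  # defocus of the instrument layer, px
    frame_blur_sigma: float = 0.0  # optional global defocus, px
    illumination_amp: float = 0.0  # relative gain oscillation amplitude
    illumination_period_s: float = 25.0
    ink_events: tuple[InkEvent, ...] = ()

    def gain(self, t: float) -> float:
        if self.illumination_amp == 0.0:
            return 1.0
        return 1.0 + self.illumination_amp * math.sin(
            2.0 * math.pi * t / self.illumination_period_s
        )


@dataclass(frozen=True)
class InstrumentScenario:
    """Timed path of the instrument tip plus its physical model.

    ``waypoints`` are (time_s, world tip position mm) pairs, linearly
    interpolated; the tool is absent before ``entry_time_s``.
    ``direction_world`` points from the tip toward the handle, so markers
    B, C, D sit at tip + AB/AC/AD along it. ``target_points_mm`` and
    ``target_times_s`` record where and when the true tip touches the
    simulated anatomical targets.
    """

    model: InstrumentModel
    entry_time_s: float
    waypoints: tuple[tuple[float, tuple[float, float, float]], ...]
    direction_world: tuple[float, float, float]
    target_points_mm: tuple[tuple[float, float, float], ...] = ()
    target_times_s: tuple[float, ...] = ()
    marker_radius_mm: float = 0.35
    shaft_radius_mm: float = 0.22

    def tip_world(self, t: float) -> np.ndarray | None:
        if t < self.entry_time_s or not self.waypoints:
            return None
        times = np.array([w[0] for w in self.waypoints])
        pts = np.array([w[1] for w in self.waypoints], dtype=float)
        if t <= times[0]:
            return pts[0].copy()
        if t >= times[-1]:
            return pts[-1].copy()
        return np.array(
            [np.interp(t, times, pts[:, k]) for k in range(3)]
        )

    def axis_world(self) -> np.ndarray:
        u = np.asarray(self.direction_world, dtype=float)
        return u / np.linalg.norm(u)


@dataclass(frozen=True)
class SceneSpec:
    """Full description of one synthetic experiment (hashable, seeded)."""

    seed: int
    membrane_radius_mm: float = 2.5
    n_fiducials: int = 6
    texture_params: TextureParams = field(default_factory=TextureParams)
    px_per_mm: float = 60.0
    working_distance_mm: float = 115.0
    frame_size: tuple[int, int] = (384, 384)  # (width, height)
    fps: float = 12.0
    duration_s: float = 120.0
    trajectory: CameraTrajectory = field(default_factory=CameraTrajectory)
    instrument: InstrumentScenario | None = None
    degradations: DegradationParams = field(default_factory=DegradationParams)
    fiducial_radius_mm: float = 0.25  # paper-scale 0.5 mm diameter markers
    fiducial_ring_frac: float = 0.8
    canal_depth_offset_mm: float = -1.5  # canal wall sits closer to camera

    def __post_init__(self) -> None:
        if self.n_fiducials not in (5, 6):
            raise ConfigError(f"n_fiducials must be 5 or 6, got {self.n_fiducials}")
        if self.px_per_mm <= 0:
            raise ConfigError("px_per_mm must be positive")
        if self.membrane_radius_mm <= 0 or self.fps <= 0 or self.duration_s <= 0:
            raise ConfigError("scene dimensions, fps and duration must be positive")

    @property
    def focal_px(self) -> float:
        return self.px_per_mm * self.working_distance_mm

    @property
    def intrinsics(self) -> CameraIntrinsics:
        w, h = self.frame_size
        return CameraIntrinsics(
            focal_px=self.focal_px,
            principal_point=((w - 1) / 2.0, (h - 1) / 2.0),
            image_size=(w, h),
        )

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))

    # ------------------------------------------------------------------ #
    # Presets mirroring the bench protocols
    # ------------------------------------------------------------------ #

    @classmethod
    def preset_static(cls, seed: int, duration_s: float = 10.0) -> "SceneSpec":
        return cls(seed=seed, duration_s=duration_s,
                   trajectory=CameraTrajectory(speed_class="static"))

    @classmethod
    def preset_2min(cls, seed: int, speed_class: str = "high") -> "SceneSpec":
        """Two-minute tracking run with full x/y/z translation + rotation."""
        return cls(seed=seed, duration_s=120.0,
                   trajectory=CameraTrajectory(speed_class=speed_class))

    @classmethod
    def preset_8min(cls, seed: int, speed_class: str = "low",
                    ink_time_s: float | None = 300.0) -> "SceneSpec":
        """Eight-minute run, 5 fiducials, lighting drift, optional ink."""
        ink = ()
        if ink_time_s is not None:
            ink = (InkEvent(time_s=ink_time_s, center_mm=(1.4, 1.6), radius_mm=0.9),)
        return cls(
            seed=seed, duration_s=480.0, n_fiducials=5,
            trajectory=CameraTrajectory(speed_class=speed_class),
            degradations=DegradationParams(illumination_amp=0.12, ink_events=ink),
        )

    @classmethod
    def preset_jerk(cls, seed: int, duration_s: float = 12.0,
                    jerk_time_s: float = 6.0) -> "SceneSpec":
        return cls(seed=seed, duration_s=duration_s,
                   trajectory=CameraTrajectory(speed_class="jerk",
                                               jerk_time_s=jerk_time_s))

    @classmethod
    def preset_registration(cls, seed: int) -> "SceneSpec":
        """Single-frame scene at a seeded off-reference pose, for scoring
        CT-to-video registration against truth."""
        rng = np.random.default_rng([seed, 417])
        traj = CameraTrajectory(
            speed_class="static",
            fixed_offset_mm=(
                float(rng.uniform(-0.5, 0.5)),
                float(rng.uniform(-0.5, 0.5)),
                float(rng.uniform(-4.0, 4.0)),
            ),
            fixed_rot_deg=float(rng.uniform(-15.0, 15.0)),
            fixed_tilt_deg=float(rng.uniform(-4.0, 4.0)),
        )
        return cls(seed=seed, duration_s=1.0, fps=1.0, trajectory=traj)

    @classmethod
    def preset_procedure(cls, seed: int) -> "SceneSpec":
        """Full guided procedure: quasi-static view, instrument driven to
        three membrane-depth targets (umbo / incus-tip / round-window
        analogs), microscope at focal length 5000 px and 115 mm working
        distance as in the bench setup."""
        model = InstrumentModel.from_spacings(3.0, 3.0, 3.0)
        targets = ((1.9, 0.6, 1.2), (2.3, 1.1, 3.2), (2.6, -0.9, 2.4))
        # tool lies close to the focal plane (shallow ~7 deg pitch): the
        # microscope's depth of field keeps the marker segment in focus
        u = np.array([-0.95, -0.28, -0.12])
        u /= np.linalg.norm(u)
        entry = np.array([1.6, 0.0, -1.5])

        def hover(p):
            return tuple(np.asarray(p) + np.array([0.0, 0.0, -1.2]))

        wps = [(3.0, tuple(entry))]
        t = 6.0
        times = []
        for tgt in targets:
            wps.append((t, hover(tgt)))
            wps.append((t + 1.2, tgt))
            wps.append((t + 2.2, tgt))  # dwell on target
            wps.append((t + 3.2, hover(tgt)))
            times.append(t + 1.7)
            t += 5.0
        wps.append((t + 1.0, tuple(entry)))
        scenario = InstrumentScenario(
            model=model,
            entry_time_s=3.0,
            waypoints=tuple(wps),
            direction_world=tuple(u),
            target_points_mm=targets,
            target_times_s=tuple(times),
        )
        return cls(
            seed=seed,
            membrane_radius_mm=3.2,
            px_per_mm=5000.0 / 115.0,
            frame_size=(640, 512),
            duration_s=t + 2.0,
            trajectory=CameraTrajectory(speed_class="low", amp_xy_mm=0.25,
                                        amp_z_mm=0.6, rot_amp_deg=2.0),
            instrument=scenario,
        )


@dataclass
class FrameGroundTruth:
    """Exact (pre-degradation) truth for one rendered frame."""

    frame_index: int
    time_s: float
    true_plane_homography: Homography  # reference frame -> this frame
    fiducial_px: np.ndarray  # (n, 2)
    instrument_present: bool = False
    marker_px: dict[str, np.ndarray] | None = None  # labels b, c, d
    markers_cam_mm: dict[str, np.ndarray] | None = None
    tip_3d_mm: np.ndarray | None = None  # camera frame, label A
    tip_px: np.ndarray | None = None


# ---------------------------------------------------------------------- #
# Texture and fiducial layout
# ---------------------------------------------------------------------- #


def generate_membrane_texture(seed: int, texture_params: TextureParams,
                              size_px: int) -> np.ndarray:
    """Deterministic feature-rich membrane texture in [0, 1], shape (n, n).

    Layered model: smooth large-scale shading (the membrane's sheen), a
    Poisson field of soft blobs (vascular spots, malleus shadow scale), and
    fine speckle that gives the corner detector dense, well-localized
    structure.
    """
    if size_px <= 0:
        raise ConfigError("texture size must be positive")
    rng = np.random.default_rng([seed, 101])
    n = int(size_px)
    base = gaussian_filter(rng.standard_normal((n, n)), n / 24.0)
    blobs = gaussian_filter(rng.standard_normal((n, n)), n / 110.0)
    detail = gaussian_filter(rng.standard_normal((n, n)), 4.0)
    speckle = gaussian_filter(rng.standard_normal((n, n)), 2.0)
    img = (
        0.7 * _unit(base)
        + 0.9 * _unit(blobs)
        + 0.8 * _unit(detail)
        + texture_params.speckle * _unit(speckle)
    )
    img = _unit(img)
    lo = 0.5 - texture_params.contrast / 2.0
    return lo + texture_params.contrast * img


def _unit(a: np.ndarray) -> np.ndarray:
    a = a - a.min()
    rng = np.ptp(a)
    return a / rng if rng > 0 else a


def place_fiducials(spec: SceneSpec) -> np.ndarray:
    """Fiducial positions (mm) on the membrane periphery.

    Markers sit on a ring near the rim, far apart and non-collinear, with
    their centroid close to the membrane centre (the projected target).
    Deterministic for a given spec seed; layouts violating the spacing,
    triangle-area or centroid constraints are rejected and resampled.
    """
    n = spec.n_fiducials
    R = spec.membrane_radius_mm
    rng = np.random.default_rng([spec.seed, 202])
    for _ in range(200):
        angles = (
            2.0 * math.pi * np.arange(n) / n
            + rng.uniform(-0.1, 0.1, n) * 2.0 * math.pi / n
            + rng.uniform(0.0, 2.0 * math.pi)
        )
        radii = R * spec.fiducial_ring_frac * (1.0 + rng.uniform(-0.06, 0.06, n))
        pts = np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        min_pair = d[np.triu_indices(n, 1)].min()
        if min_pair < 0.6 * R:
            continue
        if np.linalg.norm(pts.mean(axis=0)) > 0.05 * R:
            continue
        from .geometry import _min_triangle_area

        if _min_triangle_area(pts) < 0.08 * R * R:
            continue
        return pts
    raise ConfigError("could not place fiducials satisfying layout constraints")


# ---------------------------------------------------------------------- #
# Scene realization (cached per spec)
# ---------------------------------------------------------------------- #


class _Realization:
    """Precomputed textures, layout and reference geometry for a spec."""

    def __init__(self, spec: SceneSpec) -> None:
        self.spec = spec
        self.intr = spec.intrinsics
        w, h = spec.frame_size
        half_mm = max(w, h) / 2.0 / spec.px_per_mm
        amp = spec.trajectory._params()[0]
        if spec.trajectory.jerk_time_s is not None:
            amp += max(abs(v) for v in spec.trajectory.jerk_offset_mm)
        self.ext_mm = half_mm + amp + 1.5
        self.tex_ppmm = 1.5 * spec.px_per_mm
        tex_n = int(math.ceil(2 * self.ext_mm * self.tex_ppmm))
        self.fiducials_mm = place_fiducials(spec)

        base = generate_membrane_texture(spec.seed, spec.texture_params, tex_n)
        self.membrane_tex = base.copy()
        # grey fiducial discs drawn into the membrane plane itself
        r_px = spec.fiducial_radius_mm * self.tex_ppmm
        for fx, fy in self.fiducials_mm:
            cx, cy = self._mm_to_tex(fx, fy)
            _draw_soft_disc(self.membrane_tex, cx, cy, r_px, 0.22)

        rng = np.random.default_rng([spec.seed, 303])
        canal = gaussian_filter(rng.standard_normal((tex_n, tex_n)), 3.0)
        canal = 0.12 + 0.3 * _unit(canal)
        self.canal_tex = canal

        # soft membrane-disc alpha in texture space
        yy, xx = np.mgrid[0:tex_n, 0:tex_n].astype(float)
        cx0, cy0 = self._mm_to_tex(0.0, 0.0)
        dist = np.hypot(xx - cx0, yy - cy0)
        edge = spec.membrane_radius_mm * self.tex_ppmm * 1.12
        self.membrane_alpha = np.clip((edge - dist) / 3.0 + 0.5, 0.0, 1.0)

        self.pose0 = spec.trajectory.pose(0.0, spec.working_distance_mm)
        self.H_world2ref = self._world_to_image_h(self.pose0, 0.0)
        self.A_mm2tex = np.array(
            [
                [self.tex_ppmm, 0.0, self.ext_mm * self.tex_ppmm],
                [0.0, self.tex_ppmm, self.ext_mm * self.tex_ppmm],
                [0.0, 0.0, 1.0],
            ]
        )
        self.ref_fiducial_px = self._project_plane(self.H_world2ref, self.fiducials_mm)

        # --- CT virtual-endoscopy analog ------------------------------- #
        ct_tone = 0.2 + 0.55 * (1.0 - base)
        ct_tone = gaussian_filter(ct_tone, 1.5)
        for fx, fy in self.fiducials_mm:
            cx, cy = self._mm_to_tex(fx, fy)
            _draw_soft_disc(ct_tone, cx, cy, r_px, 0.97)  # bright protrusions
        ang = math.radians(6.0)
        ca, sa = math.cos(ang), math.sin(ang)
        self.H_ref2ct = Homography(
            np.array(
                [
                    [0.95 * ca, -0.95 * sa, 14.0],
                    [0.95 * sa, 0.95 * ca, -9.0],
                    [4e-6, -3e-6, 1.0],
                ]
            )
        )
        H_tex2ct = self.H_ref2ct.matrix @ self.H_world2ref @ np.linalg.inv(self.A_mm2tex)
        ct = warp(ct_tone, ProjectiveTransform(np.linalg.inv(H_tex2ct)),
                  output_shape=(h, w), order=3, mode="constant", cval=0.1)
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        vign = 1.0 - 0.1 * ((xx - w / 2) ** 2 + (yy - h / 2) ** 2) / ((w / 2) ** 2 + (h / 2) ** 2)
        self.ct_render = np.clip(ct * vign * 255.0, 0, 255).round().astype(np.uint8)
        self.ct_marker_px = self.H_ref2ct.apply(self.ref_fiducial_px)

    # -- coordinate helpers -------------------------------------------- #

    def _mm_to_tex(self, x_mm: float, y_mm: float) -> tuple[float, float]:
        return (
            (x_mm + self.ext_mm) * self.tex_ppmm,
            (y_mm + self.ext_mm) * self.tex_ppmm,
        )

    def _world_to_image_h(self, pose: Pose3D, plane_z_mm: float) -> np.ndarray:
        """Homography (3x3 array) from plane z=const (mm) to image px."""
        R, t = pose.rotation, pose.translation
        cols = np.column_stack([R[:, 0], R[:, 1], R[:, 2] * plane_z_mm + t])
        return self.intr.matrix @ cols

    @staticmethod
    def _project_plane(H: np.ndarray, pts_mm: np.ndarray) -> np.ndarray:
        hom = np.column_stack([pts_mm, np.ones(len(pts_mm))]) @ H.T
        return hom[:, :2] / hom[:, 2:3]

    # -- per-frame truth and rendering --------------------------------- #

    def truth_at(self, frame_index: int) -> FrameGroundTruth:
        spec = self.spec
        t = frame_index / spec.fps
        pose = spec.trajectory.pose(t, spec.working_distance_mm)
        Hw = self._world_to_image_h(pose, 0.0)
        H_ref2cur = Homography(Hw @ np.linalg.inv(self.H_world2ref))
        fid_px = self._project_plane(Hw, self.fiducials_mm)
        gt = FrameGroundTruth(
            frame_index=frame_index,
            time_s=t,
            true_plane_homography=H_ref2cur,
            fiducial_px=fid_px,
        )
        scen = spec.instrument
        if scen is not None:
            tip_w = scen.tip_world(t)
            if tip_w is not None:
                u = scen.axis_world()
                m = scen.model
                world = {
                    "b": tip_w + m.ab * u,
                    "c": tip_w + m.ac * u,
                    "d": tip_w + m.ad * u,
                }
                cam = {k: pose.transform(v) for k, v in world.items()}
                tip_cam = pose.transform(tip_w)
                gt.instrument_present = True
                gt.markers_cam_mm = cam
                gt.marker_px = {k: project_point(self.intr, v) for k, v in cam.items()}
                gt.tip_3d_mm = tip_cam
                gt.tip_px = project_point(self.intr, tip_cam)
        return gt

    def _render_plane(self, pose: Pose3D) -> np.ndarray:
        """Membrane + canal planes for one camera pose (float RGB)."""
        spec = self.spec
        w, h = spec.frame_size
        Hw0 = self._world_to_image_h(pose, 0.0)
        Hw1 = self._world_to_image_h(pose, spec.canal_depth_offset_mm)
        inv_mem = ProjectiveTransform(
            np.linalg.inv(Hw0 @ np.linalg.inv(self.A_mm2tex))
        )
        inv_can = ProjectiveTransform(
            np.linalg.inv(Hw1 @ np.linalg.inv(self.A_mm2tex))
        )
        mem = warp(self.membrane_tex, inv_mem, output_shape=(h, w), order=3,
                   mode="constant", cval=0.15)
        alpha = warp(self.membrane_alpha, inv_mem, output_shape=(h, w), order=1,
                     mode="constant", cval=0.0)
        can = warp(self.canal_tex, inv_can, output_shape=(h, w), order=1,
                   mode="constant", cval=0.12)
        gray = alpha * mem + (1.0 - alpha) * can
        return gray[:, :, None] * _MEMBRANE_TINT[None, None, :]

    def _jerk_exposure(self, t: float) -> np.ndarray:
        """Motion-blurred exposure across the instantaneous pose jump:
        the frame integrates sub-exposures along the jump path."""
        spec = self.spec
        traj = spec.trajectory
        pre = traj.pose(traj.jerk_time_s - 1e-6, spec.working_distance_mm)
        post = traj.pose(t, spec.working_distance_mm)
        acc = None
        for s in np.linspace(0.0, 1.0, 6):
            trans = pre.translation + s * (post.translation - pre.translation)
            sub = Pose3D(rotation=post.rotation, translation=trans)
            img = self._render_plane(sub)
            acc = img if acc is None else acc + img
        return acc / 6.0

    def render(self, frame_index: int) -> tuple[np.ndarray, FrameGroundTruth]:
        spec = self.spec
        gt = self.truth_at(frame_index)
        t = gt.time_s
        traj = spec.trajectory
        pose = traj.pose(t, spec.working_distance_mm)
        jerk_cross = (
            traj.speed_class == "jerk"
            and traj.jerk_time_s is not None
            and (t - 1.0 / spec.fps) < traj.jerk_time_s <= t
        )
        img = self._jerk_exposure(t) if jerk_cross else self._render_plane(pose)

        deg = spec.degradations
        if gt.instrument_present:
            img = self._composite_instrument(img, gt, pose, deg)

        for ev in deg.ink_events:
            if t >= ev.time_s:
                center = pose.transform(np.array([*ev.center_mm, 0.0]))
                cpx = project_point(self.intr, center)
                r_px = ev.radius_mm * self.intr.focal_px / center[2]
                _blend_soft_disc_rgb(img, cpx[0], cpx[1], r_px,
                                     (0.35, 0.04, 0.05), ev.opacity, softness=4.0)

        img = img * deg.gain(t)
        if deg.frame_blur_sigma > 0:
            img = gaussian_filter(img, (deg.frame_blur_sigma, deg.frame_blur_sigma, 0))
        rng = np.random.default_rng([spec.seed, 1009, frame_index])
        if deg.noise_sigma > 0:
            img = img + rng.normal(0.0, deg.noise_sigma / 255.0, img.shape)
        out = np.clip(img * 255.0, 0, 255).round().astype(np.uint8)
        return out, gt

    def _composite_instrument(self, img, gt, pose, deg) -> np.ndarray:
        spec = self.spec
        h, w = img.shape[:2]
        layer = np.zeros((h, w, 3))
        lalpha = np.zeros((h, w))
        scen = spec.instrument
        m = scen.model
        u = scen.axis_world()
        tip_w = pose.rotation.T @ (gt.tip_3d_mm - pose.translation)
        handle_w = tip_w + (m.ad + 30.0) * u
        handle_cam = pose.transform(handle_w)
        tip_px = gt.tip_px
        handle_px = project_point(self.intr, handle_cam)
        z_tip = gt.tip_3d_mm[2]
        shaft_r_px = scen.shaft_radius_mm * self.intr.focal_px / z_tip
        _draw_capsule(layer, lalpha, tip_px, handle_px, shaft_r_px, (0.62, 0.6, 0.55))
        for idx, lbl in enumerate(("b", "c", "d")):
            p = gt.marker_px[lbl]
            z = gt.markers_cam_mm[lbl][2]
            r_px = scen.marker_radius_mm * self.intr.focal_px / z
            _draw_disc_rgb(layer, lalpha, p[0], p[1], r_px, _MARKER_COLOR_TABLE[idx])
        if deg.marker_blur_sigma > 0:
            s = deg.marker_blur_sigma
            layer = gaussian_filter(layer, (s, s, 0))
            lalpha = gaussian_filter(lalpha, s)
        return img * (1.0 - lalpha[:, :, None]) + layer * lalpha[:, :, None]


@lru_cache(maxsize=4)
def _realize(spec: SceneSpec) -> _Realization:
    return _Realization(spec)


# ---------------------------------------------------------------------- #
# Soft rasterization helpers (1 px anti-aliased edges so centroids are
# sub-pixel accurate)
# ---------------------------------------------------------------------- #


def _coverage(xx, yy, cx, cy, radius, softness=1.0):
    d = np.hypot(xx - cx, yy - cy)
    return np.clip((radius - d) / softness + 0.5, 0.0, 1.0)


def _disc_window(shape, cx, cy, radius):
    h, w = shape[:2]
    x0 = max(int(cx - radius) - 3, 0)
    x1 = min(int(cx + radius) + 4, w)
    y0 = max(int(cy - radius) - 3, 0)
    y1 = min(int(cy + radius) + 4, h)
    if x0 >= x1 or y0 >= y1:
        return None
    yy, xx = np.mgrid[y0:y1, x0:x1].astype(float)
    return (slice(y0, y1), slice(x0, x1)), xx, yy


def _draw_soft_disc(img, cx, cy, radius, value, softness=1.0):
    win = _disc_window(img.shape, cx, cy, radius)
    if win is None:
        return
    sl, xx, yy = win
    a = _coverage(xx, yy, cx, cy, radius, softness)
    img[sl] = img[sl] * (1.0 - a) + value * a


def _draw_disc_rgb(color_buf, alpha_buf, cx, cy, radius, color):
    win = _disc_window(alpha_buf.shape, cx, cy, radius)
    if win is None:
        return
    sl, xx, yy = win
    a = _coverage(xx, yy, cx, cy, radius)
    for k in range(3):
        color_buf[sl + (k,)] = color_buf[sl + (k,)] * (1.0 - a) + color[k] * a
    alpha_buf[sl] = np.maximum(alpha_buf[sl], a)


def _blend_soft_disc_rgb(img, cx, cy, radius, color, opacity, softness=1.0):
    win = _disc_window(img.shape, cx, cy, radius)
    if win is None:
        return
    sl, xx, yy = win
    a = opacity * _coverage(xx, yy, cx, cy, radius, softness)
    img[sl] = img[sl] * (1.0 - a[:, :, None]) + np.asarray(color) * a[:, :, None]


def _draw_capsule(color_buf, alpha_buf, p0, p1, radius, color):
    """Anti-aliased thick segment (tool shaft) into a colour+alpha layer."""
    h, w = alpha_buf.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    v = np.asarray(p1, float) - np.asarray(p0, float)
    L2 = float(v @ v)
    if L2 < 1e-12:
        return
    tt = np.clip(((xx - p0[0]) * v[0] + (yy - p0[1]) * v[1]) / L2, 0.0, 1.0)
    d = np.hypot(xx - (p0[0] + tt * v[0]), yy - (p0[1] + tt * v[1]))
    a = np.clip(radius - d + 0.5, 0.0, 1.0)
    mask = a > 0
    for k in range(3):
        color_buf[:, :, k] = np.where(mask, color[k], color_buf[:, :, k])
    alpha_buf[:] = np.maximum(alpha_buf, a)


# ---------------------------------------------------------------------- #
# Public dataset API
# ---------------------------------------------------------------------- #


class _LazyFrames:
    """Sequence of rendered frames, computed on demand (deterministic)."""

    def __init__(self, real: _Realization) -> None:
        self._real = real
        self._n = real.spec.n_frames

    def __len__(self) -> int:
        return self._n

    def __getitem__(self, i: int) -> np.ndarray:
        if isinstance(i, slice):
            return [self[j] for j in range(*i.indices(self._n))]
        if i < 0:
            i += self._n
        if not 0 <= i < self._n:
            raise IndexError(i)
        return self._real.render(i)[0]

    def __iter__(self):
        for i in range(self._n):
            yield self[i]


class SyntheticDataset:
    """Rendered frame sequence + exact truths + CT-render analog."""

    def __init__(self, spec: SceneSpec) -> None:
        self.spec = spec
        self._real = _realize(spec)
        self.intrinsics = self._real.intr
        self.frames = _LazyFrames(self._real)
        self.truths = [self._real.truth_at(i) for i in range(spec.n_frames)]
        self.ct_render = self._real.ct_render
        self.ct_marker_px = self._real.ct_marker_px
        self.H_ref_to_ct = self._real.H_ref2ct
        self.reference_fiducials_px = self._real.ref_fiducial_px
        self.fiducials_mm = self._real.fiducials_mm

    def __len__(self) -> int:
        return len(self.frames)

    def frame(self, i: int) -> np.ndarray:
        return self.frames[i]

    def with_spec(self, **changes) -> "SyntheticDataset":
        return SyntheticDataset(replace(self.spec, **changes))


def render_frame(spec: SceneSpec, t: float) -> tuple[np.ndarray, FrameGroundTruth]:
    """Render the frame nearest to time ``t`` (seconds) with its truth."""
    if not 0.0 <= t < spec.duration_s:
        raise ConfigError(f"t={t} outside trajectory duration [0, {spec.duration_s})")
    return _realize(spec).render(int(round(t * spec.fps)))


def simulate_dataset(spec: SceneSpec) -> SyntheticDataset:
    """Materialize the dataset view of a scene spec (frames stay lazy)."""
    return SyntheticDataset(spec)
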