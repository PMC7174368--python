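"""Constant-velocity Kalman filtering of 2D marker centre points.

Defocus and segmentation jitter degrade the raw colour-blob centroids; a
per-marker linear Kalman filter with a constant-velocity motion model
smooths them. State is ``(x, y, vx, vy)`` in pixels and pixels/second;
process noise follows the standard white-acceleration discretization. The
covariance update uses the Joseph form, which preserves symmetry and
positive-definiteness in floating point.
"""

from __future__ import annotations

import numpy as np

from .exceptions import OtoARError

__all__ = ["ConstantVelocityKalman", "MarkerFilterBank"]


class ConstantVelocityKalman:
    """2D constant-velocity Kalman filter for one marker.

    Parameters
    ----------
    initial_xy:
        First observed position (px); velocity is initialized to zero.
    sigma_accel:
        White-acceleration process noise, px/s^2.
    sigma_meas:
        Measurement noise standard deviation, px.
    initial_pos_var, initial_vel_var:
        Diagonal prior variances.
    """

    def __init__(
        self,
        initial_xy,
        sigma_accel: float = 1500.0,
        sigma_meas: float = 0.5,
        initial_pos_var: float = 4.0,
        initial_vel_var: float = 400.0,
    ) -> None:
        x, y = np.asarray(initial_xy, dtype=float)
        self.x = np.array([x, y, 0.0, 0.0])
        self.P = np.diag([initial_pos_var, initial_pos_var, initial_vel_var, initial_vel_var])
        self.sigma_accel = float(sigma_accel)
        self.R = float(sigma_meas) ** 2 * np.eye(2)
        self.H = np.array([[1.0, 0.0, 0.0, 0.0], [0.0, 1.0, 0.0, 0.0]])

    @property
    def position(self) -> np.ndarray:
        return self.x[:2].copy()

    @property
    def velocity(self) -> np.ndarray:
        return self.x[2:].copy()

    def _fq(self, dt: float):
        F = np.eye(4)
        F[0, 2] = F[1, 3] = dt
        q = self.sigma_accel**2
        d4, d3, d2 = dt**4 / 4.0, dt**3 / 2.0, dt**2
        Q = q * np.array(
            [
                [d4, 0.0, d3, 0.0],
                [0.0, d4, 0.0, d3],
                [d3, 0.0, d2, 0.0],
                [0.0, d3, 0.0, d2],
            ]
        )
        return F, Q

    def predict(self, dt: float) -> np.ndarray:
        F, Q = self._fq(dt)
        self.x = F @ self.x
        self.P = F @ self.P @ F.T + Q
        self.P = 0.5 * (self.P + self.P.T)
        return self.position

    def update(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        S = self.H @ self.P @ self.H.T + self.R
        K = self.P @ self.H.T @ np.linalg.inv(S)
        self.x = self.x + K @ (z - self.H @ self.x)
        ikh = np.eye(4) - K @ self.H
        # Joseph form keeps P symmetric positive-definite.
        self.P = ikh @ self.P @ ikh.T + K @ self.R @ K.T
        self.P = 0.5 * (self.P + self.P.T)
        self._check_pd()
        return self.position

    def step(self, z, dt: float) -> np.ndarray:
        """Predict over ``dt`` then update with ``z`` (or predict only if
        ``z`` is None). Returns the posterior position."""
        self.predict(dt)
        if z is not None:
            self.update(z)
        return self.position

    def _check_pd(self) -> None:
        if not np.all(np.isfinite(self.P)):
            raise OtoARError("Kalman covariance became non-finite")
        eigmin = np.linalg.eigvalsh(self.P).min()
        if eigmin <= 0:
            raise OtoARError(f"Kalman covariance lost positive-definiteness ({eigmin})")


class MarkerFilterBank:
    """Independent constant-velocity filters for the three tool markers.

    Markers are keyed by their colour index (the detector reports one
    candidate per configured colour), so identity is maintained even when
    a marker drops out and only its prediction is available.
    """

    def __init__(self, sigma_accel: float = 1500.0, sigma_meas: float = 0.5) -> None:
        self.sigma_accel = sigma_accel
        self.sigma_meas = sigma_meas
        self.filters: dict[int, ConstantVelocityKalman] = {}

    def step(self, observations: dict[int, np.ndarray | None], dt: float) -> dict[int, np.ndarray]:
        """Advance all filters by ``dt``.

        ``observations`` maps colour index -> observed centre (px) or None
        when that marker was not detected this frame. Unseen keys are
        initialized on first observation. Returns refined positions.
        """
        refined: dict[int, np.ndarray] = {}
        for key, z in observations.items():
            if key not in self.filters:
                if z is None:
                    continue
                self.filters[key] = ConstantVelocityKalman(
                    z, sigma_accel=self.sigma_accel, sigma_meas=self.sigma_meas
                )
                refined[key] = self.filters[key].position
            else:
                refined[key] = self.filters[key].step(z, dt)
        return refined

    def reset(self) -> None:
        self.filters.clear()
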