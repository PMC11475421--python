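"""Constant-velocity Kalman filtering on a 7-D bounding-box state.

The state is x = (u, v, s, r, u', v', s'): box center (u, v) in px, area
s in px^2, aspect ratio r (width/height, held constant by the motion
model), and per-frame rates of the first three. Observations are
z = (u, v, s, r) converted from a corner-format box. The time step is
one frame throughout.

Lost-and-recovered tracks are repaired by re-running the filter along a
linearly interpolated *virtual trajectory* spanning the gap between the
last real observation and the re-associated one (observation-centric
re-update), which removes the error the filter accumulates while
predicting blind.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Observation",
    "KalmanState",
    "NoiseModel",
    "BoxKalmanFilter",
    "box_to_z",
    "z_to_box",
    "make_virtual_trajectory",
]

_PSD_TOL = 1e-8


def box_to_z(box) -> np.ndarray:
    """Convert (left, top, width, height) to (u, v, s, r)."""
    l, t, w, h = box
    if w <= 0 or h <= 0:
        raise ValueError(f"box must have positive size, got {box}")
    return np.array([l + w / 2.0, t + h / 2.0, w * h, w / h], dtype=float)


def z_to_box(z) -> tuple[float, float, float, float]:
    """Convert (u, v, s, r) back to (left, top, width, height)."""
    u, v, s, r = np.asarray(z, dtype=float)
    w = float(np.sqrt(max(s, 1e-12) * max(r, 1e-12)))
    h = float(np.sqrt(max(s, 1e-12) / max(r, 1e-12)))
    return (u - w / 2.0, v - h / 2.0, w, h)


Observation = np.ndarray  # shape (4,): (u, v, s, r)


@dataclass
class KalmanState:
    """Gaussian state belief: mean (7,) and covariance (7, 7)."""

    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).reshape(7)
        self.covariance = np.asarray(self.covariance, dtype=float).reshape(7, 7)

    def validate(self) -> None:
        P = self.covariance
        if not np.allclose(P, P.T, atol=1e-9):
            raise ValueError("covariance is not symmetric")
        if np.min(np.linalg.eigvalsh((P + P.T) / 2.0)) < -_PSD_TOL:
            raise ValueError("covariance is not positive semi-definite")

    def box(self) -> tuple[float, float, float, float]:
        return z_to_box(self.mean[:4])


def _default_F() -> np.ndarray:
    F = np.eye(7)
    F[0, 4] = F[1, 5] = F[2, 6] = 1.0  # u+=u', v+=v', s+=s'; r has no rate
    return F


def _default_H() -> np.ndarray:
    return np.eye(4, 7)


@dataclass
class NoiseModel:
    """Transition/observation matrices and noise covariances.

    Defaults follow the SORT family: observation noise 1 px^2 on centers
    and 10 on (area, aspect); small process noise, smallest on the area
    rate, which otherwise destabilizes long predictions.
    """

    F: np.ndarray = field(default_factory=_default_F)
    H: np.ndarray = field(default_factory=_default_H)
    Q: np.ndarray = field(default_factory=lambda: np.diag([1.0, 1.0, 1.0, 1.0, 1e-2, 1e-2, 1e-4]))
    R: np.ndarray = field(default_factory=lambda: np.diag([1.0, 1.0, 10.0, 10.0]))
    initial_position_var: float = 10.0
    initial_velocity_var: float = 1e4

    def __post_init__(self) -> None:
        for name in ("F", "H", "Q", "R"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))


class BoxKalmanFilter:
    """Stateless predict/update/re-update operations for one noise model."""

    def __init__(self, model: NoiseModel | None = None):
        self.model = model if model is not None else NoiseModel()

    # -- lifecycle ---------------------------------------------------------

    def initiate(self, z: Observation) -> KalmanState:
        """State for a newly born track: mean from z, zero velocities,
        large velocity uncertainty (velocities are unobserved at birth)."""
        m = self.model
        mean = np.zeros(7)
        mean[:4] = z
        P = np.diag(
            [m.initial_position_var] * 4 + [m.initial_velocity_var] * 3
        ).astype(float)
        return KalmanState(mean, P)

    # -- core recursion ----------------------------------------------------

    def predict(self, state: KalmanState) -> KalmanState:
        """Propagate one frame: mean' = F mean, P' = F P F^T + Q.

        If the predicted area would go non-positive, the area rate is
        zeroed first so the box stays valid during long occlusions.
        """
        state.validate()
        m = self.model
        mean = state.mean.copy()
        if mean[2] + mean[6] <= 0:
            mean[6] = 0.0
        mean = m.F @ mean
        P = m.F @ state.covariance @ m.F.T + m.Q
        return KalmanState(mean, (P + P.T) / 2.0)

    def update(self, state: KalmanState, z: Observation) -> KalmanState:
        """Condition the prior on observation z (standard Kalman update)."""
        m = self.model
        z = np.asarray(z, dtype=float).reshape(4)
        P = state.covariance
        S = m.H @ P @ m.H.T + m.R
        cond = np.linalg.cond(S)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError(
                f"innovation covariance ill-conditioned (cond={cond:.3e})"
            )
        K = P @ m.H.T @ np.linalg.inv(S)
        mean = state.mean + K @ (z - m.H @ state.mean)
        Pn = (np.eye(7) - K @ m.H) @ P
        return KalmanState(mean, (Pn + Pn.T) / 2.0)

    def re_update(
        self,
        state_at_t1: KalmanState,
        virtual: list[Observation],
        z_t2: Observation,
    ) -> KalmanState:
        """Replay the filter from the last pre-gap posterior to t2.

        Runs predict+update once per virtual observation (in order), then
        once for the real re-associated observation ``z_t2``. With an
        empty virtual sequence this is an ordinary predict+update.
        """
        state = state_at_t1
        for z_bar in virtual:
            state = self.update(self.predict(state), z_bar)
        return self.update(self.predict(state), z_t2)


def make_virtual_trajectory(
    z_t1: Observation, z_t2: Observation, t1: int, t2: int
) -> list[Observation]:
    """Linearly interpolated observations for the interior frames t1 < t < t2.

    Component-wise interpolation in (u, v, s, r) at fraction
    (t - t1) / (t2 - t1). Returns [] when the gap has no interior frames.
    """
    z1 = np.asarray(z_t1, dtype=float)
    z2 = np.asarray(z_t2, dtype=float)
    if t2 <= t1 + 1:
        return []
    return [z1 + (z2 - z1) * ((t - t1) / (t2 - t1)) for t in range(t1 + 1, t2)]
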