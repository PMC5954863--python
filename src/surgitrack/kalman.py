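"""Kalman filtering primitives and federated (local/master) fusion.

Each tracked object carries two *local* filters — one fed by segmentation
measurements, one by template-matching measurements — over a shared
constant-velocity state (px, py, vx, vy).  A *master* estimate fuses the
local posteriors by information weighting:

    P_m = (P_1^{-1} + P_2^{-1})^{-1},   x_m = P_m (P_1^{-1} x_1 + P_2^{-1} x_2)

This is the reset-free federated variant: the master never feeds back into
the locals, so a faulty measurement stream cannot contaminate the other.
A local that has been coasting (predict-only) for too long is excluded from
the fusion.

Robustness devices:
* gating — a measurement whose innovation exceeds a Euclidean gate radius
  is treated as absent (outlier rejection);
* adaptive gain — the measurement covariance is inflated quadratically with
  the jump distance from the previous position, so large jumps are trusted
  less: R_eff = R0 * (1 + (dist/d_ref)^2).

Updates use the Joseph form to preserve covariance symmetry/PSD.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "KalmanState",
    "constant_velocity_state",
    "predict",
    "update",
    "adapt_gain",
    "gate_measurement",
    "local_update",
    "fuse_estimates",
]


@dataclass
class KalmanState:
    """Generic linear-Gaussian filter state (x, P) with model matrices."""

    x: np.ndarray
    P: np.ndarray
    F: np.ndarray
    Q: np.ndarray
    H: np.ndarray
    R: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.atleast_1d(np.asarray(self.x, dtype=float))
        for name in ("P", "F", "Q", "H", "R"):
            setattr(self, name, np.atleast_2d(np.asarray(getattr(self, name), dtype=float)))

    @property
    def position(self) -> tuple[float, float]:
        return float(self.x[0]), float(self.x[1])


def constant_velocity_state(
    x0: float,
    y0: float,
    q_pos: float = 1.0,
    q_vel: float = 4.0,
    r0: float = 9.0,
    p0_pos: float = 25.0,
    p0_vel: float = 25.0,
) -> KalmanState:
    """4-state constant-velocity model observing position only.

    Units: pixels and pixels/frame; Q and R defaults in px^2.
    """
    F = np.array(
        [[1, 0, 1, 0], [0, 1, 0, 1], [0, 0, 1, 0], [0, 0, 0, 1]], dtype=float
    )
    H = np.array([[1, 0, 0, 0], [0, 1, 0, 0]], dtype=float)
    return KalmanState(
        x=np.array([x0, y0, 0.0, 0.0]),
        P=np.diag([p0_pos, p0_pos, p0_vel, p0_vel]).astype(float),
        F=F,
        Q=np.diag([q_pos, q_pos, q_vel, q_vel]).astype(float),
        H=H,
        R=np.eye(2) * r0,
    )


def predict(state: KalmanState) -> KalmanState:
    """Time update: x ← Fx, P ← FPFᵀ + Q."""
    x = state.F @ state.x
    P = state.F @ state.P @ state.F.T + state.Q
    return replace(state, x=x, P=0.5 * (P + P.T))


def update(
    state: KalmanState, z: np.ndarray, R_eff: np.ndarray | None = None
) -> KalmanState:
    """Measurement update in Joseph form (symmetry/PSD-preserving)."""
    z = np.atleast_1d(np.asarray(z, dtype=float))
    if not np.all(np.isfinite(z)):
        raise ValueError(f"non-finite measurement {z}")
    R = state.R if R_eff is None else np.atleast_2d(R_eff)
    H = state.H
    S = H @ state.P @ H.T + R
    K = state.P @ H.T @ np.linalg.inv(S)
    x = state.x + K @ (z - H @ state.x)
    I_KH = np.eye(state.P.shape[0]) - K @ H
    P = I_KH @ state.P @ I_KH.T + K @ R @ K.T
    return replace(state, x=x, P=0.5 * (P + P.T))


def adapt_gain(
    R0: np.ndarray,
    measurement: tuple[float, float],
    prev_position: tuple[float, float],
    d_ref: float = 32.0,
) -> np.ndarray:
    """Inflate R with the squared jump from the previous position.

    R_eff = R0 * (1 + (dist/d_ref)^2): a zero jump keeps R0; a jump of
    d_ref doubles it; trust decreases monotonically with jump size.
    """
    dist = float(np.hypot(measurement[0] - prev_position[0],
                          measurement[1] - prev_position[1]))
    return np.atleast_2d(np.asarray(R0, dtype=float)) * (1.0 + (dist / d_ref) ** 2)


def gate_measurement(
    state: KalmanState, measurement: tuple[float, float], gate_radius: float = 64.0
) -> bool:
    """Accept iff the Euclidean innovation is within the (closed) gate."""
    zpred = state.H @ state.x
    innov = float(np.hypot(measurement[0] - zpred[0], measurement[1] - zpred[1]))
    return innov <= gate_radius


def local_update(
    state: KalmanState,
    measurement: tuple[float, float] | None,
    gate_radius: float = 64.0,
    prev_position: tuple[float, float] | None = None,
    d_ref: float = 32.0,
) -> tuple[KalmanState, bool]:
    """Predict, then update if the measurement exists and passes the gate.

    Returns the new state and whether the measurement was accepted.  The
    measurement covariance is scaled by the adaptive-gain rule relative to
    ``prev_position`` when given.
    """
    state = predict(state)
    if measurement is None:
        return state, False
    if not np.all(np.isfinite(np.asarray(measurement, dtype=float))):
        raise ValueError(f"non-finite measurement {measurement}")
    if not gate_measurement(state, measurement, gate_radius):
        return state, False
    R_eff = None
    if prev_position is not None:
        R_eff = adapt_gain(state.R, measurement, prev_position, d_ref)
    return update(state, np.asarray(measurement, dtype=float), R_eff), True


def fuse_estimates(
    estimates: list[tuple[np.ndarray, np.ndarray]]
) -> tuple[np.ndarray, np.ndarray]:
    """Information-weighted fusion of (x, P) estimates.

    With one estimate the master equals it; with several,
    P_m = (Σ P_i^{-1})^{-1} and x_m = P_m Σ P_i^{-1} x_i.
    Raises ``np.linalg.LinAlgError`` on singular covariance.
    """
    if not estimates:
        raise ValueError("no estimates to fuse")
    if len(estimates) == 1:
        x, P = estimates[0]
        return np.array(x, dtype=float), np.array(P, dtype=float)
    infos = [np.linalg.inv(np.asarray(P, dtype=float)) for _, P in estimates]
    info_sum = np.sum(infos, axis=0)
    P_m = np.linalg.inv(info_sum)
    x_m = P_m @ np.sum(
        [Ii @ np.asarray(x, dtype=float) for (x, _), Ii in zip(estimates, infos)],
        axis=0,
    )
    return x_m, 0.5 * (P_m + P_m.T)
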