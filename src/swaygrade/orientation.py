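"""Raw 6-axis IMU signals to body-segment pitch/roll orientation.

Static sensor-to-segment alignment uses the gravity direction during quiet
standing; orientation tracking is a multiplicative extended Kalman filter
(quaternion state, 3-dimensional attitude-error covariance) that integrates
the gyroscope and corrects tilt with the accelerometer as a gravity
reference. Yaw is unobservable without a magnetometer and is never consumed
downstream — only pitch (anterior-posterior tilt, about the left-right axis)
and roll (medial-lateral tilt, about the forward axis) are extracted, via a
ZYX Euler decomposition of the quaternion.

The filter is implemented batched over recordings: one pass runs N
recordings in lock-step, so a whole cohort is filtered with a single loop
over time samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .synthetic import GRAVITY, IMURecording

G_WORLD = np.array([0.0, 0.0, -GRAVITY])


@dataclass(frozen=True)
class AlignmentRotation:
    """Rotation mapping the sensor frame onto the anatomical segment frame."""

    rotation: np.ndarray  # (3, 3)

    def __post_init__(self):
        r = np.asarray(self.rotation, dtype=float)
        if r.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal")
        if not np.isclose(np.linalg.det(r), 1.0, atol=1e-9):
            raise ValueError("rotation must be proper (det = +1)")
        object.__setattr__(self, "rotation", r)

    @classmethod
    def identity(cls) -> "AlignmentRotation":
        return cls(np.eye(3))


@dataclass
class SegmentOrientation:
    """Pitch/roll angle time series for one body segment."""

    placement: str
    pitch: np.ndarray  # rad, anterior-posterior tilt
    roll: np.ndarray  # rad, medial-lateral tilt
    sample_rate: float

    def __post_init__(self):
        self.pitch = np.asarray(self.pitch, dtype=float)
        self.roll = np.asarray(self.roll, dtype=float)
        if self.pitch.shape != self.roll.shape:
            raise ValueError("pitch and roll must have equal length")

    def __len__(self) -> int:
        return len(self.pitch)


@dataclass(frozen=True)
class EKFParams:
    """Noise settings for the orientation filter (engineering defaults)."""

    gyro_noise_sd: float = 0.005  # rad/s
    accel_noise_sd: float = 0.05  # m/s^2
    initial_state_sd: float = 0.1  # rad
    gravity: float = GRAVITY

    def __post_init__(self):
        if min(self.gyro_noise_sd, self.accel_noise_sd,
               self.initial_state_sd) <= 0:
            raise ValueError("noise standard deviations must be positive")


def _minimal_rotation(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Smallest-angle rotation matrix carrying unit vector u onto v."""
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    c = float(np.dot(u, v))
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about any axis orthogonal to u
        ortho = np.array([1.0, 0.0, 0.0])
        if abs(u[0]) > 0.9:
            ortho = np.array([0.0, 1.0, 0.0])
        axis = np.cross(u, ortho)
        axis /= np.linalg.norm(axis)
        return Rotation.from_rotvec(np.pi * axis).as_matrix()
    angle = np.arctan2(s, c)
    return Rotation.from_rotvec(angle * axis / s).as_matrix()


def static_alignment(recording: IMURecording,
                     calibration_window: float) -> AlignmentRotation:
    """Sensor-to-segment rotation from a quiet-standing calibration window.

    The mean accelerometer vector over the window is taken as the gravity
    direction; the returned rotation is the minimal rotation mapping it onto
    the segment-frame gravity axis (0, 0, -g). Yaw about gravity is left
    unconstrained by this construction (fixed at zero by minimality).
    """
    if calibration_window <= 0:
        raise ValueError("calibration_window must be positive")
    n = int(round(calibration_window * recording.sample_rate))
    if n < 1 or n > len(recording):
        raise ValueError("calibration window outside the recording")
    mean_a = recording.accel[:n].mean(axis=0)
    norm = np.linalg.norm(mean_a)
    if abs(norm - GRAVITY) > 0.2 * GRAVITY:
        raise ValueError(
            f"mean accel norm {norm:.2f} departs from gravity by >20%; "
            "motion during the calibration window?")
    return AlignmentRotation(_minimal_rotation(mean_a, G_WORLD))


def _init_orientation(accel0: np.ndarray) -> Rotation:
    """Initial segment-to-world rotation from the first gravity samples."""
    n = accel0.shape[0]
    mats = np.empty((n, 3, 3))
    for i in range(n):
        norm = np.linalg.norm(accel0[i])
        if norm < 1e-9:
            mats[i] = np.eye(3)
        else:
            # R maps sensor->world and must satisfy R a0 = g_world direction
            mats[i] = _minimal_rotation(accel0[i] / norm,
                                        G_WORLD / GRAVITY)
    return Rotation.from_matrix(mats)


def ekf_orientation_batch(accel: np.ndarray, gyro: np.ndarray,
                          sample_rate: float,
                          params: EKFParams | None = None) -> tuple:
    """Run the orientation filter on N recordings in lock-step.

    Parameters
    ----------
    accel, gyro : (N, T, 3) arrays in the (aligned) segment frame.
    sample_rate : Hz.

    Returns
    -------
    pitch, roll : (N, T) arrays, radians.
    """
    params = params or EKFParams()
    accel = np.asarray(accel, dtype=float)
    gyro = np.asarray(gyro, dtype=float)
    if accel.ndim != 3 or accel.shape != gyro.shape or accel.shape[-1] != 3:
        raise ValueError("accel and gyro must both be (N, T, 3)")
    if not (np.isfinite(accel).all() and np.isfinite(gyro).all()):
        raise ValueError("non-finite values in input channels")
    n_rec, n_t, _ = accel.shape
    dt = 1.0 / sample_rate

    rot = _init_orientation(accel[:, 0, :])
    eye3 = np.eye(3)
    P = np.broadcast_to(params.initial_state_sd ** 2 * eye3,
                        (n_rec, 3, 3)).copy()
    Q = (params.gyro_noise_sd * dt) ** 2 * eye3
    r_meas = params.accel_noise_sd ** 2

    quats = np.empty((n_t, n_rec, 4))
    quats[0] = rot.as_quat()
    for k in range(1, n_t):
        step = Rotation.from_rotvec(gyro[:, k - 1, :] * dt)
        rot = rot * step
        phi = step.inv().as_matrix()  # body-frame error propagation
        P = phi @ P @ phi.transpose(0, 2, 1) + Q

        g_s = rot.inv().apply(G_WORLD)  # predicted gravity, sensor frame
        # H = [g_s]x : attitude error couples into the gravity measurement
        H = np.zeros((n_rec, 3, 3))
        H[:, 0, 1] = -g_s[:, 2]
        H[:, 0, 2] = g_s[:, 1]
        H[:, 1, 0] = g_s[:, 2]
        H[:, 1, 2] = -g_s[:, 0]
        H[:, 2, 0] = -g_s[:, 1]
        H[:, 2, 1] = g_s[:, 0]
        S = H @ P @ H.transpose(0, 2, 1) + r_meas * eye3
        K = P @ H.transpose(0, 2, 1) @ np.linalg.inv(S)
        innov = accel[:, k, :] - g_s
        dtheta = np.einsum("nij,nj->ni", K, innov)
        rot = rot * Rotation.from_rotvec(dtheta)
        P = (eye3 - K @ H) @ P
        quats[k] = rot.as_quat()

    eul = Rotation.from_quat(quats.reshape(-1, 4)).as_euler("zyx")
    eul = eul.reshape(n_t, n_rec, 3)
    pitch = eul[:, :, 1].T.copy()
    roll = eul[:, :, 2].T.copy()
    return pitch, roll


def ekf_orientation(recording: IMURecording,
                    alignment: AlignmentRotation | None = None,
                    params: EKFParams | None = None) -> SegmentOrientation:
    """Orientation estimate for a single recording.

    The alignment rotation is applied to both accelerometer and gyroscope
    channels before filtering; output is sample-aligned with the input.
    """
    a = recording.accel
    g = recording.gyro
    if alignment is not None:
        a = a @ alignment.rotation.T
        g = g @ alignment.rotation.T
    pitch, roll = ekf_orientation_batch(a[None], g[None],
                                        recording.sample_rate, params)
    return SegmentOrientation(placement=recording.placement,
                              pitch=pitch[0], roll=roll[0],
                              sample_rate=recording.sample_rate)


def gyro_integration_oracle(gyro: np.ndarray, sample_rate: float,
                            initial: Rotation | None = None) -> tuple:
    """Pure gyro dead-reckoning reference (no gravity correction).

    Independent oracle for filter consistency tests: integrates the body
    angular rate sample by sample and returns (pitch, roll) in radians.
    """
    n = gyro.shape[0]
    dt = 1.0 / sample_rate
    rot = initial if initial is not None else Rotation.identity()
    out = np.empty((n, 3))
    out[0] = rot.as_euler("zyx")
    for k in range(1, n):
        rot = rot * Rotation.from_rotvec(gyro[k - 1] * dt)
        out[k] = rot.as_euler("zyx")
    return out[:, 1], out[:, 2]


def clip_repetition(orientation: SegmentOrientation, start: float,
                    duration: float = 30.0) -> SegmentOrientation:
    """Clip an orientation series to one exercise repetition window."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    i0 = int(round(start * orientation.sample_rate))
    n = int(round(duration * orientation.sample_rate))
    if i0 < 0 or i0 + n > len(orientation):
        raise ValueError("clip window exceeds the recording")
    return SegmentOrientation(
        placement=orientation.placement,
        pitch=orientation.pitch[i0:i0 + n].copy(),
        roll=orientation.roll[i0:i0 + n].copy(),
        sample_rate=orientation.sample_rate)


def write_orientation_csv(orientation: SegmentOrientation, path) -> None:
    """Write one repetition's orientation as a CSV (t, pitch, roll)."""
    import pandas as pd

    t = np.arange(len(orientation)) / orientation.sample_rate
    pd.DataFrame({"t": t, "pitch": orientation.pitch,
                  "roll": orientation.roll}).to_csv(
        path, index=False, float_format="%.8f")
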