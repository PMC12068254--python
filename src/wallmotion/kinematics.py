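"""Kinematic feature extraction from 3D wall-point trajectories.

A trajectory is converted into the 5-channel feature series the network
consumes: speed (mm/s), acceleration magnitude (mm/s^2), and the
smoothness-of-motion angles at each point between its temporal neighbours,
projected onto the XY, XZ and YZ coordinate planes (radians, in [0, pi];
pi means locally straight motion).

Conventions (the finite-difference scheme and channel alignment are fixed
here for determinism):

* speed_t   = ||p_{t+1} - p_t|| * rate                (forward difference)
* accel_t   = ||p_{t+1} - 2 p_t + p_{t-1}|| * rate^2  (central second difference)
* angle_t   = vertex angle at p_t between segments to p_{t-1} and p_{t+1}
  in each projection plane; a projected segment shorter than 1e-9 mm yields
  pi (a motionless point reads as maximally smooth)
* channels are aligned to length L = T - 2 by dropping the first speed sample.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import CubicSpline

from .exceptions import ConfigError, DataError
from .io import Trajectory

CHANNEL_NAMES = ("speed", "accel", "angle_xy", "angle_xz", "angle_yz")
_PLANES = {"angle_xy": (0, 1), "angle_xz": (0, 2), "angle_yz": (1, 2)}
_DEGENERATE_SEGMENT = 1e-9  # mm


@dataclass
class FeatureSeries:
    """5 x L kinematic feature matrix for one trajectory."""

    values: np.ndarray
    point_id: str
    patient_id: str
    label: int
    rate: float
    channel_names: tuple = CHANNEL_NAMES

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.channel_names):
            raise DataError(f"values must be 5 x L, got {self.values.shape}")
        if self.values.shape[1] < 1:
            raise DataError("feature series must have length >= 1")
        if not np.all(np.isfinite(self.values)):
            raise DataError("non-finite feature value")

    @property
    def length(self) -> int:
        return self.values.shape[1]


def interpolate_trajectory(traj: Trajectory, factor: int) -> Trajectory:
    """Cubic-spline upsampling by an integer factor.

    The new grid contains every original sample time, so original positions
    are reproduced exactly; factor = 1 returns the trajectory unchanged.
    """
    if factor < 1:
        raise ConfigError("interpolation factor must be >= 1")
    if factor == 1:
        return traj
    if traj.n_samples < 4:
        raise DataError("nonlinear interpolation needs at least 4 samples")
    t_old = traj.times
    n_new = (traj.n_samples - 1) * factor + 1
    t_new = np.arange(n_new) / (traj.rate * factor)
    spline = CubicSpline(t_old, traj.coords, axis=0)
    coords = spline(t_new)
    coords[::factor] = traj.coords  # exact at original sample times
    return replace(traj, coords=coords, rate=traj.rate * factor)


def compute_speed(traj: Trajectory) -> np.ndarray:
    """Forward-difference speed series, length T - 1, mm/s."""
    if traj.n_samples < 2:
        raise DataError("speed needs at least 2 samples")
    return np.linalg.norm(np.diff(traj.coords, axis=0), axis=1) * traj.rate


def compute_acceleration(traj: Trajectory) -> np.ndarray:
    """Central-second-difference acceleration magnitude, length T - 2, mm/s^2."""
    if traj.n_samples < 3:
        raise DataError("acceleration needs at least 3 samples")
    p = traj.coords
    return np.linalg.norm(p[2:] - 2.0 * p[1:-1] + p[:-2], axis=1) * traj.rate**2


def compute_planar_angles(traj: Trajectory) -> dict:
    """Vertex angles at each interior point, projected per coordinate plane.

    Returns {"angle_xy": ..., "angle_xz": ..., "angle_yz": ...}, each of
    length T - 2, values in [0, pi].
    """
    if traj.n_samples < 3:
        raise DataError("angles need at least 3 samples")
    p = traj.coords
    out = {}
    for name, (i, j) in _PLANES.items():
        q = p[:, [i, j]]
        v1 = q[:-2] - q[1:-1]   # p_t -> p_{t-1}
        v2 = q[2:] - q[1:-1]    # p_t -> p_{t+1}
        n1 = np.linalg.norm(v1, axis=1)
        n2 = np.linalg.norm(v2, axis=1)
        ok = (n1 > _DEGENERATE_SEGMENT) & (n2 > _DEGENERATE_SEGMENT)
        cosang = np.ones(len(v1))
        cosang[ok] = np.clip(
            (v1[ok] * v2[ok]).sum(axis=1) / (n1[ok] * n2[ok]), -1.0, 1.0
        )
        ang = np.full(len(v1), np.pi)
        ang[ok] = np.arccos(cosang[ok])
        out[name] = ang
    return out


def build_feature_series(traj: Trajectory, interpolation_factor: int = 1) -> FeatureSeries:
    """Assemble the 5 x L feature matrix (L = T' - 2 after interpolation)."""
    traj = interpolate_trajectory(traj, interpolation_factor)
    if traj.n_samples < 3:
        raise DataError("feature extraction needs at least 3 samples")
    speed = compute_speed(traj)[1:]  # align to interior points
    accel = compute_acceleration(traj)
    angles = compute_planar_angles(traj)
    values = np.vstack([speed, accel] + [angles[k] for k in CHANNEL_NAMES[2:]])
    return FeatureSeries(
        values=values,
        point_id=traj.point_id,
        patient_id=traj.patient_id,
        label=traj.label,
        rate=traj.rate,
    )


def feature_matrix(
    trajectories, interpolation_factor: int = 1
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack feature series for a list of trajectories.

    Returns (X, y, patients): X is (N, 5, L), y the labels (0/1/-1) and
    patients the patient-id array.  All trajectories must share T.
    """
    series = [build_feature_series(tr, interpolation_factor) for tr in trajectories]
    lengths = {s.length for s in series}
    if len(lengths) > 1:
        raise DataError(f"trajectories have mixed lengths {sorted(lengths)}")
    X = np.stack([s.values for s in series])
    y = np.array([s.label for s in series], dtype=int)
    patients = np.array([s.patient_id for s in series])
    return X, y, patients


def normalization_stats(X: np.ndarray) -> dict:
    """Per-channel mean/sd over a (N, 5, L) training array (leakage guard:
    call this on training folds only)."""
    mean = X.mean(axis=(0, 2))
    sd = X.std(axis=(0, 2))
    sd = np.where(sd < 1e-12, 1.0, sd)
    return {"mean": mean, "sd": sd}


def apply_normalization(X: np.ndarray, stats: dict) -> np.ndarray:
    return (X - stats["mean"][None, :, None]) / stats["sd"][None, :, None]
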