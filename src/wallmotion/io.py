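"""Trajectory and point-cloud I/O, color-to-class mapping, and the
nearest-point label transfer that attaches intraoperative wall labels to
4D-CTA observation points.

Trajectory files are plain CSV with columns
``point_id, patient_id, label, t, x, y, z`` (t in seconds, coordinates in mm;
label 0 = TW, 1 = HR, -1 = unlabeled).  Point clouds are ASCII PLY with
optional uchar RGB per vertex.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh

from .exceptions import ConfigError, DataError

TW = 0
HR = 1
UNLABELED = -1

TRAJECTORY_COLUMNS = ["point_id", "patient_id", "label", "t", "x", "y", "z"]


@dataclass
class Trajectory:
    """One wall point's T x 3 coordinate time series.

    Coordinates are in mm; ``rate`` is the sampling rate in Hz. ``label`` is
    0 for thin-walled (TW), 1 for hyperplastic remodeling (HR), -1 for
    unlabeled points.
    """

    point_id: str
    patient_id: str
    label: int
    coords: np.ndarray
    rate: float = 100.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise DataError(f"coords must be T x 3, got {self.coords.shape}")
        if self.coords.shape[0] < 3:
            raise DataError("trajectory needs at least 3 samples")
        if not np.all(np.isfinite(self.coords)):
            raise DataError(f"non-finite coordinate in trajectory {self.point_id!r}")
        if self.rate <= 0:
            raise DataError("sampling rate must be positive")
        if self.label not in (TW, HR, UNLABELED):
            raise DataError(f"label must be 0, 1 or -1, got {self.label}")

    @property
    def n_samples(self) -> int:
        return self.coords.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate


@dataclass
class LabeledCloud:
    """Point cloud with optional per-point labels and/or RGB colors."""

    points: np.ndarray
    labels: np.ndarray | None = None
    colors: np.ndarray | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise DataError(f"points must be n x 3, got {self.points.shape}")
        if self.points.shape[0] < 1:
            raise DataError("cloud must contain at least one point")
        if not np.all(np.isfinite(self.points)):
            raise DataError("non-finite point coordinate")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (self.points.shape[0],):
                raise DataError("labels must be one per point")
        if self.colors is not None:
            self.colors = np.asarray(self.colors, dtype=np.uint8)
            if self.colors.shape[0] != self.points.shape[0]:
                raise DataError("colors must be one per point")

    def __len__(self) -> int:
        return self.points.shape[0]


# ---------------------------------------------------------------------------
# Trajectory CSV
# ---------------------------------------------------------------------------

def write_trajectories(trajectories: list[Trajectory], path) -> None:
    """Write trajectories to CSV, one row per time sample, 12 significant
    digits so a write/read round trip preserves coordinates."""
    frames = []
    for tr in trajectories:
        frames.append(
            pd.DataFrame(
                {
                    "point_id": tr.point_id,
                    "patient_id": tr.patient_id,
                    "label": tr.label,
                    "t": tr.times,
                    "x": tr.coords[:, 0],
                    "y": tr.coords[:, 1],
                    "z": tr.coords[:, 2],
                }
            )
        )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=TRAJECTORY_COLUMNS
    )
    df.to_csv(path, index=False, float_format="%.12g")


def read_trajectories(path) -> list[Trajectory]:
    """Read a trajectory CSV; rows of each point are ordered by t.

    Raises :class:`DataError` naming the offending file row for missing
    columns, NaN coordinates, or duplicated time stamps within a point.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    bad = df[["t", "x", "y", "z"]].isna().any(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise DataError(f"{path}: NaN value in data row {row} (point_id="
                        f"{df['point_id'].iloc[row]!r})")

    out: list[Trajectory] = []
    for pid, grp in df.groupby("point_id", sort=False):
        grp = grp.sort_values("t", kind="stable")
        t = grp["t"].to_numpy(dtype=float)
        dt = np.diff(t)
        if np.any(dt <= 0):
            row = int(grp.index[np.argmax(dt <= 0) + 1])
            raise DataError(
                f"{path}: non-increasing t within point {pid!r} at data row {row}"
            )
        rate = 1.0 / float(np.median(dt)) if len(dt) else 100.0
        out.append(
            Trajectory(
                point_id=str(pid),
                patient_id=str(grp["patient_id"].iloc[0]),
                label=int(grp["label"].iloc[0]),
                coords=grp[["x", "y", "z"]].to_numpy(dtype=float),
                rate=rate,
            )
        )
    return out


# ---------------------------------------------------------------------------
# PLY point clouds
# ---------------------------------------------------------------------------

def write_cloud(cloud: LabeledCloud, path) -> None:
    """Write an ASCII PLY with uchar RGB (white where no color is set)."""
    colors = cloud.colors
    if colors is None:
        colors = np.full((len(cloud), 3), 255, dtype=np.uint8)
    pc = trimesh.PointCloud(cloud.points, colors=colors)
    data = trimesh.exchange.ply.export_ply(pc, encoding="ascii")
    with open(path, "wb") as fh:
        fh.write(data)


def read_cloud(path) -> LabeledCloud:
    pc = trimesh.load(str(path), force=None)
    points = np.asarray(pc.vertices, dtype=float)
    colors = None
    try:
        c = np.asarray(pc.colors)
        if c.size:
            colors = c[:, :3].astype(np.uint8)
    except (AttributeError, ValueError):
        pass
    return LabeledCloud(points=points, colors=colors)


# ---------------------------------------------------------------------------
# Color -> class mapping
# ---------------------------------------------------------------------------

def _validate_mapping(mapping: dict) -> dict:
    """Mapping must assign the classes TW and HR to the colors blue and red.

    Which color denotes which wall class is an annotation convention, not a
    fact of the data, so it must be stated explicitly — there is no default.
    """
    if mapping is None:
        raise ConfigError(
            "a color mapping like {'blue': 'TW', 'red': 'HR'} is required; "
            "the blue/red -> TW/HR correspondence is a dataset convention"
        )
    norm = {str(k).lower(): str(v).upper() for k, v in mapping.items()}
    if set(norm) != {"blue", "red"} or set(norm.values()) != {"TW", "HR"}:
        raise ConfigError(
            f"mapping must assign blue and red to TW and HR, got {mapping!r}"
        )
    return norm


_CLASS_CODE = {"TW": TW, "HR": HR}


def color_to_label(rgb, mapping: dict, margin: int = 50) -> int:
    """Map an RGB triple to TW/HR/unlabeled.

    A channel is dominant when it exceeds both other channels by ``margin``;
    red- or blue-dominant points map through ``mapping``; anything else
    (including green-dominant) is unlabeled.
    """
    norm = _validate_mapping(mapping)
    r, g, b = (int(v) for v in rgb)
    for v in (r, g, b):
        if not 0 <= v <= 255:
            raise DataError(f"RGB channel out of [0, 255]: {rgb!r}")
    if r >= g + margin and r >= b + margin:
        return _CLASS_CODE[norm["red"]]
    if b >= r + margin and b >= g + margin:
        return _CLASS_CODE[norm["blue"]]
    return UNLABELED


def labels_from_colors(cloud: LabeledCloud, mapping: dict, margin: int = 50) -> LabeledCloud:
    """Return a copy of ``cloud`` with labels derived from its colors."""
    if cloud.colors is None:
        raise DataError("cloud has no colors to map")
    labels = np.array(
        [color_to_label(rgb, mapping, margin) for rgb in cloud.colors], dtype=int
    )
    return LabeledCloud(points=cloud.points, labels=labels, colors=cloud.colors)


# ---------------------------------------------------------------------------
# Nearest-point label transfer
# ---------------------------------------------------------------------------

def nearest_point_label_transfer(primary: LabeledCloud, colored: LabeledCloud) -> LabeledCloud:
    """Assign to every primary point the label of its Euclidean-nearest
    colored point; distance ties go to the lowest colored-point index.

    The distance matrix is evaluated in blocks; ``argmin`` returns the first
    (lowest-index) minimizer, which makes the tie rule exact rather than
    dependent on a spatial index's internal ordering.
    """
    if colored.labels is None:
        raise DataError("colored cloud must carry labels")
    if len(colored) == 0 or len(primary) == 0:
        raise DataError("both clouds must be non-empty")
    labels = np.empty(len(primary), dtype=int)
    block = 2048
    cpts = colored.points
    for lo in range(0, len(primary), block):
        chunk = primary.points[lo : lo + block]
        d2 = ((chunk[:, None, :] - cpts[None, :, :]) ** 2).sum(axis=2)
        labels[lo : lo + len(chunk)] = colored.labels[np.argmin(d2, axis=1)]
    return LabeledCloud(points=primary.points, labels=labels, colors=primary.colors)
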