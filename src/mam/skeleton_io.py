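"""Pose-sequence containers, file I/O, and kinematic preprocessing.

A recording is a sequence of 3-D coordinates of ``V = 17`` critical joints
(the Human3.6M skeleton convention used by monocular 3-D pose estimators).
Before feature construction, sequences are standardized to 25 fps, smoothed
with a centered 5-frame moving average, and z-score normalized per coordinate
dimension — in that order.

File formats:

* CSV with columns ``frame,joint,x,y,z`` (``joint`` is a canonical name);
* HDF5 with dataset ``coords`` shaped ``(frames, 17, 3)`` and attributes
  ``fps``, ``subject_id``, ``joint_convention``;
* FMs-interval annotations as a two-column CSV ``start_s,end_s``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "JOINT_NAMES",
    "N_JOINTS",
    "N_DIMS",
    "PoseSequence",
    "FMIntervalAnnotation",
    "read_pose_sequence",
    "write_pose_sequence",
    "read_annotation",
    "write_annotation",
    "resample_to_25fps",
    "smooth_moving_average",
    "normalize_coordinates",
    "preprocess",
]

#: Human3.6M 17-joint skeleton, the convention of the upstream pose estimator.
JOINT_NAMES: tuple[str, ...] = (
    "pelvis",
    "right_hip",
    "right_knee",
    "right_ankle",
    "left_hip",
    "left_knee",
    "left_ankle",
    "spine",
    "thorax",
    "neck",
    "head",
    "left_shoulder",
    "left_elbow",
    "left_wrist",
    "right_shoulder",
    "right_elbow",
    "right_wrist",
)

N_JOINTS = 17
N_DIMS = 3
TARGET_FPS = 25.0


@dataclasses.dataclass
class PoseSequence:
    """Per-frame 3-D coordinates of the 17 critical joints.

    Parameters
    ----------
    subject_id:
        Opaque identifier of the recording.
    fps:
        Frames per second of ``coords`` (positive).
    coords:
        Array of shape ``(T, 17, 3)``; finite values only.
    joint_convention:
        Name of the joint ordering; only ``"h36m17"`` is defined.
    """

    subject_id: str
    fps: float
    coords: np.ndarray
    joint_convention: str = "h36m17"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (N_JOINTS, N_DIMS):
            raise ValueError(
                f"coords must have shape (T, {N_JOINTS}, {N_DIMS}); "
                f"got {self.coords.shape}"
            )
        if self.coords.shape[0] < 1:
            raise ValueError("sequence must contain at least one frame")
        if not self.fps > 0:
            raise ValueError(f"fps must be positive; got {self.fps}")
        bad = ~np.isfinite(self.coords)
        if bad.any():
            frame = int(np.argwhere(bad)[0, 0])
            raise ValueError(f"non-finite coordinate value in frame {frame}")
        if self.joint_convention != "h36m17":
            raise ValueError(f"unknown joint convention {self.joint_convention!r}")

    @property
    def n_frames(self) -> int:
        return int(self.coords.shape[0])

    @property
    def duration_s(self) -> float:
        """Duration spanned by the sampling grid, ``(T - 1) / fps``."""
        return (self.n_frames - 1) / self.fps

    def copy_with(self, **updates) -> "PoseSequence":
        kwargs = dict(
            subject_id=self.subject_id,
            fps=self.fps,
            coords=self.coords,
            joint_convention=self.joint_convention,
        )
        kwargs.update(updates)
        return PoseSequence(**kwargs)


@dataclasses.dataclass
class FMIntervalAnnotation:
    """Expert-annotated intervals (in seconds) where fidgety movements occur.

    Intervals are normalized on construction: sorted, merged when overlapping
    or abutting, and required to satisfy ``start < end``.
    """

    intervals: list[tuple[float, float]]

    def __post_init__(self) -> None:
        norm: list[tuple[float, float]] = []
        for start, end in sorted((float(s), float(e)) for s, e in self.intervals):
            if not start < end:
                raise ValueError(f"interval ({start}, {end}) must have start < end")
            if start < 0:
                raise ValueError(f"interval start {start} is negative")
            if norm and start <= norm[-1][1]:
                norm[-1] = (norm[-1][0], max(norm[-1][1], end))
            else:
                norm.append((start, end))
        self.intervals = norm

    def total_duration(self) -> float:
        return float(sum(e - s for s, e in self.intervals))

    def overlap_seconds(self, start_s: float, end_s: float) -> float:
        """FMs time within the half-open window ``[start_s, end_s)``."""
        return float(
            sum(
                max(0.0, min(e, end_s) - max(s, start_s))
                for s, e in self.intervals
            )
        )

    def coverage(self, duration_s: float) -> float:
        """Fraction of ``[0, duration_s)`` covered by FMs intervals."""
        if duration_s <= 0:
            raise ValueError("duration must be positive")
        return self.overlap_seconds(0.0, duration_s) / duration_s


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_JOINT_INDEX = {name: i for i, name in enumerate(JOINT_NAMES)}


def read_pose_sequence(path, fmt: str | None = None) -> PoseSequence:
    """Read a pose sequence from CSV or HDF5.

    ``fmt`` is inferred from the file suffix when omitted (``.csv`` vs
    ``.h5``/``.hdf5``). Frames missing joints, unknown joint names, or
    non-finite values are rejected with the offending frame index.
    """
    path = Path(path)
    fmt = fmt or _infer_fmt(path)
    if fmt == "csv":
        return _read_csv(path)
    if fmt == "hdf5":
        return _read_hdf5(path)
    raise ValueError(f"unknown format {fmt!r}")


def write_pose_sequence(seq: PoseSequence, path, fmt: str | None = None) -> Path:
    """Write a pose sequence; the result round-trips through
    :func:`read_pose_sequence` losslessly at float64 precision."""
    path = Path(path)
    fmt = fmt or _infer_fmt(path)
    if fmt == "csv":
        t, v = seq.n_frames, N_JOINTS
        frame = np.repeat(np.arange(t), v)
        joint = np.tile(np.asarray(JOINT_NAMES), t)
        flat = seq.coords.reshape(t * v, N_DIMS)
        df = pd.DataFrame(
            {"frame": frame, "joint": joint, "x": flat[:, 0],
             "y": flat[:, 1], "z": flat[:, 2]}
        )
        with path.open("w", newline="") as fh:
            fh.write(f"# subject_id={seq.subject_id} fps={seq.fps!r}\n")
            df.to_csv(fh, index=False, float_format="%.17g")
    elif fmt == "hdf5":
        with h5py.File(path, "w") as fh:
            dset = fh.create_dataset("coords", data=seq.coords)
            dset.attrs["fps"] = seq.fps
            dset.attrs["subject_id"] = seq.subject_id
            dset.attrs["joint_convention"] = seq.joint_convention
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def _infer_fmt(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return "csv"
    if suffix in (".h5", ".hdf5"):
        return "hdf5"
    raise ValueError(f"cannot infer format from suffix {suffix!r}")


def _read_csv(path: Path) -> PoseSequence:
    subject_id, fps = path.stem, TARGET_FPS
    with path.open() as fh:
        first = fh.readline()
        if first.startswith("#"):
            meta = dict(
                item.split("=", 1) for item in first[1:].split() if "=" in item
            )
            subject_id = meta.get("subject_id", subject_id)
            fps = float(meta.get("fps", fps))
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    required = {"frame", "joint", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"CSV must have columns {sorted(required)}")
    unknown = set(df["joint"]) - set(JOINT_NAMES)
    if unknown:
        raise ValueError(f"unknown joint names: {sorted(unknown)}")
    frames = np.sort(df["frame"].unique())
    t = len(frames)
    if not np.array_equal(frames, np.arange(t)):
        raise ValueError("frame indices must be consecutive starting at 0")
    coords = np.full((t, N_JOINTS, N_DIMS), np.nan)
    fi = df["frame"].to_numpy()
    ji = df["joint"].map(_JOINT_INDEX).to_numpy()
    coords[fi, ji, 0] = df["x"].to_numpy()
    coords[fi, ji, 1] = df["y"].to_numpy()
    coords[fi, ji, 2] = df["z"].to_numpy()
    missing = np.isnan(coords).any(axis=(1, 2))
    if missing.any():
        raise ValueError(
            f"frame {int(np.argmax(missing))} is missing joints or has "
            "non-finite values"
        )
    return PoseSequence(subject_id=subject_id, fps=fps, coords=coords)


def _read_hdf5(path: Path) -> PoseSequence:
    with h5py.File(path, "r") as fh:
        if "coords" not in fh:
            raise ValueError("HDF5 file lacks dataset 'coords'")
        dset = fh["coords"]
        coords = np.asarray(dset)
        fps = float(dset.attrs.get("fps", TARGET_FPS))
        subject_id = str(dset.attrs.get("subject_id", path.stem))
        convention = str(dset.attrs.get("joint_convention", "h36m17"))
    return PoseSequence(
        subject_id=subject_id, fps=fps, coords=coords, joint_convention=convention
    )


def read_annotation(path) -> FMIntervalAnnotation:
    df = pd.read_csv(path)
    if not {"start_s", "end_s"}.issubset(df.columns):
        raise ValueError("annotation CSV must have columns start_s,end_s")
    return FMIntervalAnnotation(list(zip(df["start_s"], df["end_s"])))


def write_annotation(ann: FMIntervalAnnotation, path) -> Path:
    path = Path(path)
    pd.DataFrame(ann.intervals, columns=["start_s", "end_s"]).to_csv(
        path, index=False
    )
    return path


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def resample_to_25fps(seq: PoseSequence) -> PoseSequence:
    """Standardize a sequence to 25 fps by per-coordinate linear interpolation.

    A 25-fps input is returned unchanged. The output time grid spans the same
    duration: ``n_out = floor((T - 1) * 25 / fps) + 1``.
    """
    if seq.fps == TARGET_FPS:
        return seq
    if seq.n_frames < 2:
        raise ValueError("cannot resample a sequence with fewer than 2 frames")
    t_in = np.arange(seq.n_frames) / seq.fps
    n_out = int(np.floor((seq.n_frames - 1) * TARGET_FPS / seq.fps)) + 1
    t_out = np.arange(n_out) / TARGET_FPS
    flat = seq.coords.reshape(seq.n_frames, -1)
    out = np.empty((n_out, flat.shape[1]))
    for j in range(flat.shape[1]):
        out[:, j] = np.interp(t_out, t_in, flat[:, j])
    return seq.copy_with(fps=TARGET_FPS, coords=out.reshape(n_out, N_JOINTS, N_DIMS))


def smooth_moving_average(seq: PoseSequence, window: int = 5) -> PoseSequence:
    """Centered moving average per coordinate channel.

    At the sequence ends the window shrinks symmetrically (at frame ``t`` the
    half-width is ``min(window // 2, t, T - 1 - t)``), so the frame count is
    unchanged and no padding values are invented.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    t_total = seq.n_frames
    if t_total < window:
        raise ValueError(f"sequence has {t_total} frames, fewer than window {window}")
    if window == 1:
        return seq
    half = window // 2
    flat = seq.coords.reshape(t_total, -1)
    csum = np.vstack([np.zeros((1, flat.shape[1])), np.cumsum(flat, axis=0)])
    out = np.empty_like(flat)
    # interior frames all at once; shrinking windows only at the two ends
    out[half : t_total - half] = (csum[window:] - csum[: t_total - window + 1]) / window
    for t in range(half):
        h = min(t, t_total - 1 - t)
        out[t] = (csum[t + h + 1] - csum[t - h]) / (2 * h + 1)
        u = t_total - 1 - t
        h = min(half, t_total - 1 - u, u)
        out[u] = (csum[u + h + 1] - csum[u - h]) / (2 * h + 1)
    return seq.copy_with(coords=out.reshape(seq.coords.shape))


def normalize_coordinates(seq: PoseSequence) -> PoseSequence:
    """Z-score each coordinate dimension over all joints and frames.

    The mean and standard deviation are computed per dimension across the
    whole sequence, making inference self-contained per recording.
    """
    mean = seq.coords.mean(axis=(0, 1))
    sd = seq.coords.std(axis=(0, 1))
    for c, name in enumerate("xyz"):
        if sd[c] == 0:
            raise ValueError(f"zero variance in dimension {name!r}; cannot normalize")
    return seq.copy_with(coords=(seq.coords - mean) / sd)


def preprocess(seq: PoseSequence, window: int = 5) -> PoseSequence:
    """Full chain: resample to 25 fps, smooth, then z-score normalize."""
    return normalize_coordinates(
        smooth_moving_average(resample_to_25fps(seq), window=window)
    )
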