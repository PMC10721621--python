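"""Joint-distance feature construction.

Each frame is represented by three ``17 x 17`` matrices of pairwise
per-dimension distances ``d^c_{i,j} = |x^c_i - x^c_j|`` — the one-dimensional
Euclidean distance between joints *i* and *j* within coordinate dimension
*c*.  Note this is deliberately NOT the full 3-D pairwise distance: keeping
the dimensions separate is what yields a ``[C, V, V]`` stack per frame, and
it preserves directional information that a single 3-D distance would
collapse.  A whole video becomes a ``[T*, C, V, V]`` tensor.

Distances are computed after z-score normalization, so entries are in
z-score units of the corresponding dimension.
"""

from __future__ import annotations

import dataclasses

import h5py
import numpy as np

from .skeleton_io import N_DIMS, N_JOINTS, PoseSequence

__all__ = [
    "FeatureBag",
    "frame_distance_matrices",
    "sequence_features",
    "window_distance_tensor",
    "save_features",
    "load_features",
]


@dataclasses.dataclass
class FeatureBag:
    """A ``[T*, C, V, V]`` distance tensor with provenance."""

    tensor: np.ndarray
    subject_id: str
    fps: float

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor)
        if self.tensor.ndim != 4 or self.tensor.shape[1:] != (
            N_DIMS,
            N_JOINTS,
            N_JOINTS,
        ):
            raise ValueError(
                f"feature tensor must be (T*, {N_DIMS}, {N_JOINTS}, {N_JOINTS}); "
                f"got {self.tensor.shape}"
            )

    @property
    def n_frames(self) -> int:
        return int(self.tensor.shape[0])


def frame_distance_matrices(frame: np.ndarray) -> np.ndarray:
    """Per-dimension distance matrices for one frame.

    Parameters
    ----------
    frame:
        Array of shape ``(V, C)`` (17 joints, 3 coordinates).

    Returns
    -------
    ndarray of shape ``(C, V, V)`` where slice ``c`` holds
    ``|x^c_i - x^c_j|``: symmetric, zero diagonal, non-negative.
    """
    frame = np.asarray(frame)
    if frame.shape != (N_JOINTS, N_DIMS):
        raise ValueError(f"frame must be ({N_JOINTS}, {N_DIMS}); got {frame.shape}")
    if not np.isfinite(frame).all():
        raise ValueError("non-finite coordinate in frame")
    # (C, V, 1) - (C, 1, V) broadcast
    x = frame.T
    return np.abs(x[:, :, None] - x[:, None, :])


def window_distance_tensor(coords: np.ndarray, start: int, length: int) -> np.ndarray:
    """Distance tensor ``(length, C, V, V)`` for ``coords[start:start+length]``.

    Used to materialize instance features lazily from a preprocessed
    coordinate array without building the full-video tensor.
    """
    seg = np.asarray(coords)[start : start + length]
    if seg.shape[0] != length:
        raise ValueError("window extends past the end of the sequence")
    x = seg.transpose(0, 2, 1)  # (T, C, V)
    return np.abs(x[:, :, :, None] - x[:, :, None, :])


def sequence_features(seq: PoseSequence) -> FeatureBag:
    """Stack :func:`frame_distance_matrices` over all frames of a sequence.

    The input is expected to be fully preprocessed (25 fps, smoothed,
    normalized); the function itself only requires a valid sequence.
    """
    tensor = window_distance_tensor(seq.coords, 0, seq.n_frames)
    return FeatureBag(tensor=tensor, subject_id=seq.subject_id, fps=seq.fps)


def save_features(bag: FeatureBag, path) -> None:
    """Cache a feature tensor to HDF5 (dataset ``features``)."""
    with h5py.File(path, "w") as fh:
        dset = fh.create_dataset("features", data=bag.tensor)
        dset.attrs["subject_id"] = bag.subject_id
        dset.attrs["fps"] = bag.fps


def load_features(path) -> FeatureBag:
    with h5py.File(path, "r") as fh:
        dset = fh["features"]
        return FeatureBag(
            tensor=np.asarray(dset),
            subject_id=str(dset.attrs.get("subject_id", "")),
            fps=float(dset.attrs.get("fps", 25.0)),
        )
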