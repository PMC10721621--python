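"""Multi-instance "bag"/"instance" construction and clip labeling.

A whole video's ``[T*, C, V, V]`` feature tensor is the MIL *bag*; it is
split into fixed-length *instances* of ``T = 240`` frames (9.6 s at 25 fps)
at a constant step.  The bag carries the video-level normal/risk label while
instance (clip) labels are latent; where expert FMs-interval annotations
exist, clips are labeled FMs when strictly more than half of the clip is
covered by annotated FMs time, and reference clips are pure windows with
coverage exactly 1 (FMs) or exactly 0 (non-FMs).

Frame-time convention: the clip starting at frame ``f`` spans the half-open
interval ``[f / fps, (f + T) / fps)``.
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np

from .features import FeatureBag
from .skeleton_io import FMIntervalAnnotation

__all__ = [
    "Instance",
    "Bag",
    "RefClip",
    "DEFAULT_T",
    "DEFAULT_STEP",
    "instance_starts",
    "split_into_instances",
    "label_clip_from_annotation",
    "extract_reference_clips",
]

#: Instance clip length in frames (9.6 s at 25 fps).
DEFAULT_T = 240
#: Step between adjacent instance windows in frames (6 s; adjacent 9.6-s
#: clips then overlap by 90 frames).
DEFAULT_STEP = 150


@dataclasses.dataclass
class Instance:
    """One fixed-length clip cut from a bag."""

    tensor: np.ndarray  # (T, C, V, V)
    start_frame: int
    alpha: float | None = None  # FMs probability, filled in by the model


@dataclasses.dataclass
class Bag:
    """An ordered set of instances from one video, carrying the video label."""

    instances: list[Instance]
    subject_id: str
    bag_label: Literal["normal", "risk", "unknown"] = "unknown"

    def __post_init__(self) -> None:
        starts = [ins.start_frame for ins in self.instances]
        if len(starts) >= 2:
            steps = np.diff(starts)
            if not (steps > 0).all() or len(set(steps.tolist())) != 1:
                raise ValueError(
                    "instance start frames must be strictly increasing with a "
                    "constant step"
                )

    def __len__(self) -> int:
        return len(self.instances)


@dataclasses.dataclass
class RefClip:
    """A reference clip with a definite FMs / non-FMs label."""

    tensor: np.ndarray  # (T, C, V, V)
    clip_label: Literal["FMs", "non-FMs"]
    start_frame: int = 0
    subject_id: str = ""


def instance_starts(n_frames: int, T: int = DEFAULT_T, step: int = DEFAULT_STEP) -> np.ndarray:
    """Start frames ``0, step, 2*step, ...`` of full windows within ``n_frames``.

    Trailing frames that do not fill a complete window are dropped.
    """
    if T < 1 or step < 1:
        raise ValueError("T and step must be positive")
    if n_frames < T:
        raise ValueError(
            f"sequence of {n_frames} frames is shorter than one instance ({T})"
        )
    count = (n_frames - T) // step + 1
    return np.arange(count) * step


def split_into_instances(
    bag_features: FeatureBag,
    T: int = DEFAULT_T,
    step: int = DEFAULT_STEP,
    bag_label: str = "unknown",
) -> Bag:
    """Split a bag feature tensor into instances of ``T`` frames."""
    starts = instance_starts(bag_features.n_frames, T=T, step=step)
    instances = [
        Instance(tensor=bag_features.tensor[s : s + T], start_frame=int(s))
        for s in starts
    ]
    return Bag(
        instances=instances,
        subject_id=bag_features.subject_id,
        bag_label=bag_label,  # type: ignore[arg-type]
    )


def clip_overlap_fraction(
    ann: FMIntervalAnnotation, start_frame: int, T: int, fps: float
) -> float:
    """Fraction of the clip window covered by annotated FMs time."""
    start_s = start_frame / fps
    end_s = (start_frame + T) / fps
    return ann.overlap_seconds(start_s, end_s) / (T / fps)


def label_clip_from_annotation(
    ann: FMIntervalAnnotation,
    start_frame: int,
    T: int = DEFAULT_T,
    fps: float = 25.0,
) -> Literal["FMs", "non-FMs"]:
    """Label a clip FMs iff strictly more than half of it is annotated FMs."""
    return "FMs" if clip_overlap_fraction(ann, start_frame, T, fps) > 0.5 else "non-FMs"


def extract_reference_clips(
    seq_features: FeatureBag,
    ann: FMIntervalAnnotation,
    T: int = DEFAULT_T,
    step: int = DEFAULT_STEP,
) -> list[RefClip]:
    """Pure-coverage reference clips from an annotated sequence.

    Windows completely covered by FMs (fraction exactly 1) become FMs
    reference clips; windows containing no FMs time (fraction exactly 0)
    become non-FMs reference clips; partially covered windows are discarded.
    """
    fps = seq_features.fps
    clips: list[RefClip] = []
    for s in instance_starts(seq_features.n_frames, T=T, step=step):
        frac = clip_overlap_fraction(ann, int(s), T, fps)
        if frac >= 1.0 or frac <= 0.0:
            clips.append(
                RefClip(
                    tensor=seq_features.tensor[s : s + T],
                    clip_label="FMs" if frac >= 1.0 else "non-FMs",
                    start_frame=int(s),
                    subject_id=seq_features.subject_id,
                )
            )
    return clips
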