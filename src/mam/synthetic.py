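"""Synthetic supine-infant motion with ground-truth FMs intervals.

The clinical videos behind this method are restricted-access, so the
pipeline is exercised on a kinematic simulator that reproduces the
*statistical* structure the model relies on:

* a supine 17-joint skeleton template;
* slow, large-amplitude gross movements of limbs, neck and trunk present
  throughout the recording (band 0.05-0.3 Hz);
* fidgety movements (FMs): small-amplitude, higher-frequency (0.8-2.5 Hz),
  multidirectional oscillations of neck, trunk and limb joints, present
  only inside annotated FMs intervals;
* FMs intervals from an alternating renewal process with exponential bout
  lengths, tuned so expected coverage matches the drawn per-infant target;
* per-class coverage targets matching the reported medians: continuous
  FMs ≈ 0.74 and intermittent ≈ 0.46 (together the normal group), and
  sporadic/absent ≈ 0.14 for the risk group;
* infant characteristics drawn from the reported cohort distributions and
  deliberately identical between groups (the cohorts showed no significant
  group differences), so the info branch carries no label signal.

FMs amplitudes and bands are not quantified clinically; they are chosen so
that the detection problem is solvable but not trivial, and they are the
explicit difficulty knob of the benchmark (``fm_amplitude`` relative to
``gross_amplitude``).
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np
import pandas as pd

from .network import Characteristics
from .skeleton_io import (
    N_DIMS,
    N_JOINTS,
    FMIntervalAnnotation,
    JOINT_NAMES,
    PoseSequence,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticInfant",
    "simulate_characteristics",
    "simulate_fms_intervals",
    "simulate_infant",
    "simulate_cohort",
    "cohort_manifest",
]

#: Supine template: x to the infant's left, y toward the feet, z up
#: (arbitrary length units, roughly decimeters for a ~60 cm infant).
_TEMPLATE = {
    "pelvis": (0.0, 0.0, 0.5),
    "right_hip": (-0.8, 0.2, 0.5),
    "left_hip": (0.8, 0.2, 0.5),
    "right_knee": (-1.0, 1.4, 0.9),
    "left_knee": (1.0, 1.4, 0.9),
    "right_ankle": (-0.9, 2.4, 0.6),
    "left_ankle": (0.9, 2.4, 0.6),
    "spine": (0.0, -1.0, 0.6),
    "thorax": (0.0, -1.9, 0.7),
    "neck": (0.0, -2.4, 0.7),
    "head": (0.0, -3.1, 0.8),
    "left_shoulder": (1.1, -1.9, 0.6),
    "right_shoulder": (-1.1, -1.9, 0.6),
    "left_elbow": (1.6, -1.0, 0.7),
    "right_elbow": (-1.6, -1.0, 0.7),
    "left_wrist": (1.4, 0.0, 0.9),
    "right_wrist": (-1.4, 0.0, 0.9),
}

#: Joints engaged by movement (all but the near-rigid pelvis/hip base).
_MOBILE = [
    "right_knee", "left_knee", "right_ankle", "left_ankle",
    "spine", "thorax", "neck", "head",
    "left_shoulder", "right_shoulder",
    "left_elbow", "right_elbow", "left_wrist", "right_wrist",
]

#: Distal joints where fidgety oscillations are most visible.
_FM_JOINTS = [
    "neck", "head", "left_elbow", "right_elbow", "left_wrist", "right_wrist",
    "left_knee", "right_knee", "left_ankle", "right_ankle",
]


@dataclasses.dataclass
class SyntheticConfig:
    """Knobs of the motion simulator (defaults = benchmark conditions)."""

    duration_s: float = 300.0          # near the ~295-299 s cohort medians
    fps: float = 25.0
    gross_band_hz: tuple[float, float] = (0.05, 0.3)
    gross_amplitude: float = 0.9       # template length units
    fm_band_hz: tuple[float, float] = (0.8, 2.5)
    fm_amplitude: float = 0.5          # the difficulty knob (~0.3 z-units)
    noise_sd: float = 0.03             # pose-estimation jitter
    mean_cycle_s: float = 40.0         # FMs bout + pause renewal cycle
    # coverage distributions per FMs category: (mean, sd, low, high)
    coverage_continuous: tuple = (0.74, 0.08, 0.55, 0.95)
    coverage_intermittent: tuple = (0.46, 0.08, 0.25, 0.58)
    coverage_sporadic: tuple = (0.14, 0.08, 0.0, 0.32)
    p_continuous_in_normal: float = 0.347   # 60 of 173 normal-group infants
    p_absent_in_risk: float = 0.25          # sporadic vs fully absent FMs

    def __post_init__(self) -> None:
        if not 0 < self.gross_band_hz[0] < self.gross_band_hz[1]:
            raise ValueError("gross band must be positive and ordered")
        if not self.gross_band_hz[1] < self.fm_band_hz[0] < self.fm_band_hz[1]:
            raise ValueError("FMs band must lie strictly above the gross band")
        if self.fm_band_hz[1] > self.fps / 2:
            raise ValueError("FMs band exceeds the Nyquist frequency")


@dataclasses.dataclass
class SyntheticInfant:
    """One simulated recording with ground truth."""

    infant_id: str
    group: Literal["normal", "risk"]
    category: Literal["continuous", "intermittent", "sporadic", "absent"]
    characteristics: Characteristics
    pose: PoseSequence
    annotation: FMIntervalAnnotation
    target_coverage: float


def simulate_characteristics(group: str, rng: np.random.Generator) -> Characteristics:
    """Draw characteristics from the cohort distributions.

    Identical distributions for both groups — by construction the
    characteristics carry no group signal, mirroring the cohorts' lack of
    significant group differences.
    """
    del group  # same distribution for both groups, deliberately

    def trunc_normal(mean, sd, lo, hi):
        while True:
            x = rng.normal(mean, sd)
            if lo <= x <= hi:
                return float(x)

    return Characteristics(
        sex="male" if rng.random() < 0.5 else "female",
        gestational_age_wk=trunc_normal(35.1, 3.2, 24.0, 42.0),
        birth_weight_g=trunc_normal(2420.0, 670.0, 500.0, 5000.0),
        corrected_age_wk=trunc_normal(12.5, 2.7, 9.0, 20.0),
    )


def simulate_fms_intervals(
    duration_s: float,
    coverage: float,
    rng: np.random.Generator,
    mean_cycle_s: float = 40.0,
) -> FMIntervalAnnotation:
    """Alternating renewal process of FMs bouts and pauses.

    Bout and pause lengths are exponential with means ``coverage *
    mean_cycle_s`` and ``(1 - coverage) * mean_cycle_s``; the stationary
    fraction of time in a bout then equals ``coverage``.  The initial state
    is drawn with probability ``coverage``.
    """
    if not 0.0 <= coverage <= 1.0:
        raise ValueError("coverage must lie in [0, 1]")
    if coverage == 0.0:
        return FMIntervalAnnotation([])
    if coverage == 1.0:
        return FMIntervalAnnotation([(0.0, duration_s)])
    mean_on = coverage * mean_cycle_s
    mean_off = (1.0 - coverage) * mean_cycle_s
    intervals: list[tuple[float, float]] = []
    t = 0.0
    in_bout = rng.random() < coverage
    while t < duration_s:
        length = rng.exponential(mean_on if in_bout else mean_off)
        end = min(t + length, duration_s)
        if in_bout and end > t:
            intervals.append((t, end))
        t = end
        in_bout = not in_bout
    return FMIntervalAnnotation(intervals)


def _band_oscillation(
    n: int, fps: float, band: tuple[float, float], rng: np.random.Generator,
    n_components: int = 6,
) -> np.ndarray:
    """Sum of random sinusoids within a frequency band, unit RMS."""
    t = np.arange(n) / fps
    freqs = rng.uniform(band[0], band[1], n_components)
    phases = rng.uniform(0, 2 * np.pi, n_components)
    amps = rng.uniform(0.5, 1.0, n_components)
    x = np.sum(
        amps[:, None] * np.sin(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]),
        axis=0,
    )
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _smooth_gate(
    n: int, fps: float, ann: FMIntervalAnnotation, ramp_s: float = 0.3
) -> np.ndarray:
    """0/1 envelope of the FMs intervals with short cosine on/off ramps."""
    t = np.arange(n) / fps
    gate = np.zeros(n)
    for start, end in ann.intervals:
        gate = np.maximum(
            gate,
            np.clip((t - start) / ramp_s, 0, 1) * np.clip((end - t) / ramp_s, 0, 1),
        )
    return 0.5 - 0.5 * np.cos(np.pi * gate)


def _draw_category(group: str, cfg: SyntheticConfig, rng: np.random.Generator) -> str:
    if group == "normal":
        return (
            "continuous" if rng.random() < cfg.p_continuous_in_normal else "intermittent"
        )
    return "absent" if rng.random() < cfg.p_absent_in_risk else "sporadic"


def _draw_coverage(category: str, cfg: SyntheticConfig, rng: np.random.Generator) -> float:
    if category == "absent":
        return 0.0
    mean, sd, lo, hi = {
        "continuous": cfg.coverage_continuous,
        "intermittent": cfg.coverage_intermittent,
        "sporadic": cfg.coverage_sporadic,
    }[category]
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def simulate_infant(
    config: SyntheticConfig,
    group: Literal["normal", "risk"],
    rng: np.random.Generator,
    infant_id: str = "synthetic",
) -> SyntheticInfant:
    """Simulate one supine recording with ground-truth FMs intervals."""
    cfg = config
    n = int(round(cfg.duration_s * cfg.fps))
    category = _draw_category(group, cfg, rng)
    coverage = _draw_coverage(category, cfg, rng)
    ann = simulate_fms_intervals(cfg.duration_s, coverage, rng, cfg.mean_cycle_s)
    gate = _smooth_gate(n, cfg.fps, ann)

    coords = np.empty((n, N_JOINTS, N_DIMS))
    template = np.array([_TEMPLATE[name] for name in JOINT_NAMES])
    coords[:] = template[None, :, :]
    mobile_idx = {name: JOINT_NAMES.index(name) for name in _MOBILE}
    fm_set = set(_FM_JOINTS)
    for name, j in mobile_idx.items():
        # gross movement in every axis, everywhere in the recording
        for c in range(N_DIMS):
            coords[:, j, c] += cfg.gross_amplitude * _band_oscillation(
                n, cfg.fps, cfg.gross_band_hz, rng, n_components=4
            )
            # fidgety oscillation only inside annotated intervals
            if name in fm_set:
                coords[:, j, c] += (
                    cfg.fm_amplitude
                    * gate
                    * _band_oscillation(n, cfg.fps, cfg.fm_band_hz, rng)
                )
    coords += rng.normal(0.0, cfg.noise_sd, coords.shape)

    pose = PoseSequence(subject_id=infant_id, fps=cfg.fps, coords=coords)
    characteristics = simulate_characteristics(group, rng)
    return SyntheticInfant(
        infant_id=infant_id,
        group=group,
        category=category,  # type: ignore[arg-type]
        characteristics=characteristics,
        pose=pose,
        annotation=ann,
        target_coverage=coverage,
    )


def simulate_cohort(
    n: int,
    config: SyntheticConfig | None = None,
    risk_fraction: float = 0.237,
    seed: int = 0,
) -> list[SyntheticInfant]:
    """Simulate a cohort with the reported risk-group share (23.7%).

    Group counts are ``round(n * risk_fraction)`` risk and the rest normal;
    the result is deterministic given ``seed``.
    """
    if n < 2:
        raise ValueError("cohort must contain at least 2 infants")
    cfg = config or SyntheticConfig()
    n_risk = int(round(n * risk_fraction))
    n_risk = min(max(n_risk, 1), n - 1)  # both groups represented
    rng = np.random.default_rng(seed)
    infants = []
    groups = ["normal"] * (n - n_risk) + ["risk"] * n_risk
    for i, group in enumerate(groups):
        infants.append(
            simulate_infant(cfg, group, rng, infant_id=f"syn{i:04d}")  # type: ignore[arg-type]
        )
    return infants


def cohort_manifest(infants: list[SyntheticInfant]) -> pd.DataFrame:
    """Per-infant summary table of a simulated cohort."""
    rows = []
    for inf in infants:
        ch = inf.characteristics
        rows.append(
            {
                "infant_id": inf.infant_id,
                "group": inf.group,
                "category": inf.category,
                "target_coverage": inf.target_coverage,
                "realized_coverage": inf.annotation.coverage(
                    inf.pose.n_frames / inf.pose.fps
                ),
                "sex": ch.sex,
                "gestational_age_wk": ch.gestational_age_wk,
                "birth_weight_g": ch.birth_weight_g,
                "corrected_age_wk": ch.corrected_age_wk,
                "n_frames": inf.pose.n_frames,
                "fps": inf.pose.fps,
            }
        )
    return pd.DataFrame(rows)
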