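"""Inference, FMs quantification, concordance and evaluation statistics.

At application time the reference branch is dropped: instances are scored by
the shared encoder + classifier, thresholded at 0.5 into FMs / non-FMs
clips, and summarized as the *FMs frequency* — the proportion of FMs clips
in the video.  The frequency separates normal from risk recordings (the
quantitative assessment) and, within the normal group, continuous from
intermittent FMs at the 0.603 threshold.

Also provided: the confusion-matrix metrics (accuracy, sensitivity,
specificity, PPV, NPV), Cohen's kappa for model-vs-expert clip concordance,
tie-corrected ROC AUC with a stratified bootstrap CI, and the cohort
balance tests (Yates-corrected chi-square for sex; Shapiro-screened t-test
or Mann-Whitney for continuous characteristics).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .bags import Bag, instance_starts, label_clip_from_annotation
from .network import Characteristics, MAMModel
from .skeleton_io import FMIntervalAnnotation

__all__ = [
    "PredictionResult",
    "ConfusionCounts",
    "predict_instances",
    "predict_video",
    "binarize_clips",
    "fms_frequency",
    "classify_group_by_frequency",
    "classify_fms_category",
    "youden_threshold",
    "concordance_kappa",
    "per_video_kappa",
    "classification_metrics",
    "roc_auc",
    "rank_clips_for_review",
    "cohort_balance_tests",
]


@dataclasses.dataclass
class PredictionResult:
    """Per-video prediction: instance alphas, FMs frequency, group call."""

    subject_id: str
    start_frames: np.ndarray
    alphas: np.ndarray
    fps: float
    T: int
    fms_frequency: float
    normal_probability: float | None = None
    group_call: Literal["normal", "risk"] | None = None
    category_call: Literal["continuous", "intermittent"] | None = None

    def clip_windows_s(self) -> list[tuple[float, float]]:
        return [
            (s / self.fps, (s + self.T) / self.fps) for s in self.start_frames
        ]


def predict_instances(model: MAMModel, bag: Bag | np.ndarray, chunk: int = 32) -> np.ndarray:
    """FMs probability ``alpha`` per instance of a bag (deterministic)."""
    if isinstance(bag, Bag):
        tensors = np.stack([ins.tensor for ins in bag.instances])
    else:
        tensors = np.asarray(bag)
    return model.predict_alpha(tensors, chunk=chunk)


def binarize_clips(alphas: Sequence[float], threshold: float = 0.5) -> np.ndarray:
    """Clip calls: FMs (1) iff ``alpha >= threshold`` (ties count as FMs)."""
    alphas = np.asarray(alphas, dtype=float)
    if ((alphas < 0) | (alphas > 1)).any():
        raise ValueError("alphas must lie in [0, 1]")
    return (alphas >= threshold).astype(int)


def fms_frequency(clip_calls: Sequence[int]) -> float:
    """Proportion of FMs clips in the video."""
    calls = np.asarray(clip_calls)
    if calls.size == 0:
        raise ValueError("no clips")
    return float(calls.sum() / calls.size)


def classify_group_by_frequency(
    frequency: float, threshold: float
) -> Literal["normal", "risk"]:
    """Normal iff the FMs frequency reaches the calibrated threshold."""
    return "normal" if frequency >= threshold else "risk"


def classify_fms_category(
    frequency: float, threshold: float = 0.603
) -> Literal["continuous", "intermittent"]:
    """Continuous FMs iff frequency >= 0.603 (tie resolved as continuous)."""
    return "continuous" if frequency >= threshold else "intermittent"


def youden_threshold(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Score threshold maximizing sensitivity + specificity - 1.

    Candidate thresholds are midpoints between adjacent distinct scores;
    calls use ``score >= threshold`` for the positive class.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes required to calibrate a threshold")
    uniq = np.unique(scores)
    cands = np.concatenate([[uniq[0] - 1e-9], (uniq[:-1] + uniq[1:]) / 2, [uniq[-1] + 1e-9]])
    best, best_j = cands[0], -np.inf
    pos = labels == 1
    for c in cands:
        pred = scores >= c
        sens = (pred & pos).sum() / pos.sum()
        spec = (~pred & ~pos).sum() / (~pos).sum()
        j = sens + spec - 1
        if j > best_j:
            best_j, best = j, c
    return float(best)


def predict_video(
    model: MAMModel,
    coords: np.ndarray,
    fps: float,
    ch: Characteristics | None = None,
    T: int | None = None,
    step: int | None = None,
    subject_id: str = "",
    frequency_threshold: float | None = None,
) -> PredictionResult:
    """Full inference on one preprocessed coordinate array.

    Splits into instances, scores each clip, and derives the FMs frequency;
    group/category calls are attached when a frequency threshold is given.
    """
    from .features import window_distance_tensor

    cfg = model.config
    T = T or cfg.T
    step = step or cfg.step
    starts = instance_starts(coords.shape[0], T=T, step=step)
    tensors = np.stack([window_distance_tensor(coords, int(s), T) for s in starts])
    alphas = model.predict_alpha(tensors)
    calls = binarize_clips(alphas, cfg.clip_threshold)
    freq = fms_frequency(calls)
    # bag probability needs characteristics when the info branch is enabled
    normal_p = (
        model.predict_bag_probability(alphas, ch)
        if (ch is not None or not cfg.use_info)
        else None
    )
    result = PredictionResult(
        subject_id=subject_id,
        start_frames=starts,
        alphas=alphas,
        fps=fps,
        T=T,
        fms_frequency=freq,
        normal_probability=normal_p,
    )
    if frequency_threshold is not None:
        result.group_call = classify_group_by_frequency(freq, frequency_threshold)
    result.category_call = classify_fms_category(freq, cfg.category_threshold)
    return result


# ---------------------------------------------------------------------------
# agreement and classification statistics
# ---------------------------------------------------------------------------

def concordance_kappa(calls_a: Sequence[int], calls_b: Sequence[int]) -> float:
    """Cohen's kappa between two aligned binary call sequences.

    Expected agreement uses the product of the raters' marginals; when the
    expected agreement is 1 (both raters constant) kappa is undefined and
    NaN is returned.
    """
    a = np.asarray(calls_a)
    b = np.asarray(calls_b)
    if a.shape != b.shape:
        raise ValueError("call sequences must have equal length")
    n = a.size
    if n == 0:
        raise ValueError("empty call sequences")
    p_o = float((a == b).sum() / n)
    cats = np.union1d(a, b)
    p_e = float(sum((a == c).sum() / n * (b == c).sum() / n for c in cats))
    if p_e == 1.0:
        return math.nan
    return (p_o - p_e) / (1.0 - p_e)


def per_video_kappa(
    model: MAMModel,
    coords: np.ndarray,
    ann: FMIntervalAnnotation,
    fps: float,
    T: int | None = None,
    step: int | None = None,
) -> float:
    """Model-vs-expert clip concordance for one video.

    Both raters are evaluated on the same window grid: the model via
    thresholded instance alphas, the expert via the >0.5-coverage rule
    applied to the annotated intervals.
    """
    cfg = model.config
    T = T or cfg.T
    step = step or cfg.step
    result = predict_video(model, coords, fps, T=T, step=step)
    model_calls = binarize_clips(result.alphas, cfg.clip_threshold)
    expert_calls = np.array(
        [
            1 if label_clip_from_annotation(ann, int(s), T=T, fps=fps) == "FMs" else 0
            for s in result.start_frames
        ]
    )
    return concordance_kappa(model_calls, expert_calls)


@dataclasses.dataclass
class ConfusionCounts:
    """Infant-level confusion counts (positive class = risk detection task
    is the caller's choice; metrics are label-agnostic)."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("counts must be non-negative")
        if self.tp + self.fn + self.tn + self.fp == 0:
            raise ValueError("confusion table is empty")


def classification_metrics(cm: ConfusionCounts) -> dict[str, float]:
    """Accuracy, sensitivity, specificity, PPV and NPV.

    A metric whose denominator is zero is reported as NaN.
    """

    def ratio(num, den):
        return num / den if den > 0 else math.nan

    total = cm.tp + cm.fn + cm.tn + cm.fp
    return {
        "accuracy": ratio(cm.tp + cm.tn, total),
        "sensitivity": ratio(cm.tp, cm.tp + cm.fn),
        "specificity": ratio(cm.tn, cm.tn + cm.fp),
        "ppv": ratio(cm.tp, cm.tp + cm.fp),
        "npv": ratio(cm.tn, cm.tn + cm.fn),
    }


def roc_auc(
    scores: Sequence[float],
    labels: Sequence[int],
    ci: bool = False,
    n_boot: int = 2000,
    seed: int = 0,
) -> float | tuple[float, tuple[float, float]]:
    """Area under the ROC curve by the tie-corrected Mann-Whitney statistic.

    With ``ci=True`` also returns a stratified-bootstrap 95% interval
    (``n_boot`` resamples, seeded).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes required for ROC analysis")

    def auc(p, q):
        ranks = stats.rankdata(np.concatenate([p, q]))
        return (ranks[: p.size].sum() - p.size * (p.size + 1) / 2) / (p.size * q.size)

    point = float(auc(pos, neg))
    if not ci:
        return point
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bp = pos[rng.integers(0, pos.size, pos.size)]
        bq = neg[rng.integers(0, neg.size, neg.size)]
        boots[i] = auc(bp, bq)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return point, (float(lo), float(hi))


def rank_clips_for_review(result: PredictionResult, k: int) -> list[dict]:
    """Top-``k`` clips by FMs probability, for expert review or teaching.

    Ties break by earlier start frame; returns start/end in seconds with
    the alpha of each clip.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    order = np.lexsort((result.start_frames, -result.alphas))
    out = []
    for idx in order[:k]:
        start = int(result.start_frames[idx])
        out.append(
            {
                "start_s": start / result.fps,
                "end_s": (start + result.T) / result.fps,
                "alpha": float(result.alphas[idx]),
            }
        )
    return out


def cohort_balance_tests(
    *,
    table: np.ndarray | None = None,
    sample_a: Sequence[float] | None = None,
    sample_b: Sequence[float] | None = None,
    normality_alpha: float = 0.05,
) -> dict:
    """Two-tailed group-balance test for one characteristic.

    Categorical (``table``: 2x2 counts): chi-square with Yates continuity
    correction.  Continuous (two samples): Shapiro normality screen at 0.05
    on each group selects Student's t-test (both normal) or Mann-Whitney.
    """
    if table is not None:
        table = np.asarray(table)
        if table.shape != (2, 2) or (table < 0).any() or table.sum() == 0:
            raise ValueError("need a non-degenerate 2x2 count table")
        chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
        return {"test": "chi-square (Yates)", "statistic": float(chi2), "p": float(p)}
    if sample_a is None or sample_b is None:
        raise ValueError("provide either a 2x2 table or two samples")
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    normal = (
        stats.shapiro(a).pvalue > normality_alpha
        and stats.shapiro(b).pvalue > normality_alpha
    )
    if normal:
        res = stats.ttest_ind(a, b)
        return {"test": "t-test", "statistic": float(res.statistic), "p": float(res.pvalue)}
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {"test": "Mann-Whitney", "statistic": float(res.statistic), "p": float(res.pvalue)}
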