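"""Joint training of the reference, main and info branches.

Each optimization step uses one composed batch: reference clips of both
classes (nominally 16 FMs + 16 non-FMs) plus the instances of one normal
and one risk bag (up to 16 each, subsampled uniformly without replacement).
All clips pass the *shared* spatio-temporal encoder in a single forward;
the four loss terms are summed unweighted and minimized with momentum SGD
under a triangular cyclic learning rate (initial/base rate 1e-3 rising to
3e-3 at mid-cycle over a 10-epoch cycle).

Instance features are materialized lazily from preprocessed coordinate
arrays, so whole-video distance tensors never need to be held in memory.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from . import autodiff as ad
from ._malloc import tune_malloc
from .bags import instance_starts
from .features import window_distance_tensor
from .losses import (
    class_centers,
    closeness,
    cross_entropy_bags,
    cross_entropy_clips,
    total_loss,
    triplet_batch_mean,
)
from .network import DTYPE, Characteristics, MAMModel, ModelConfig
from .skeleton_io import FMIntervalAnnotation

__all__ = [
    "LazyClip",
    "TrainingBag",
    "TrainingDataset",
    "TrainingBatch",
    "compose_batch",
    "train_mam",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclasses.dataclass
class LazyClip:
    """A clip addressed by (sequence, start); features built on demand."""

    coords: np.ndarray  # preprocessed (T_total, V, C) array, shared
    start: int
    T: int
    label: int | None = None  # 1 = FMs, 0 = non-FMs (reference clips)

    def materialize(self) -> np.ndarray:
        return window_distance_tensor(self.coords, self.start, self.T).astype(DTYPE)


@dataclasses.dataclass
class TrainingBag:
    """One video: preprocessed coordinates, label, characteristics."""

    coords: np.ndarray
    y: int  # 1 = normal, 0 = risk
    characteristics: Characteristics | None
    subject_id: str
    annotation: FMIntervalAnnotation | None = None
    starts: np.ndarray | None = None

    def instance_clips(self, T: int, step: int) -> list[LazyClip]:
        if self.starts is None:
            self.starts = instance_starts(self.coords.shape[0], T=T, step=step)
        return [LazyClip(self.coords, int(s), T) for s in self.starts]


@dataclasses.dataclass
class TrainingDataset:
    """Reference-clip pool plus labeled bags."""

    ref_clips: list[LazyClip]
    bags: list[TrainingBag]
    T: int
    step: int
    fps: float

    def __post_init__(self) -> None:
        labels = {c.label for c in self.ref_clips}
        if not {0, 1} <= labels:
            raise ValueError("reference pool must contain both classes")
        ys = {b.y for b in self.bags}
        if not {0, 1} <= ys:
            raise ValueError("bag pool must contain both normal and risk bags")

    def info_stats(self) -> tuple[np.ndarray, np.ndarray]:
        """Training-set mean/sd of (GA, BW, CA) for standardization."""
        rows = np.array(
            [
                [
                    b.characteristics.gestational_age_wk,
                    b.characteristics.birth_weight_g,
                    b.characteristics.corrected_age_wk,
                ]
                for b in self.bags
                if b.characteristics is not None
            ]
        )
        if rows.size == 0:
            raise ValueError("no characteristics available")
        sd = rows.std(axis=0)
        sd[sd == 0] = 1.0
        return rows.mean(axis=0), sd


@dataclasses.dataclass
class TrainingBatch:
    ref_tensors: np.ndarray        # (n_ref, T, C, V, V)
    ref_labels: np.ndarray         # (n_ref,)
    bag_tensors: list[np.ndarray]  # per bag: (k, T, C, V, V)
    bag_labels: list[int]
    bag_characteristics: list[Characteristics | None]


def _sample(pool: Sequence, k: int, rng: np.random.Generator) -> list:
    if len(pool) == 0:
        raise ValueError("empty sampling pool")
    if len(pool) <= k:
        return list(pool)
    idx = rng.choice(len(pool), size=k, replace=False)
    return [pool[i] for i in idx]


def compose_batch(
    ref_pool: Sequence[LazyClip],
    normal_bag: TrainingBag,
    risk_bag: TrainingBag,
    rng: np.random.Generator,
    T: int,
    step: int,
    ref_per_class: int = 16,
    inst_per_bag: int = 16,
) -> TrainingBatch:
    """Sample one training batch (nominally 2*ref_per_class + 2*inst_per_bag).

    Bags with fewer instances than requested contribute all of them.
    """
    fms = [c for c in ref_pool if c.label == 1]
    non = [c for c in ref_pool if c.label == 0]
    if not fms or not non:
        raise ValueError("reference pool must contain both classes")
    refs = _sample(fms, ref_per_class, rng) + _sample(non, ref_per_class, rng)
    ref_tensors = np.stack([c.materialize() for c in refs])
    ref_labels = np.array([c.label for c in refs])
    bag_tensors, bag_labels, bag_chars = [], [], []
    for bag in (normal_bag, risk_bag):
        clips = _sample(bag.instance_clips(T, step), inst_per_bag, rng)
        bag_tensors.append(np.stack([c.materialize() for c in clips]))
        bag_labels.append(bag.y)
        bag_chars.append(bag.characteristics)
    return TrainingBatch(ref_tensors, ref_labels, bag_tensors, bag_labels, bag_chars)


class _SGD:
    """Momentum SGD over the model's parameter tensors."""

    def __init__(self, params, momentum: float = 0.9):
        self.params = list(params)
        self.momentum = momentum
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr: float) -> None:
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            v *= self.momentum
            v += p.grad
            p.data -= (lr * v).astype(p.data.dtype)
            p.grad = None


def _cyclic_lr(step: int, steps_per_cycle: int, base_lr: float, max_lr: float) -> float:
    """Triangular cycle rising from ``base_lr`` (the published initial rate)
    to ``max_lr`` at mid-cycle and back."""
    x = (step % steps_per_cycle) / steps_per_cycle
    return base_lr + (max_lr - base_lr) * (1.0 - abs(1.0 - 2.0 * x))


def _train_step(
    model: MAMModel, batch: TrainingBatch
) -> tuple[ad.Tensor, dict[str, float]]:
    cfg = model.config
    n_ref = batch.ref_tensors.shape[0]
    all_tensors = np.concatenate([batch.ref_tensors] + batch.bag_tensors)
    reps = model.encode_clip(all_tensors)
    alphas = model.classify_clip(reps)

    ref_reps = reps[:n_ref]
    ref_alphas = alphas[:n_ref]
    l_c1 = cross_entropy_clips(batch.ref_labels, ref_alphas)
    l_t = triplet_batch_mean(ref_reps, batch.ref_labels, margin=cfg.margin)
    p_center, n_center = class_centers(ref_reps, batch.ref_labels)

    inst_reps = reps[n_ref:]
    inst_alphas = alphas[n_ref:]
    l_c = closeness(inst_reps, inst_alphas, p_center, n_center)

    bag_probs = []
    offset = n_ref
    for tensors, ch in zip(batch.bag_tensors, batch.bag_characteristics):
        k = tensors.shape[0]
        bag_alphas = alphas[offset : offset + k]
        offset += k
        s, _ = model.fuse_bag(bag_alphas)
        info = model.encode_info(ch) if (cfg.use_info and ch is not None) else None
        normal_p, _ = model.predict_bag(s, info)
        bag_probs.append(normal_p.reshape(1))
    l_c2 = cross_entropy_bags(
        np.asarray(batch.bag_labels, dtype=float), ad.concatenate(bag_probs)
    )

    loss = total_loss(l_t, l_c, l_c1, l_c2)
    terms = {
        "L_t": l_t.item(),
        "L_c": l_c.item(),
        "L_c1": l_c1.item(),
        "L_c2": l_c2.item(),
        "total": loss.item(),
    }
    return loss, terms


def _pretrain_step(model: MAMModel, tensors: np.ndarray, labels: np.ndarray) -> float:
    """Reference-branch pretraining step: cross-entropy + Triplet only."""
    reps = model.encode_clip(tensors)
    alphas = model.classify_clip(reps)
    l_c1 = cross_entropy_clips(labels, alphas)
    l_t = triplet_batch_mean(reps, labels, margin=model.config.margin)
    loss = l_c1 + l_t
    value = loss.item()
    loss.backward()
    return value


def train_mam(
    dataset: TrainingDataset,
    config: ModelConfig,
    epochs: int = 300,
    pretrain_epochs: int = 50,
    pairs_per_epoch: int | None = None,
    ref_per_class: int = 16,
    inst_per_bag: int = 16,
    base_lr: float = 1e-3,
    max_lr: float = 3e-3,
    momentum: float = 0.9,
    cycle_epochs: int = 10,
    log_path: str | Path | None = None,
    verbose: bool = False,
) -> tuple[MAMModel, list[dict]]:
    """Train the full model; returns the model and a per-epoch loss log.

    Training follows the published two-stage protocol: the reference branch
    (shared encoder + classifier) is first pretrained on labeled FMs /
    non-FMs reference clips with the cross-entropy and Triplet losses, then
    all three branches are trained jointly.  One joint epoch pairs each
    risk (minority-class) bag — or ``pairs_per_epoch`` random pairs when
    given — with a randomly matched bag of the other class.  Training
    aborts on a non-finite loss, returning the parameters from the end of
    the previous epoch.
    """
    tune_malloc()
    model = MAMModel(config)
    model.set_info_stats(*dataset.info_stats())
    rng = np.random.default_rng(config.seed)
    opt = _SGD(model.parameters(), momentum=momentum)

    normal_bags = [b for b in dataset.bags if b.y == 1]
    risk_bags = [b for b in dataset.bags if b.y == 0]
    n_pairs = pairs_per_epoch or min(len(normal_bags), len(risk_bags))
    steps_per_cycle = max(1, cycle_epochs * n_pairs)

    # -- stage 1: reference-branch pretraining -------------------------------
    fms_pool = [c for c in dataset.ref_clips if c.label == 1]
    non_pool = [c for c in dataset.ref_clips if c.label == 0]
    pre_step = 0
    for epoch in range(pretrain_epochs):
        for _ in range(n_pairs):
            refs = _sample(fms_pool, ref_per_class, rng) + _sample(
                non_pool, ref_per_class, rng
            )
            tensors = np.stack([c.materialize() for c in refs])
            labels = np.array([c.label for c in refs])
            value = _pretrain_step(model, tensors, labels)
            if not np.isfinite(value):
                raise FloatingPointError(
                    f"pretraining diverged at epoch {epoch}"
                )
            opt.step(_cyclic_lr(pre_step, steps_per_cycle, base_lr, max_lr))
            pre_step += 1
        if verbose:
            print(f"pretrain epoch {epoch:3d}  L_c1+L_t {value:.4f}")

    log: list[dict] = []
    snapshot = [p.data.copy() for p in model.parameters()]
    step = 0
    log_file = open(log_path, "w") if log_path is not None else None
    try:
        for epoch in range(epochs):
            # random normal/risk matching, minority class cycled through
            order_n = rng.permutation(len(normal_bags))
            order_r = rng.permutation(len(risk_bags))
            sums = {"L_t": 0.0, "L_c": 0.0, "L_c1": 0.0, "L_c2": 0.0, "total": 0.0}
            lr = base_lr
            for i in range(n_pairs):
                batch = compose_batch(
                    dataset.ref_clips,
                    normal_bags[order_n[i % len(normal_bags)]],
                    risk_bags[order_r[i % len(risk_bags)]],
                    rng,
                    T=dataset.T,
                    step=dataset.step,
                    ref_per_class=ref_per_class,
                    inst_per_bag=inst_per_bag,
                )
                loss, terms = _train_step(model, batch)
                if not np.isfinite(terms["total"]):
                    if log_file:
                        log_file.close()
                    for p, data in zip(model.parameters(), snapshot):
                        p.data = data
                    raise FloatingPointError(
                        f"training diverged at epoch {epoch}; restored last "
                        "good parameters"
                    )
                lr = _cyclic_lr(step, steps_per_cycle, base_lr, max_lr)
                loss.backward()
                opt.step(lr)
                step += 1
                for k in sums:
                    sums[k] += terms[k]
            entry = {k: v / n_pairs for k, v in sums.items()}
            entry.update(epoch=epoch, lr=lr)
            log.append(entry)
            if log_file:
                log_file.write(json.dumps(entry) + "\n")
                log_file.flush()
            if verbose:
                print(
                    f"epoch {epoch:3d}  total {entry['total']:.4f}  "
                    f"L_c1 {entry['L_c1']:.4f}  L_t {entry['L_t']:.4f}  "
                    f"L_c {entry['L_c']:.4f}  L_c2 {entry['L_c2']:.4f}  "
                    f"lr {lr:.2e}"
                )
            snapshot = [p.data.copy() for p in model.parameters()]
    finally:
        if log_file and not log_file.closed:
            log_file.close()
    return model, log


def refine_bag_head(
    model: MAMModel,
    bag_samples: Sequence[tuple[np.ndarray, Characteristics | None, int]],
    epochs: int = 200,
    lr: float = 1e-2,
    momentum: float = 0.9,
    weight_decay: float = 0.2,
    seed: int = 0,
) -> list[float]:
    """Continue training only the bag-level parameters on cached alphas.

    Joint training at desk scale sees roughly forty times fewer bag examples
    per parameter update than the full-scale protocol, which leaves the
    small fusion/info/head layers under-fit relative to the encoder.  This
    stage re-uses instance probabilities already computed for threshold
    calibration (the encoder is not touched or re-run) and continues the
    bag cross-entropy on the fusion, info and head parameters alone.  A
    ridge penalty (``weight_decay``) on the *characteristics pathway only*
    (info encoder/head and the info columns of the final head) keeps it
    from memorizing the small calibration set: with a few dozen bags a
    16-unit encoder of four characteristics can fit any labels, so its
    weights persist only where the data consistently supports them; the
    scalar video-feature pathway is left unpenalized.

    ``bag_samples``: tuples of (instance alphas, characteristics or None,
    label y with 1 = normal).  Returns the per-epoch loss trace.
    """
    params = (
        model.bag_fuse.parameters()
        + model.bag_head.parameters()
        + (model.info_encoder.parameters() + model.info_head.parameters()
           if model.config.use_info else [])
    )
    info_params = (
        set(map(id, model.info_encoder.parameters()))
        | set(map(id, model.info_head.parameters()))
        if model.config.use_info
        else set()
    )
    opt = _SGD(params, momentum=momentum)
    rng = np.random.default_rng(seed)
    trace: list[float] = []
    for _ in range(epochs):
        order = rng.permutation(len(bag_samples))
        total = 0.0
        for idx in order:
            alphas, ch, y = bag_samples[idx]
            s, _ = model.fuse_bag(ad.Tensor(np.asarray(alphas, dtype=np.float32)))
            info = (
                model.encode_info(ch)
                if (model.config.use_info and ch is not None)
                else None
            )
            normal_p, _ = model.predict_bag(s, info)
            loss = cross_entropy_bags(np.array([float(y)]), normal_p.reshape(1))
            total += loss.item()
            loss.backward()
            if weight_decay:
                for p in params:
                    if id(p) in info_params:
                        p.data *= 1.0 - lr * weight_decay
                if model.config.use_info:
                    # info columns of the final head (row 0 acts on s)
                    model.bag_head.weight.data[1:, :] *= 1.0 - lr * weight_decay
            opt.step(lr)
        trace.append(total / len(bag_samples))
        if not np.isfinite(trace[-1]):
            raise FloatingPointError("bag-head refinement diverged")
    return trace


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

_SCHEMA = "mam-checkpoint-1"


def save_checkpoint(model: MAMModel, path, extra: dict | None = None) -> None:
    """Single-archive checkpoint: parameters, config, standardization stats."""
    arrays = {f"param:{name}": p.data for name, p in model.named_parameters()}
    meta = {
        "schema": _SCHEMA,
        "config": model.config.to_dict(),
        "extra": extra or {},
    }
    np.savez(
        path,
        __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        info_mean=model.info_mean,
        info_sd=model.info_sd,
        **arrays,
    )


def load_checkpoint(path) -> tuple[MAMModel, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("schema") != _SCHEMA:
            raise ValueError(f"unknown checkpoint schema {meta.get('schema')!r}")
        model = MAMModel(ModelConfig.from_dict(meta["config"]))
        params = dict(model.named_parameters())
        for key in data.files:
            if key.startswith("param:"):
                name = key[len("param:"):]
                if name not in params:
                    raise ValueError(f"checkpoint parameter {name!r} not in model")
                if params[name].data.shape != data[key].shape:
                    raise ValueError(f"shape mismatch for parameter {name!r}")
                params[name].data = data[key].copy()
        model.set_info_stats(data["info_mean"], data["info_sd"])
    return model, meta["extra"]
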