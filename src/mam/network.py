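"""The motor-assessment network.

Architecture (shared between the reference and main branches):

1. Each frame's ``[C, V, V]`` distance stack passes a 2-D convolution with a
   kernel spanning a full joint axis (size ``[17, 1]``, 3 input channels, 64
   output channels, no padding), which fuses every joint's spatial relations
   into itself and yields 17 joint tokens of dimension 64.
2. A spatial Transformer encoder (2 layers, embed 64, 4 heads, FFN 256)
   exchanges information between joint tokens; attention-based fusion
   collapses them into one frame vector.
3. Sinusoidal position encoding is added over the frame axis, a temporal
   Transformer encoder of the same configuration exchanges information over
   time, and a second attention-based fusion yields the 64-dim clip
   representation.
4. A linear classifier over the clip representation gives the FMs
   probability ``alpha`` of the clip.
5. Instance alphas of one video are combined by attention-based fusion into
   a scalar video feature ``s``; characteristics pass a small fully
   connected info encoder; a final linear head over ``[s, info]`` gives the
   normal/risk probability of the bag.

All parameters live in the tape-based autodiff engine; forward passes under
``autodiff.no_grad()`` build no graph and are used for inference.
"""

from __future__ import annotations

import dataclasses
from typing import Iterator, Literal, Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .skeleton_io import N_DIMS, N_JOINTS

__all__ = [
    "ModelConfig",
    "Characteristics",
    "MAMModel",
    "AttentionFusion",
    "attention_fuse",
    "contribution_curve",
]

DTYPE = np.float32


@dataclasses.dataclass
class ModelConfig:
    """Hyperparameters of the motor-assessment network.

    Defaults follow the published configuration: embedding dimension 64,
    4 attention heads, 2 encoder layers in each of the spatial and temporal
    Transformers, feed-forward dimension 256, 240-frame instances stepped by
    150 frames, Triplet-loss margin 0.4, clip threshold 0.5 and
    continuous/intermittent frequency threshold 0.603.
    """

    embed_dim: int = 64
    heads: int = 4
    encoder_layers: int = 2
    ffn_dim: int = 256
    T: int = 240
    step: int = 150
    margin: float = 0.4
    clip_threshold: float = 0.5
    category_threshold: float = 0.603
    use_info: bool = True
    combine: Literal["linear_head", "probability_mean"] = "linear_head"
    attn_hidden: int = 64
    info_hidden: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("embed_dim", "heads", "encoder_layers", "ffn_dim", "T",
                     "step", "attn_hidden", "info_hidden"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.embed_dim % self.heads != 0:
            raise ValueError("heads must divide embed_dim")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


@dataclasses.dataclass
class Characteristics:
    """Basic infant characteristics used by the info branch."""

    sex: Literal["male", "female"]
    gestational_age_wk: float
    birth_weight_g: float
    corrected_age_wk: float

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female'; got {self.sex!r}")
        if not self.gestational_age_wk > 0:
            raise ValueError("gestational age must be positive")
        if not self.birth_weight_g > 0:
            raise ValueError("birth weight must be positive")
        if not 9 <= self.corrected_age_wk <= 20:
            raise ValueError(
                "corrected age must lie in the 9-20 week assessment window"
            )


# ---------------------------------------------------------------------------
# module machinery
# ---------------------------------------------------------------------------

def _trunc_normal(rng: np.random.Generator, shape, std: float) -> np.ndarray:
    x = rng.normal(0.0, std, size=shape)
    # redraw once for tail values, then clamp: truncation at two standard devs
    bad = np.abs(x) > 2 * std
    x[bad] = rng.normal(0.0, std, size=int(bad.sum()))
    return np.clip(x, -2 * std, 2 * std).astype(DTYPE)


class Module:
    """Tiny parameter-container base class."""

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        std = float(np.sqrt(2.0 / (d_in + d_out)))
        self.weight = Tensor(_trunc_normal(rng, (d_in, d_out), std), requires_grad=True)
        self.bias = Tensor(np.zeros(d_out, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        d_out = self.bias.shape[0]
        if x.ndim == 1:
            return ad.affine(x.reshape(1, x.shape[0]), self.weight, self.bias).reshape(d_out)
        if x.ndim == 2:
            return ad.affine(x, self.weight, self.bias)
        lead = x.shape[:-1]
        flat = x.reshape(int(np.prod(lead)), x.shape[-1])
        return ad.affine(flat, self.weight, self.bias).reshape(lead + (d_out,))


class LayerNorm(Module):
    def __init__(self, d: int):
        self.gamma = Tensor(np.ones(d, dtype=DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(d, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.layer_norm(x, self.gamma, self.beta)


class MultiHeadSelfAttention(Module):
    def __init__(self, d: int, heads: int, rng: np.random.Generator):
        self.heads = heads
        self.d_head = d // heads
        self.wq = Linear(d, d, rng)
        self.wk = Linear(d, d, rng)
        self.wv = Linear(d, d, rng)
        self.wo = Linear(d, d, rng)

    def __call__(self, x: Tensor) -> Tensor:
        b, L, d = x.shape
        h, dh = self.heads, self.d_head

        def split(t: Tensor) -> Tensor:
            return t.reshape(b, L, h, dh).transpose(0, 2, 1, 3)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        attn = ad.softmax(scores, axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(b, L, d)
        return self.wo(ctx)


class EncoderLayer(Module):
    """Post-norm Transformer encoder layer with ReLU feed-forward."""

    def __init__(self, d: int, heads: int, ffn: int, rng: np.random.Generator):
        self.attn = MultiHeadSelfAttention(d, heads, rng)
        self.norm1 = LayerNorm(d)
        self.ff1 = Linear(d, ffn, rng)
        self.ff2 = Linear(ffn, d, rng)
        self.norm2 = LayerNorm(d)

    def __call__(self, x: Tensor) -> Tensor:
        x = self.norm1(x + self.attn(x))
        return self.norm2(x + self.ff2(self.ff1(x).relu()))


class AttentionFusion(Module):
    """Attention-based fusion: ``score = l2(tanh(l1(v)))``; softmax weights;
    the output is the weight-averaged input."""

    def __init__(self, d: int, hidden: int, rng: np.random.Generator):
        self.l1 = Linear(d, hidden, rng)
        self.l2 = Linear(hidden, 1, rng)

    def scores(self, x: Tensor) -> Tensor:
        """Raw (pre-softmax) scalar score per vector; shape (..., L)."""
        s = self.l2(self.l1(x).tanh())
        return s.reshape(s.shape[:-1])

    def __call__(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """Fuse over the second-to-last axis: (..., L, d) -> (..., d)."""
        w = ad.softmax(self.scores(x), axis=-1)
        fused = (w.reshape(w.shape + (1,)) * x).sum(axis=-2)
        return fused, w


def attention_fuse(fusion: AttentionFusion, vectors) -> tuple[np.ndarray, np.ndarray]:
    """Functional wrapper: fuse a list/array of d-dim vectors (inference)."""
    arr = np.asarray([np.asarray(v, dtype=DTYPE) for v in vectors])
    if arr.ndim != 2 or arr.shape[0] == 0:
        raise ValueError("need a non-empty list of equal-dimension vectors")
    with ad.no_grad():
        fused, w = fusion(Tensor(arr))
    return fused.data, w.data


def sinusoidal_position_encoding(T: int, d: int) -> np.ndarray:
    """Standard fixed sinusoidal position encoding, shape ``(T, d)``."""
    pos = np.arange(T)[:, None]
    i = np.arange(d // 2)[None, :]
    angle = pos / np.power(10000.0, 2 * i / d)
    pe = np.zeros((T, d))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe.astype(DTYPE)


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class ClipEncoder(Module):
    """Spatio-temporal Transformer: ``(B, T, C, V, V) -> (B, embed_dim)``."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        d = cfg.embed_dim
        # Conv2D kernel [V, 1]: for output joint token j,
        # token_j[k] = sum_{c,i} W[c,i,k] * x[c,i,j] + b[k]
        std = float(np.sqrt(2.0 / (N_DIMS * N_JOINTS + d)))
        self.conv_w = Tensor(
            _trunc_normal(rng, (N_DIMS * N_JOINTS, d), std), requires_grad=True
        )
        self.conv_b = Tensor(np.zeros(d, dtype=DTYPE), requires_grad=True)
        self.spatial = [
            EncoderLayer(d, cfg.heads, cfg.ffn_dim, rng)
            for _ in range(cfg.encoder_layers)
        ]
        self.spatial_fuse = AttentionFusion(d, cfg.attn_hidden, rng)
        self.temporal = [
            EncoderLayer(d, cfg.heads, cfg.ffn_dim, rng)
            for _ in range(cfg.encoder_layers)
        ]
        self.temporal_fuse = AttentionFusion(d, cfg.attn_hidden, rng)
        self.embed_dim = d

    def __call__(self, x: Tensor) -> Tensor:
        b, t, c, v, v2 = x.shape
        if (c, v, v2) != (N_DIMS, N_JOINTS, N_JOINTS):
            raise ValueError(f"instance tensor must be (B, T, {N_DIMS}, "
                             f"{N_JOINTS}, {N_JOINTS}); got {x.shape}")
        d = self.embed_dim
        # (B,T,C,V_i,V_j) -> (B,T,V_j,C,V_i) -> joint tokens via the [V,1] conv
        tokens = (
            x.transpose(0, 1, 4, 2, 3).reshape(b * t * v, c * v) @ self.conv_w
            + self.conv_b
        ).reshape(b * t, v, d)
        for layer in self.spatial:
            tokens = layer(tokens)
        frame_vec, _ = self.spatial_fuse(tokens)          # (B*T, d)
        seq = frame_vec.reshape(b, t, d)
        seq = seq + sinusoidal_position_encoding(t, d)
        for layer in self.temporal:
            seq = layer(seq)
        clip_rep, _ = self.temporal_fuse(seq)             # (B, d)
        return clip_rep


class InfoEncoder(Module):
    """Fully connected encoder of the 5-vector of encoded characteristics."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.fc = Linear(5, cfg.info_hidden, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc(x).tanh()


class MAMModel(Module):
    """The full multi-instance motor-assessment model.

    Weights of the spatio-temporal Transformer and the clip classifier are
    shared between the reference branch (labeled FMs/non-FMs clips) and the
    main branch (bag instances): both call the same ``encoder`` and
    ``classifier`` objects.
    """

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        d = config.embed_dim
        self.encoder = ClipEncoder(config, rng)
        self.classifier = Linear(d, 2, rng)   # logits: [non-FMs, FMs]
        self.bag_fuse = AttentionFusion(1, config.info_hidden, rng)
        self.info_encoder = InfoEncoder(config, rng)
        head_in = 1 + (config.info_hidden if config.use_info else 0)
        self.bag_head = Linear(head_in, 2, rng)    # logits: [normal, risk]
        # probability_mean variant: separate info head producing probabilities
        self.info_head = Linear(config.info_hidden, 2, rng)
        # training-set standardization stats for (GA, BW, CA)
        self.info_mean = np.array([35.1, 2420.0, 12.5], dtype=DTYPE)
        self.info_sd = np.array([3.2, 670.0, 2.7], dtype=DTYPE)

    # -- clip path ----------------------------------------------------------

    def encode_clip(self, tensors: np.ndarray | Tensor) -> Tensor:
        """Encode instance tensors ``(B, T, C, V, V)`` (or one ``(T, C, V, V)``)
        into 64-dim clip representations."""
        if not isinstance(tensors, Tensor):
            tensors = Tensor(np.asarray(tensors, dtype=DTYPE))
        if tensors.ndim == 4:
            tensors = tensors.reshape((1,) + tensors.shape)
        reps = self.encoder(tensors)
        if not np.isfinite(reps.data).all():
            raise FloatingPointError("non-finite activations in clip encoder")
        return reps

    def classify_clip(self, reps: Tensor) -> Tensor:
        """FMs probability ``alpha`` per clip representation; shape (B,)."""
        probs = ad.softmax(self.classifier(reps), axis=-1)
        return probs[:, 1]

    def predict_alpha(self, tensors: np.ndarray, chunk: int = 32) -> np.ndarray:
        """Inference path: FMs probabilities for a stack of instance tensors."""
        tensors = np.asarray(tensors, dtype=DTYPE)
        out = []
        with ad.no_grad():
            for lo in range(0, tensors.shape[0], chunk):
                reps = self.encode_clip(tensors[lo : lo + chunk])
                out.append(self.classify_clip(reps).data)
        return np.concatenate(out) if out else np.empty(0)

    # -- bag path -----------------------------------------------------------

    def fuse_bag(self, alphas: Tensor) -> tuple[Tensor, Tensor]:
        """Attention-fuse instance FMs probabilities into the video feature.

        Each instance's scalar ``alpha`` is both the score input and the
        fused value, so the (absolute) contribution of an instance depends
        only on its own FMs probability.
        """
        if alphas.shape[0] == 0:
            raise ValueError("empty bag")
        col = alphas.reshape(alphas.shape[0], 1)
        fused, w = self.bag_fuse(col)
        return fused.reshape(()), w

    def encode_info(self, ch: Characteristics) -> Tensor:
        return self.info_encoder(Tensor(self._info_vector(ch)))

    def _info_vector(self, ch: Characteristics) -> np.ndarray:
        cont = (
            np.array(
                [ch.gestational_age_wk, ch.birth_weight_g, ch.corrected_age_wk],
                dtype=DTYPE,
            )
            - self.info_mean
        ) / self.info_sd
        onehot = np.array(
            [1.0, 0.0] if ch.sex == "male" else [0.0, 1.0], dtype=DTYPE
        )
        return np.concatenate([onehot, cont]).astype(DTYPE)

    def set_info_stats(self, mean, sd) -> None:
        """Store training-set mean/sd of (GA, BW, CA) for standardization."""
        self.info_mean = np.asarray(mean, dtype=DTYPE)
        self.info_sd = np.asarray(sd, dtype=DTYPE)

    def predict_bag(
        self, s: Tensor, info: Tensor | None
    ) -> tuple[Tensor, Tensor]:
        """Normal/risk probabilities of a bag from the video feature ``s``
        and (optionally) the info vector."""
        s_vec = s.reshape(1)
        if self.config.use_info:
            if info is None:
                raise ValueError("info branch is enabled but characteristics missing")
            if self.config.combine == "probability_mean":
                main = ad.softmax(self.bag_head_main_logits(s_vec), axis=-1)
                info_p = ad.softmax(self.info_head(info), axis=-1)
                probs = (main + info_p) * 0.5
            else:
                probs = ad.softmax(
                    self.bag_head(ad.concatenate([s_vec, info], axis=0)), axis=-1
                )
        else:
            probs = ad.softmax(self.bag_head(s_vec), axis=-1)
        return probs[0], probs[1]

    def bag_head_main_logits(self, s_vec: Tensor) -> Tensor:
        # first input column of the head acts on s alone
        w = self.bag_head.weight[0:1, :]
        return (s_vec.reshape(1, 1) @ w + self.bag_head.bias).reshape(2)

    def predict_bag_probability(
        self, alphas: np.ndarray, ch: Characteristics | None
    ) -> float:
        """Inference: normal probability of a bag from its instance alphas."""
        with ad.no_grad():
            s, _ = self.fuse_bag(Tensor(np.asarray(alphas, dtype=DTYPE)))
            info = (
                self.encode_info(ch)
                if (self.config.use_info and ch is not None)
                else None
            )
            normal_p, _ = self.predict_bag(s, info)
        return float(normal_p.data)


def contribution_curve(model: MAMModel, grid: Sequence[float]) -> np.ndarray:
    """Exponentiated (pre-softmax) fusion score over a grid of alphas.

    The softmax in attention-based fusion normalizes per bag, so the
    *absolute* contribution of an instance at FMs probability ``alpha`` is
    read off as ``exp(score(alpha))``.
    """
    grid = np.asarray(grid, dtype=DTYPE)
    with ad.no_grad():
        scores = model.bag_fuse.scores(Tensor(grid.reshape(-1, 1)))
    return np.exp(scores.data)
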