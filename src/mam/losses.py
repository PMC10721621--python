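"""The four training-loss terms and their unweighted sum.

* ``cross_entropy_clips`` — binary cross-entropy over reference clips
  (FMs vs non-FMs probabilities from the shared classifier).
* ``triplet_batch_mean`` — a batch-mean Triplet (margin) loss: for every
  anchor representation, the mean Euclidean distance to all representations
  of its own class (the anchor's zero self-distance included, exactly as the
  class sum is written) minus the mean distance to the other class, plus the
  margin, hinged at zero and averaged over anchors.
* ``closeness`` — pulls each instance representation toward the reference
  cluster center (FMs or non-FMs) matching its current prediction, with
  weight ``alpha * (1 - alpha)``, so uncertain clips (``alpha`` near 0.5)
  feel the strongest pull.  Bounded by 1/4.
* ``cross_entropy_bags`` — binary cross-entropy over bag (video) normal
  probabilities.

Cluster centers are recomputed per batch from the reference half of that
batch and treated as constants: gradient flows to the instance
representations only, preserving the "reference" semantics.  Probabilities
are clamped to ``[1e-7, 1 - 1e-7]`` inside the logs.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = [
    "EPS",
    "cross_entropy_clips",
    "cross_entropy_bags",
    "triplet_batch_mean",
    "class_centers",
    "closeness",
    "total_loss",
]

EPS = 1e-7



def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _binary_cross_entropy(labels, probs: Tensor) -> Tensor:
    labels = np.asarray(labels, dtype=probs.data.dtype)
    if labels.size == 0:
        raise ValueError("empty batch")
    if labels.shape != probs.shape:
        raise ValueError("labels and probabilities must have the same length")
    p = probs.clip(EPS, 1.0 - EPS)
    return -(labels * p.log() + (1.0 - labels) * (1.0 - p).log()).mean()


def cross_entropy_clips(labels, probs) -> Tensor:
    """Mean binary cross-entropy of reference-clip FMs probabilities.

    ``labels``: 0/1 array (1 = FMs); ``probs``: predicted FMs probabilities.
    """
    return _binary_cross_entropy(labels, _as_tensor(probs))


def cross_entropy_bags(labels, probs) -> Tensor:
    """Mean binary cross-entropy of bag normal probabilities (1 = normal)."""
    return _binary_cross_entropy(labels, _as_tensor(probs))


def _pairwise_distances(reps: Tensor) -> Tensor:
    n, d = reps.shape
    diff = reps.reshape(n, 1, d) - reps.reshape(1, n, d)
    # exact distances (zero diagonal); zero subgradient at coincident points
    return diff.square().sum(axis=2).sqrt0()


def triplet_batch_mean(reps, labels, margin: float = 0.4) -> Tensor:
    """Batch-mean Triplet loss over labeled clip representations.

    Parameters
    ----------
    reps:
        ``(n, d)`` clip representations.
    labels:
        0/1 per clip (1 = FMs).  Both classes must be present.
    margin:
        Separation margin between the class mean distances.
    """
    reps = _as_tensor(reps)
    labels = np.asarray(labels)
    n = labels.shape[0]
    n1 = int(labels.sum())
    n2 = n - n1
    if n1 == 0 or n2 == 0:
        raise ValueError("triplet loss requires both classes in the batch")
    D = _pairwise_distances(reps)
    pos = (labels == 1).astype(reps.data.dtype)
    neg = 1.0 - pos
    # (n,) mean distance of each anchor to the FMs / non-FMs representations
    mean_pos = (D @ Tensor((pos / n1).reshape(n, 1))).reshape(n)
    mean_neg = (D @ Tensor((neg / n2).reshape(n, 1))).reshape(n)
    sign = np.where(labels == 1, 1.0, -1.0).astype(reps.data.dtype)
    terms = (sign * (mean_pos - mean_neg) + margin).relu()
    return terms.mean()


def class_centers(ref_reps, ref_labels) -> tuple[np.ndarray, np.ndarray]:
    """Cluster centers (FMs mean, non-FMs mean) of the reference batch.

    Returned as plain arrays — constants with respect to differentiation.
    """
    reps = ref_reps.data if isinstance(ref_reps, Tensor) else np.asarray(ref_reps)
    labels = np.asarray(ref_labels)
    if (labels == 1).sum() == 0 or (labels == 0).sum() == 0:
        raise ValueError("both reference classes must be present")
    return reps[labels == 1].mean(axis=0), reps[labels == 0].mean(axis=0)


def _center_distance(reps: Tensor, center: np.ndarray) -> Tensor:
    diff = reps - center[None, :]
    return diff.square().sum(axis=1).sqrt0()


def closeness(instance_reps, alphas, p_center, n_center) -> Tensor:
    """Closeness loss of instance representations against reference centers.

    For each instance ``i`` with representation ``b_i`` and FMs probability
    ``alpha_i``, the softmax fraction of ``exp(Dist(b_i, c))`` over the two
    centers is taken with the center matching the prediction
    (``alpha_i >= 0.5`` — FMs center) in the numerator, weighted by
    ``alpha_i * (1 - alpha_i)`` and averaged over instances.  Evaluated in
    the numerically stable logistic form
    ``1 / (1 + exp(d_other - d_chosen))``.
    """
    reps = _as_tensor(instance_reps)
    alphas = _as_tensor(alphas)
    if reps.shape[0] == 0:
        raise ValueError("empty instance batch")
    p_center = np.asarray(p_center, dtype=reps.data.dtype)
    n_center = np.asarray(n_center, dtype=reps.data.dtype)
    d_p = _center_distance(reps, p_center)
    d_n = _center_distance(reps, n_center)
    m = (alphas.data >= 0.5).astype(reps.data.dtype)  # selection is not differentiated
    chosen = d_p * m + d_n * (1.0 - m)
    other = d_n * m + d_p * (1.0 - m)
    frac = 1.0 / (1.0 + (other - chosen).exp())
    w = alphas * (1.0 - alphas)
    return (w * frac).mean()


def total_loss(l_t, l_c, l_c1, l_c2) -> Tensor:
    """Unweighted sum of the four loss terms."""
    parts = {"L_t": l_t, "L_c": l_c, "L_c1": l_c1, "L_c2": l_c2}
    for name, part in parts.items():
        value = part.data if isinstance(part, Tensor) else part
        if not np.isfinite(value):
            raise FloatingPointError(f"loss component {name} is non-finite")
    return _as_tensor(l_t) + _as_tensor(l_c) + _as_tensor(l_c1) + _as_tensor(l_c2)
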