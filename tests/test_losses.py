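"""Loss terms vs independent brute-force oracles and analytic spot values."""

import math

import numpy as np
import pytest

from mam.autodiff import Tensor
from mam.losses import (
    class_centers,
    closeness,
    cross_entropy_bags,
    cross_entropy_clips,
    total_loss,
    triplet_batch_mean,
)

RNG = np.random.default_rng(7)


# -- independent oracles (plain loops, no shared code paths) ----------------

def oracle_cross_entropy(labels, probs, eps=1e-7):
    total = 0.0
    for g, p in zip(labels, probs):
        p = min(max(p, eps), 1 - eps)
        total += g * math.log(p) + (1 - g) * math.log(1 - p)
    return -total / len(labels)


def oracle_triplet(reps, labels, margin=0.4):
    n = len(labels)
    terms = []
    for i in range(n):
        same = [np.linalg.norm(reps[i] - reps[k]) for k in range(n) if labels[k] == labels[i]]
        other = [np.linalg.norm(reps[i] - reps[k]) for k in range(n) if labels[k] != labels[i]]
        terms.append(max(sum(same) / len(same) - sum(other) / len(other) + margin, 0.0))
    return sum(terms) / n


def oracle_closeness(reps, alphas, p_center, n_center):
    terms = []
    for b, a in zip(reps, alphas):
        dp = np.linalg.norm(b - p_center)
        dn = np.linalg.norm(b - n_center)
        if a >= 0.5:
            frac = math.exp(dp) / (math.exp(dp) + math.exp(dn))
        else:
            frac = math.exp(dn) / (math.exp(dp) + math.exp(dn))
        terms.append(a * (1 - a) * frac)
    return sum(terms) / len(terms)


# -- analytic spot values ----------------------------------------------------

class TestSpotValues:
    def test_cross_entropy_at_half_is_ln2(self):
        assert cross_entropy_clips([1], [0.5]).item() == pytest.approx(math.log(2), abs=1e-12)

    def test_cross_entropy_perfect_predictions_near_zero(self):
        assert cross_entropy_clips([1, 0], [1.0, 0.0]).item() <= 1.1e-7

    def test_triplet_zero_when_negatives_beyond_margin(self):
        # single FMs anchor at the origin; non-FMs all at distance 1
        reps = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [-1.0, 0.0]])
        labels = [1, 0, 0, 0]
        # the anchor's own term: max(0 - 1 + 0.4, 0) = 0
        anchor_term = max(0.0 - 1.0 + 0.4, 0.0)
        assert anchor_term == 0.0
        assert triplet_batch_mean(reps, labels).item() == pytest.approx(
            oracle_triplet(reps, labels), abs=1e-12
        )

    def test_triplet_equals_margin_for_coincident_reps(self):
        reps = np.zeros((6, 8))
        # every per-anchor term equals the margin exactly; the batch mean
        # only rounds at machine precision
        assert triplet_batch_mean(reps, [1, 1, 1, 0, 0, 0], margin=0.4).item() == pytest.approx(0.4, abs=1e-15)

    def test_closeness_at_alpha_half_equidistant_is_eighth(self):
        b = np.array([[0.0, 0.0]])
        val = closeness(b, [0.5], np.array([2.0, 0.0]), np.array([-2.0, 0.0]))
        assert val.item() == pytest.approx(0.125, abs=1e-12)

    def test_closeness_vanishes_at_confident_alpha(self):
        b = RNG.normal(size=(1, 4))
        p, n = RNG.normal(size=4), RNG.normal(size=4)
        assert closeness(b, [1.0], p, n).item() == pytest.approx(0.0, abs=1e-15)

    def test_total_loss_sums(self):
        assert total_loss(0.4, 0.125, 0.693, 0.693).item() == pytest.approx(1.911)

    def test_total_loss_rejects_nonfinite_naming_term(self):
        with pytest.raises(FloatingPointError, match="L_c1"):
            total_loss(0.0, 0.0, float("nan"), 0.0)


# -- brute-force agreement ----------------------------------------------------

@pytest.mark.parametrize("trial", range(5))
def test_cross_entropy_matches_loop_oracle(trial):
    rng = np.random.default_rng(trial)
    n = rng.integers(5, 11)
    labels = rng.integers(0, 2, n)
    probs = rng.uniform(0.001, 0.999, n)
    for fn in (cross_entropy_clips, cross_entropy_bags):
        assert fn(labels, probs).item() == pytest.approx(
            oracle_cross_entropy(labels, probs), rel=1e-12
        )


@pytest.mark.parametrize("trial", range(5))
def test_triplet_matches_loop_oracle(trial):
    rng = np.random.default_rng(100 + trial)
    n = int(rng.integers(5, 11))
    labels = np.concatenate([[1, 0], rng.integers(0, 2, n - 2)])
    reps = rng.normal(size=(n, 6))
    got = triplet_batch_mean(reps, labels).item()
    assert got == pytest.approx(oracle_triplet(reps, labels), rel=1e-10)


@pytest.mark.parametrize("trial", range(5))
def test_closeness_matches_loop_oracle(trial):
    rng = np.random.default_rng(200 + trial)
    n = int(rng.integers(5, 11))
    reps = rng.normal(size=(n, 6))
    alphas = rng.uniform(0, 1, n)
    p_c, n_c = rng.normal(size=6), rng.normal(size=6)
    got = closeness(reps, alphas, p_c, n_c).item()
    assert got == pytest.approx(oracle_closeness(reps, alphas, p_c, n_c), rel=1e-10)


# -- structural properties ----------------------------------------------------

class TestProperties:
    def test_losses_permutation_invariant(self):
        rng = np.random.default_rng(3)
        n = 8
        labels = np.array([1, 1, 1, 0, 0, 0, 1, 0])
        reps = rng.normal(size=(n, 5))
        alphas = rng.uniform(0, 1, n)
        probs = rng.uniform(0.01, 0.99, n)
        p_c, n_c = class_centers(reps, labels)
        perm = rng.permutation(n)
        assert cross_entropy_clips(labels, probs).item() == pytest.approx(
            cross_entropy_clips(labels[perm], probs[perm]).item(), rel=1e-12
        )
        assert triplet_batch_mean(reps, labels).item() == pytest.approx(
            triplet_batch_mean(reps[perm], labels[perm]).item(), rel=1e-10
        )
        assert closeness(reps, alphas, p_c, n_c).item() == pytest.approx(
            closeness(reps[perm], alphas[perm], p_c, n_c).item(), rel=1e-10
        )

    def test_closeness_bounded_by_quarter(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            reps = rng.normal(size=(6, 4)) * rng.uniform(0.1, 10)
            alphas = rng.uniform(0, 1, 6)
            val = closeness(reps, alphas, rng.normal(size=4), rng.normal(size=4)).item()
            assert 0.0 <= val <= 0.25

    def test_triplet_zero_when_classes_separated_beyond_margin(self):
        # two tight clusters far apart: every anchor satisfies the margin
        reps = np.vstack([np.zeros((4, 3)), 100.0 + np.zeros((4, 3))])
        labels = [1] * 4 + [0] * 4
        assert triplet_batch_mean(reps, labels, margin=0.4).item() == 0.0

    def test_triplet_requires_both_classes(self):
        with pytest.raises(ValueError, match="both classes"):
            triplet_batch_mean(np.zeros((3, 2)), [1, 1, 1])

    def test_closeness_centers_require_both_classes(self):
        with pytest.raises(ValueError, match="both reference classes"):
            class_centers(np.zeros((3, 2)), [1, 1, 1])

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cross_entropy_clips([], [])


# -- differentiation ----------------------------------------------------------

def _fd_grad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        up, down = x.copy(), x.copy()
        up[i] += eps
        down[i] -= eps
        g[i] = (f(up) - f(down)) / (2 * eps)
    return g


def test_loss_gradients_match_finite_differences():
    """Each loss term back-propagates the analytic gradient (rel err < 1e-4)."""
    rng = np.random.default_rng(11)
    reps = rng.normal(size=(5, 4))
    labels = np.array([1, 1, 0, 0, 1])
    alphas = rng.uniform(0.1, 0.9, 5)
    p_c, n_c = rng.normal(size=4), rng.normal(size=4)

    cases = [
        (lambda r: oracle_triplet(r, labels), lambda t: triplet_batch_mean(t, labels)),
        (
            lambda r: oracle_closeness(r, alphas, p_c, n_c),
            lambda t: closeness(t, alphas, p_c, n_c),
        ),
    ]
    for oracle, impl in cases:
        t = Tensor(reps.copy(), requires_grad=True)
        impl(t).backward()
        fd = _fd_grad(lambda r: oracle(r), reps)
        np.testing.assert_allclose(t.grad, fd, atol=1e-4 * (np.abs(fd).max() + 1e-8))

    probs = rng.uniform(0.1, 0.9, 5)
    t = Tensor(probs.copy(), requires_grad=True)
    cross_entropy_clips(labels, t).backward()
    fd = _fd_grad(lambda p: oracle_cross_entropy(labels, p), probs)
    np.testing.assert_allclose(t.grad, fd, atol=1e-4 * np.abs(fd).max())


def test_total_loss_gradient_is_sum_of_gradients():
    rng = np.random.default_rng(12)
    reps = rng.normal(size=(5, 4))
    labels = np.array([1, 1, 0, 0, 1])
    alphas = rng.uniform(0.1, 0.9, 5)
    p_c, n_c = class_centers(reps, labels)

    t_sum = Tensor(reps.copy(), requires_grad=True)
    total_loss(
        triplet_batch_mean(t_sum, labels),
        closeness(t_sum, alphas, p_c, n_c),
        0.0,
        0.0,
    ).backward()

    g_parts = np.zeros_like(reps)
    for make in (
        lambda t: triplet_batch_mean(t, labels),
        lambda t: closeness(t, alphas, p_c, n_c),
    ):
        t = Tensor(reps.copy(), requires_grad=True)
        make(t).backward()
        g_parts += t.grad
    np.testing.assert_allclose(t_sum.grad, g_parts, atol=1e-10)
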