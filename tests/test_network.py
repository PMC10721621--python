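"""Network components: shapes, probability laws, equivariances."""

import numpy as np
import pytest

from mam import autodiff as ad
from mam.autodiff import Tensor
from mam.network import (
    AttentionFusion,
    Characteristics,
    MAMModel,
    ModelConfig,
    attention_fuse,
    contribution_curve,
    sinusoidal_position_encoding,
)


class TestModelConfig:
    def test_heads_must_divide_embed_dim(self):
        with pytest.raises(ValueError, match="divide"):
            ModelConfig(embed_dim=64, heads=5)

    def test_round_trip_dict(self):
        cfg = ModelConfig(T=48, step=30, seed=3)
        assert ModelConfig.from_dict(cfg.to_dict()) == cfg


class TestCharacteristics:
    def test_corrected_age_window_enforced(self):
        with pytest.raises(ValueError, match="9-20"):
            Characteristics("male", 35.0, 2500.0, 25.0)

    def test_sex_values_validated(self):
        with pytest.raises(ValueError, match="sex"):
            Characteristics("other", 35.0, 2500.0, 12.0)


class TestEncodeClip:
    def test_representation_is_64_dim_finite(self, tiny_model, tiny_instances):
        reps = tiny_model.encode_clip(tiny_instances)
        assert reps.shape == (3, 64)
        assert np.isfinite(reps.data).all()

    def test_deterministic_in_eval_mode(self, tiny_model, tiny_instances):
        with ad.no_grad():
            a = tiny_model.encode_clip(tiny_instances).data
            b = tiny_model.encode_clip(tiny_instances).data
        np.testing.assert_array_equal(a, b)

    def test_joint_permutation_equivariance(self, tiny_instances):
        """Permuting joints in the input AND in the conv kernel consistently
        leaves the clip representation unchanged (spatial attention has no
        positional order over joints)."""
        model = MAMModel(ModelConfig(T=12, step=8, seed=3))
        perm = np.random.default_rng(0).permutation(17)
        x = tiny_instances
        x_perm = x[:, :, :, perm][:, :, :, :, perm]
        with ad.no_grad():
            ref = model.encode_clip(x).data
        # conv weight rows are (c, i) pairs flattened; permute the joint axis
        w = model.encoder.conv_w.data.reshape(3, 17, 64)
        model.encoder.conv_w.data = w[:, perm].reshape(3 * 17, 64)
        with ad.no_grad():
            out = model.encode_clip(x_perm).data
        np.testing.assert_allclose(out, ref, atol=1e-4)

    def test_not_invariant_to_per_dimension_offset(self, tiny_model, tiny_instances):
        """Adding a constant to one dimension's distance entries must change
        the output: no hidden normalization erases scale information."""
        shifted = tiny_instances.copy()
        shifted[:, :, 0] += 1.0
        with ad.no_grad():
            a = tiny_model.encode_clip(tiny_instances).data
            b = tiny_model.encode_clip(shifted).data
        assert np.abs(a - b).max() > 1e-4

    def test_shape_mismatch_rejected(self, tiny_model):
        with pytest.raises(ValueError, match="instance tensor"):
            tiny_model.encode_clip(np.zeros((2, 12, 3, 16, 17), dtype=np.float32))

    def test_weight_count_below_one_million(self, tiny_model):
        assert tiny_model.n_parameters() < 1_000_000


class TestAttentionFusion:
    def test_single_vector_passes_through(self, rng):
        fusion = AttentionFusion(4, 8, rng)
        v = rng.normal(size=(1, 4))
        fused, w = attention_fuse(fusion, v)
        np.testing.assert_allclose(fused, v[0], rtol=1e-6)
        np.testing.assert_allclose(w, [1.0])

    def test_identical_vectors_fuse_to_themselves(self, rng):
        fusion = AttentionFusion(4, 8, rng)
        v = np.tile(rng.normal(size=(1, 4)), (5, 1))
        fused, w = attention_fuse(fusion, v)
        np.testing.assert_allclose(fused, v[0], rtol=1e-5)
        assert w.sum() == pytest.approx(1.0, abs=1e-9)

    def test_weights_sum_to_one_and_fused_in_hull(self, rng):
        fusion = AttentionFusion(6, 8, rng)
        v = rng.normal(size=(7, 6))
        fused, w = attention_fuse(fusion, v)
        assert w.sum() == pytest.approx(1.0, abs=1e-9)
        assert (fused <= v.max(axis=0) + 1e-9).all()
        assert (fused >= v.min(axis=0) - 1e-9).all()

    def test_empty_input_rejected(self, rng):
        fusion = AttentionFusion(4, 8, rng)
        with pytest.raises(ValueError, match="non-empty"):
            attention_fuse(fusion, [])


class TestClassifier:
    def test_zero_weights_give_half(self, tiny_model, tiny_instances):
        model = MAMModel(ModelConfig(T=12, step=8, seed=1))
        model.classifier.weight.data[:] = 0.0
        model.classifier.bias.data[:] = 0.0
        with ad.no_grad():
            reps = model.encode_clip(tiny_instances)
            alphas = model.classify_clip(reps).data
        np.testing.assert_allclose(alphas, 0.5, atol=1e-9)

    def test_logit_shift_invariance(self, tiny_model, tiny_instances):
        with ad.no_grad():
            reps = tiny_model.encode_clip(tiny_instances)
            before = tiny_model.classify_clip(reps).data
        tiny_model.classifier.bias.data += 3.21  # shift both logits equally
        with ad.no_grad():
            after = tiny_model.classify_clip(reps).data
        tiny_model.classifier.bias.data -= 3.21
        np.testing.assert_allclose(before, after, atol=1e-5)

    def test_probabilities_in_unit_interval(self, tiny_model, tiny_instances):
        with ad.no_grad():
            alphas = tiny_model.classify_clip(
                tiny_model.encode_clip(tiny_instances)
            ).data
        assert ((alphas > 0) & (alphas < 1)).all()


class TestBagFusion:
    def test_single_instance_returns_alpha(self, tiny_model):
        with ad.no_grad():
            s, w = tiny_model.fuse_bag(Tensor(np.array([0.37], dtype=np.float32)))
        assert s.data == pytest.approx(0.37, abs=1e-6)
        np.testing.assert_allclose(w.data, [1.0])

    def test_equal_alphas_fuse_to_that_alpha(self, tiny_model):
        with ad.no_grad():
            s, _ = tiny_model.fuse_bag(Tensor(np.full(6, 0.8, dtype=np.float32)))
        assert s.data == pytest.approx(0.8, abs=1e-6)

    def test_fused_value_within_alpha_range(self, tiny_model, rng):
        alphas = rng.uniform(0, 1, 9).astype(np.float32)
        with ad.no_grad():
            s, w = tiny_model.fuse_bag(Tensor(alphas))
        assert alphas.min() - 1e-6 <= s.data <= alphas.max() + 1e-6
        assert w.data.sum() == pytest.approx(1.0, abs=1e-6)

    def test_empty_bag_rejected(self, tiny_model):
        with pytest.raises(ValueError, match="empty bag"):
            tiny_model.fuse_bag(Tensor(np.empty(0)))


class TestInfoBranchAndBagHead:
    CH = Characteristics("female", 34.0, 2300.0, 13.0)

    def test_info_vector_is_16_dim_deterministic(self, tiny_model):
        with ad.no_grad():
            a = tiny_model.encode_info(self.CH).data
            b = tiny_model.encode_info(self.CH).data
        assert a.shape == (16,)
        np.testing.assert_array_equal(a, b)

    def test_standardization_uses_stored_stats(self, tiny_model):
        vec = tiny_model._info_vector(self.CH)
        mean, sd = tiny_model.info_mean, tiny_model.info_sd
        # round-trip: de-standardize recovers the raw characteristics
        raw = vec[2:] * sd + mean
        np.testing.assert_allclose(raw, [34.0, 2300.0, 13.0], rtol=1e-5)
        np.testing.assert_allclose(vec[:2], [0.0, 1.0])  # female one-hot

    def test_bag_probabilities_sum_to_one(self, tiny_model):
        with ad.no_grad():
            s, _ = tiny_model.fuse_bag(Tensor(np.array([0.3, 0.9], dtype=np.float32)))
            info = tiny_model.encode_info(self.CH)
            p_normal, p_risk = tiny_model.predict_bag(s, info)
        # float32 softmax: complementary probabilities at single precision
        assert p_normal.item() + p_risk.item() == pytest.approx(1.0, abs=1e-6)

    def test_zero_head_gives_even_odds(self):
        model = MAMModel(ModelConfig(T=12, step=8, seed=2))
        model.bag_head.weight.data[:] = 0.0
        model.bag_head.bias.data[:] = 0.0
        with ad.no_grad():
            s, _ = model.fuse_bag(Tensor(np.array([0.5], dtype=np.float32)))
            p_normal, p_risk = model.predict_bag(s, model.encode_info(self.CH))
        assert p_normal.item() == pytest.approx(0.5, abs=1e-9)

    def test_without_info_branch_characteristics_are_ignored(self):
        model = MAMModel(ModelConfig(T=12, step=8, seed=2, use_info=False))
        other = Characteristics("male", 30.0, 3100.0, 10.0)
        a = model.predict_bag_probability(np.array([0.2, 0.7]), self.CH)
        b = model.predict_bag_probability(np.array([0.2, 0.7]), other)
        assert a == b

    def test_missing_characteristics_rejected_when_info_enabled(self, tiny_model):
        with pytest.raises(ValueError, match="characteristics missing"):
            with ad.no_grad():
                s, _ = tiny_model.fuse_bag(Tensor(np.array([0.5], dtype=np.float32)))
                tiny_model.predict_bag(s, None)


class TestContributionCurve:
    def test_positive_and_matches_manual_evaluation(self, tiny_model):
        grid = np.linspace(0, 1, 11)
        curve = contribution_curve(tiny_model, grid)
        assert curve.shape == (11,)
        assert (curve > 0).all()
        # manual evaluation of the two fusion linear maps
        f = tiny_model.bag_fuse
        for a, c in zip(grid, curve):
            h = np.tanh(np.array([[a]], dtype=np.float32) @ f.l1.weight.data + f.l1.bias.data)
            score = float((h @ f.l2.weight.data + f.l2.bias.data).squeeze())
            assert c == pytest.approx(np.exp(score), rel=1e-5)


def test_position_encoding_rows_alternate_sin_cos():
    pe = sinusoidal_position_encoding(50, 8)
    assert pe.shape == (50, 8)
    np.testing.assert_allclose(pe[0, 0::2], 0.0)
    np.testing.assert_allclose(pe[0, 1::2], 1.0)
    assert np.abs(pe).max() <= 1.0 + 1e-6
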