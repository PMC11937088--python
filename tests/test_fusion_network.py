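"""Architecture contracts: shallow extraction, attention fusion, channel
split, the expert backbone layer shapes, gated heads, ablation switches
and modality isolation."""

import numpy as np
import pytest

from berryfuse import autodiff as ad
from berryfuse.autodiff import Tensor
from berryfuse.fusion_network import (ExpertEmbeddings, ExpertNetwork,
                                      FusionConfig, FusionExpertNet,
                                      ShallowExtractor, softplus_inverse,
                                      split_masked)

SMALL = FusionConfig(shallow_channels=4, width_multiplier=0.125)


def small_net(**overrides):
    cfg = FusionConfig(shallow_channels=4, width_multiplier=0.125, **overrides)
    return FusionExpertNet(cfg, seed=1)


def batch(rng, n=2, hw=32):
    return (Tensor(rng.normal(size=(n, 3, hw, hw)).astype(np.float32)),
            Tensor(rng.normal(size=(n, 1, hw, hw)).astype(np.float32)))


class TestShallowExtract:
    def test_spatial_resolution_preserved(self, rng):
        net = small_net()
        rgb, depth = batch(rng, hw=40)
        preds, _, bundle = net(rgb, depth)
        assert bundle.f_rgb.shape == (2, 4, 40, 40)
        assert bundle.f_d.shape == (2, 4, 40, 40)

    def test_parameter_disjointness(self, rng):
        """Perturbing the RGB extractor leaves the depth features untouched."""
        net = small_net()
        rgb, depth = batch(rng)
        _, _, before = net(rgb, depth)
        for _, p in net.shallow_rgb.named_parameters():
            p.data += 1.0
        _, _, after = net(rgb, depth)
        np.testing.assert_array_equal(before.f_d.data, after.f_d.data)
        assert not np.array_equal(before.f_rgb.data, after.f_rgb.data)

    def test_zero_inputs_zero_features(self):
        rng = np.random.default_rng(0)
        ext = ShallowExtractor(3, 4, rng)
        out = ext(Tensor(np.zeros((1, 3, 8, 8), np.float32)))
        np.testing.assert_array_equal(out.data, 0.0)  # zero-init biases

    def test_modality_spatial_mismatch_rejected(self, rng):
        net = small_net()
        rgb = Tensor(rng.normal(size=(1, 3, 32, 32)).astype(np.float32))
        depth = Tensor(rng.normal(size=(1, 1, 48, 48)).astype(np.float32))
        with pytest.raises(ValueError, match="spatial"):
            net(rgb, depth)


class TestAttentionFuse:
    def test_zero_conv_gives_half_mask(self, rng):
        net = small_net()
        net.attention.conv.weight.data[...] = 0.0
        net.attention.conv.bias.data[...] = 0.0
        rgb, depth = batch(rng)
        _, _, bundle = net(rgb, depth)
        np.testing.assert_allclose(bundle.w_s.data, 0.5, atol=1e-7)
        np.testing.assert_allclose(bundle.f_rgbd_masked.data,
                                   0.5 * bundle.f_rgbd.data, atol=1e-6)

    def test_toy_identity_kernel_hand_check(self):
        """Single-channel 2x2 input: avg-pool = max-pool = the input; an
        identity-center kernel on the avg map alone gives W_S = sigmoid(x)."""
        from berryfuse.fusion_network import SpatialAttention

        att = SpatialAttention(7, np.random.default_rng(0))
        att.conv.weight.data[...] = 0.0
        att.conv.bias.data[...] = 0.0
        att.conv.weight.data[0, 0, 3, 3] = 1.0  # center tap, avg channel
        x = np.array([[[[0.3, -1.2], [2.0, 0.0]]]], dtype=np.float32)
        w_s = att(Tensor(x))
        np.testing.assert_allclose(w_s.data, 1.0 / (1.0 + np.exp(-x)), atol=1e-6)

    def test_mask_strictly_inside_unit_interval(self, rng):
        net = small_net()
        for _ in range(5):
            rgb, depth = batch(rng)
            _, _, bundle = net(rgb, depth)
            assert np.all(bundle.w_s.data > 0.0)
            assert np.all(bundle.w_s.data < 1.0)
            assert bundle.w_s.shape[1] == 1

    def test_masked_is_elementwise_product(self, rng):
        net = small_net()
        rgb, depth = batch(rng)
        _, _, b = net(rgb, depth)
        np.testing.assert_allclose(b.f_rgbd_masked.data,
                                   b.w_s.data * b.f_rgbd.data, atol=1e-6)


class TestConcatAndSplit:
    def test_concatenation_recoverable_by_slicing(self, rng):
        net = small_net()
        rgb, depth = batch(rng)
        _, _, b = net(rgb, depth)
        c = b.f_rgb.shape[1]
        np.testing.assert_array_equal(b.f_rgbd.data[:, :c], b.f_rgb.data)
        np.testing.assert_array_equal(b.f_rgbd.data[:, c:], b.f_d.data)

    def test_split_shapes_and_identity(self, rng):
        x = Tensor(rng.normal(size=(2, 8, 5, 5)))
        m_rgb, m_rgbd, m_d = split_masked(x)
        assert m_rgb.shape == (2, 4, 5, 5)
        assert m_rgbd.shape == (2, 8, 5, 5)
        assert m_d.shape == (2, 4, 5, 5)
        np.testing.assert_array_equal(
            np.concatenate([m_rgb.data, m_d.data], axis=1), m_rgbd.data)

    def test_odd_channels_rejected(self, rng):
        with pytest.raises(ValueError, match="even"):
            split_masked(Tensor(rng.normal(size=(1, 5, 4, 4))))

    def test_ablated_attention_mask_is_identity(self, rng):
        net = small_net(ablate_attention=True)
        rgb, depth = batch(rng)
        _, _, b = net(rgb, depth)
        np.testing.assert_array_equal(b.w_s.data, 1.0)
        np.testing.assert_array_equal(b.f_rgbd_masked.data, b.f_rgbd.data)
        c = b.f_rgb.shape[1]
        np.testing.assert_array_equal(b.m_rgb.data, b.f_rgb.data)


class TestExpertBackbone:
    def test_full_width_layer_shapes_match_contract(self):
        """224x224 input: spatial 112/56/56/28/14/7, channels 64/64/64/128/256/512."""
        expert = ExpertNetwork(4, FusionConfig(shallow_channels=4), np.random.default_rng(0))
        trace = expert.shape_trace(224)
        assert trace == [("conv1", 112, 64), ("maxpool", 56, 64),
                         ("conv2", 56, 64), ("conv3", 28, 128),
                         ("conv4", 14, 256), ("conv5", 7, 512)]

    @pytest.mark.parametrize("width,expected", [(1.0, 512), (0.25, 128), (0.125, 64)])
    def test_embedding_length_scales_with_width(self, rng, width, expected):
        cfg = FusionConfig(shallow_channels=2, width_multiplier=width)
        expert = ExpertNetwork(2, cfg, np.random.default_rng(0))
        out = expert(Tensor(rng.normal(size=(1, 2, 32, 32)).astype(np.float32)))
        assert out.shape == (1, expected)

    def test_too_small_input_rejected(self, rng):
        expert = ExpertNetwork(2, SMALL, np.random.default_rng(0))
        with pytest.raises(ValueError, match="at least"):
            expert(Tensor(rng.normal(size=(1, 2, 16, 16)).astype(np.float32)))


class TestPredictTraits:
    def test_single_gate_isolates_expert(self, rng):
        net = small_net()
        emb_dim = net.config.embedding_dim
        father = Tensor(rng.normal(size=(2, emb_dim)).astype(np.float32))
        mother = Tensor(rng.normal(size=(2, emb_dim)).astype(np.float32))
        child = Tensor(rng.normal(size=(2, emb_dim)).astype(np.float32))
        net.gate_raw.data[...] = softplus_inverse(0.0)  # all gates ~ 0
        net.gate_raw.data[0, 0] = softplus_inverse(1.0)  # task 0 <- father only
        p1, _ = net.predict_traits(ExpertEmbeddings(father, mother, child))
        p2, _ = net.predict_traits(ExpertEmbeddings(
            father, mother * 3.0, child + 1.0))
        np.testing.assert_allclose(p1.data[:, 0], p2.data[:, 0], atol=1e-6)

    def test_contribution_matrix_nonnegative(self, rng):
        net = small_net()
        net.gate_raw.data[...] = rng.normal(size=(3, 3)) * 5
        _, gates = net.predict_traits(ExpertEmbeddings(
            *[Tensor(rng.normal(size=(1, net.config.embedding_dim)).astype(np.float32))
              for _ in range(3)]))
        assert gates.shape == (3, 3)
        assert np.all(gates >= 0.0)

    def test_identical_embeddings_and_heads_coincide(self, rng):
        net = small_net()
        v = Tensor(rng.normal(size=(2, net.config.embedding_dim)).astype(np.float32))
        for head in net.heads[1:]:  # copy head 0 into the others
            head.weight.data = net.heads[0].weight.data.copy()
            head.bias.data = net.heads[0].bias.data.copy()
        net.gate_raw.data[...] = 0.5
        preds, _ = net.predict_traits(ExpertEmbeddings(v, v, v))
        np.testing.assert_allclose(preds.data[:, 0], preds.data[:, 1], atol=1e-6)
        np.testing.assert_allclose(preds.data[:, 1], preds.data[:, 2], atol=1e-6)


class TestForward:
    def test_batch_shapes(self, rng):
        net = small_net()
        rgb, depth = batch(rng, n=3)
        preds, emb, _ = net(rgb, depth)
        assert preds.shape == (3, 3)
        assert emb.father.shape == emb.mother.shape == emb.child.shape

    def test_expert_ablation_shares_embedding(self, rng):
        net = small_net(ablate_experts=True)
        rgb, depth = batch(rng)
        _, emb, _ = net(rgb, depth)
        assert emb.experts_ablated
        assert emb.father is emb.mother is emb.child

    def test_empty_batch_rejected(self):
        net = small_net()
        with pytest.raises(ValueError, match="empty"):
            net(Tensor(np.zeros((0, 3, 32, 32), np.float32)),
                Tensor(np.zeros((0, 1, 32, 32), np.float32)))

    def test_modality_isolation_under_attention_ablation(self, rng):
        """With the mask ablated, the father embedding is invariant to the
        depth pixels (and the mother to the RGB pixels): the branches are
        information-isolated."""
        net = small_net(ablate_attention=True)
        rgb, depth = batch(rng)
        rgb.requires_grad = depth.requires_grad = True
        _, emb, _ = net(rgb, depth)
        emb.father.sum().backward()
        assert depth.grad is None or np.all(depth.grad == 0.0)
        assert np.any(rgb.grad != 0.0)

        rgb2, depth2 = batch(rng)
        rgb2.requires_grad = depth2.requires_grad = True
        _, emb2, _ = net(rgb2, depth2)
        emb2.mother.sum().backward()
        assert rgb2.grad is None or np.all(rgb2.grad == 0.0)
        assert np.any(depth2.grad != 0.0)

    def test_batch_permutation_equivariance(self, rng):
        net = small_net().eval()
        rgb, depth = batch(rng, n=4)
        with ad.no_grad():
            preds, _, _ = net(rgb, depth)
            perm = [2, 0, 3, 1]
            preds_p, _, _ = net(Tensor(rgb.data[perm]), Tensor(depth.data[perm]))
        np.testing.assert_allclose(preds_p.data, preds.data[perm], atol=1e-5)

    def test_config_validation(self):
        with pytest.raises(ValueError, match="odd"):
            FusionConfig(attention_kernel=4)
        with pytest.raises(ValueError, match="width_multiplier"):
            FusionConfig(width_multiplier=1.5)
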