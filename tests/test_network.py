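"""Architecture contracts: attention maps, heads, mixing, checkpoints."""

import numpy as np
import pytest

from somnoscore import autodiff as ad
from somnoscore.autodiff import Tensor
from somnoscore.network import (
    ModelConfig,
    TwoBranchNet,
    channel_attention,
    temporal_attention,
)
from somnoscore.psg_io import ContextWindow
from somnoscore.stages import SAMPLES_PER_EPOCH, STAGES


def _epochs(rng, n=1):
    return rng.standard_normal((n, 5, SAMPLES_PER_EPOCH)).astype(np.float32) * 30


class TestTemporalAttention:
    def test_single_timestep_gives_two(self):
        out = temporal_attention(Tensor(np.array([[[3.0], [1.0]]])))
        assert out.data[0, 0] == pytest.approx(2.0)

    def test_hand_evaluated_two_step_map(self):
        """channel-max [3,2] -> 1 + softmax = [1.7311, 1.2689]."""
        F = Tensor(np.array([[[1.0, 2.0], [3.0, 0.0]]]))
        out = temporal_attention(F).data[0]
        assert out == pytest.approx([1.7311, 1.2689], abs=1e-4)

    def test_invariants_on_random_maps(self, rng):
        for _ in range(50):
            F = Tensor(rng.standard_normal((2, 6, 9)))
            m = temporal_attention(F).data
            assert np.all(m > 1.0) and np.all(m < 2.0)
            assert np.allclose((m - 1.0).sum(axis=1), 1.0, atol=1e-9)


class TestChannelAttention:
    @staticmethod
    def _params(rng, c, h):
        return (
            Tensor(rng.standard_normal((c, h)), requires_grad=True),
            Tensor(rng.standard_normal(h), requires_grad=True),
            Tensor(rng.standard_normal((h, c)), requires_grad=True),
            Tensor(rng.standard_normal(c), requires_grad=True),
        )

    def test_single_channel_gives_one(self, rng):
        F = Tensor(rng.standard_normal((2, 1, 8)))
        out = channel_attention(F, *self._params(rng, 1, 1))
        assert out.data == pytest.approx(np.ones((2, 1)))

    def test_simplex_output(self, rng):
        F = Tensor(rng.standard_normal((3, 7, 11)))
        m = channel_attention(F, *self._params(rng, 7, 2)).data
        assert np.all(m > 0)
        assert np.allclose(m.sum(axis=1), 1.0, atol=1e-9)

    def test_against_scalar_recomputation(self, rng):
        """Brute-force pool -> shared MLP -> sum -> softmax with loops."""
        c, h, t = 3, 2, 4
        F = rng.standard_normal((1, c, t))
        w1, b1, w2, b2 = self._params(rng, c, h)
        out = channel_attention(Tensor(F), w1, b1, w2, b2).data[0]

        def mlp(d):
            hid = np.maximum(d @ w1.data + b1.data, 0.0)
            return hid @ w2.data + b2.data

        logits = mlp(F[0].mean(axis=1)) + mlp(F[0].max(axis=1))
        ref = np.exp(logits - logits.max())
        ref /= ref.sum()
        assert out == pytest.approx(ref, abs=1e-12)


class TestBlocksAndFeatures:
    def test_output_length_follows_stride_arithmetic(self, tiny_net, rng):
        x = Tensor(_epochs(rng, 2))
        y = tiny_net.attention_block(x, 0)
        expected = -(-SAMPLES_PER_EPOCH // tiny_net.cfg.block_strides[0])
        assert y.shape == (2, tiny_net.cfg.block_channels[0], expected)

    def test_feature_dim_default_config(self, rng):
        net = TwoBranchNet(ModelConfig(), seed=0).eval_mode()
        f = net.extract_features(_epochs(rng, 1))
        assert f.shape == (1, 256)

    def test_feature_dim_scaled_config(self, tiny_net, rng):
        f = tiny_net.extract_features(_epochs(rng, 2))
        assert f.shape == (2, tiny_net.cfg.feature_dim)

    def test_forward_deterministic_in_eval_mode(self, tiny_net, rng):
        x = _epochs(rng, 1)
        f1 = tiny_net.extract_features(x).data
        f2 = tiny_net.extract_features(x.copy()).data
        assert np.array_equal(f1, f2)

    def test_attention_invariants_hold_in_all_blocks(self, tiny_net, rng):
        tiny_net.capture_attention = True
        tiny_net.extract_features(_epochs(rng, 2))
        assert len(tiny_net.last_attention) == 3
        for maps in tiny_net.last_attention:
            assert np.allclose(maps["channel"].sum(axis=1), 1.0, atol=1e-5)
            # strict (1,2) interior up to float32 resolution: tiny softmax
            # entries underflow to 0 at long temporal lengths
            assert np.all(maps["temporal"] >= 1.0) and np.all(maps["temporal"] <= 2.0)
            assert np.allclose((maps["temporal"] - 1.0).sum(axis=1), 1.0, atol=1e-3)

    def test_gradient_reaches_conv_and_mlp_parameters(self, rng):
        net = TwoBranchNet(ModelConfig.tiny(), seed=1).train_mode()
        f = net.extract_features(_epochs(rng, 2).astype(np.float64))
        ad.sum_(ad.mul(f, f)).backward()
        for name in ("block0.conv1_w", "block0.mlp_w1", "block2.conv2_w", "block2.mlp_w2"):
            g = net.params[name].grad
            assert g is not None and np.any(g != 0), f"dead parameter {name}"

    def test_wrong_input_shape_rejected(self, tiny_net):
        with pytest.raises(ValueError, match="expected"):
            tiny_net.extract_features(np.zeros((1, 5, 100), np.float32))


class TestHeads:
    def test_elb_probabilities_on_simplex(self, tiny_net, rng):
        p = tiny_net.elb_forward(rng.standard_normal((4, tiny_net.cfg.feature_dim))).data
        assert np.all(p >= 0) and np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_zero_weights_give_uniform(self, tiny_cfg):
        net = TwoBranchNet(tiny_cfg, seed=0)
        for name, p in net.params.items():
            if name.startswith(("elb.", "slb.")):
                p.data = np.zeros_like(p.data)
        f = np.ones((2, tiny_cfg.feature_dim), np.float32)
        assert net.elb_forward(f).data == pytest.approx(np.full((2, 5), 0.2))
        w = np.ones((2, tiny_cfg.slb_input_dim), np.float32)
        assert net.slb_forward(w).data == pytest.approx(np.full((2, 5), 0.2))

    def test_single_layer_elb_matches_affine_softmax(self, rng):
        cfg = ModelConfig.tiny(elb_hidden=())
        net = TwoBranchNet(cfg, seed=0)
        f = rng.standard_normal((1, cfg.feature_dim)).astype(np.float32)
        z = f @ net.params["elb.w0"].data + net.params["elb.b0"].data
        ref = np.exp(z - z.max())
        ref /= ref.sum()
        assert net.elb_forward(f).data[0] == pytest.approx(ref[0], abs=1e-6)

    def test_slb_input_dim_default_is_1280(self):
        assert ModelConfig().slb_input_dim == 1280

    def test_slb_rejects_wrong_window_length(self, tiny_net):
        with pytest.raises(ValueError, match="SLB expects"):
            tiny_net.slb_forward(np.zeros((1, tiny_net.cfg.feature_dim * 3), np.float32))

    def test_slb_sensitive_to_window_order(self, tiny_net, rng):
        n = 2 * tiny_net.cfg.n_context + 1
        feats = rng.standard_normal((n, tiny_net.cfg.feature_dim)).astype(np.float32)
        a = tiny_net.slb_forward(feats.reshape(1, -1)).data
        b = tiny_net.slb_forward(feats[::-1].reshape(1, -1)).data
        assert not np.allclose(a, b)


class TestPredict:
    @staticmethod
    def _window(rng, n_context=2):
        t = rng.standard_normal((2 * n_context + 1, 5, SAMPLES_PER_EPOCH)).astype(np.float32) * 30
        return ContextWindow(center_index=10, tensors=t, n_context=n_context)

    def test_alpha_one_is_elb_decision(self, tiny_net, rng):
        w = self._window(rng)
        feats = tiny_net.features_no_grad(w.tensors)
        with ad.no_grad():
            p_ep = tiny_net.elb_forward(feats[2:3]).data[0]
        p, label = tiny_net.predict(w, alpha_test=1.0)
        assert p == pytest.approx(p_ep, abs=1e-7)
        assert label == STAGES[int(np.argmax(p_ep))]

    def test_alpha_zero_is_slb_decision(self, tiny_net, rng):
        w = self._window(rng)
        feats = tiny_net.features_no_grad(w.tensors)
        with ad.no_grad():
            p_seq = tiny_net.slb_forward(feats.reshape(1, -1)).data[0]
        p, label = tiny_net.predict(w, alpha_test=0.0)
        assert p == pytest.approx(p_seq, abs=1e-7)
        assert label == STAGES[int(np.argmax(p_seq))]

    def test_mixture_sums_to_one_and_is_deterministic(self, tiny_net, rng):
        w = self._window(rng)
        p1, l1 = tiny_net.predict(w, alpha_test=0.3)
        p2, l2 = tiny_net.predict(w, alpha_test=0.3)
        assert p1.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.array_equal(p1, p2) and l1 == l2

    def test_agreeing_branches_win_for_every_alpha(self, tiny_net, rng):
        for _ in range(10):
            w = self._window(rng)
            p1, _ = tiny_net.predict(w, alpha_test=1.0)
            p0, _ = tiny_net.predict(w, alpha_test=0.0)
            if np.argmax(p1) != np.argmax(p0):
                continue
            expected = STAGES[int(np.argmax(p1))]
            for a in (0.0, 0.25, 0.5, 0.75, 1.0):
                _, label = tiny_net.predict(w, alpha_test=a)
                assert label == expected

    def test_alpha_out_of_range_rejected(self, tiny_net, rng):
        with pytest.raises(ValueError, match="alpha"):
            tiny_net.predict(self._window(rng), alpha_test=1.5)


class TestConfigAndCheckpoint:
    def test_feature_dim_must_match_last_block(self):
        with pytest.raises(ValueError, match="feature_dim"):
            ModelConfig(feature_dim=128, block_channels=(64, 128, 256))

    def test_kernel_must_be_odd(self):
        with pytest.raises(ValueError, match="odd"):
            ModelConfig(kernel_width=6)

    def test_shapes_are_pure_function_of_config(self):
        a = TwoBranchNet(ModelConfig.tiny(), seed=0)
        b = TwoBranchNet(ModelConfig.tiny(), seed=99)
        assert {k: v.data.shape for k, v in a.params.items()} == \
               {k: v.data.shape for k, v in b.params.items()}

    def test_checkpoint_round_trip(self, tiny_net, rng, tmp_path):
        path = tmp_path / "ckpt.zip"
        tiny_net.save(path)
        restored = TwoBranchNet.load(path)
        x = _epochs(rng, 3)
        assert np.array_equal(
            tiny_net.features_no_grad(x), restored.features_no_grad(x)
        )
        assert restored.cfg == tiny_net.cfg
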