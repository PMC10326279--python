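"""Alpha schedule, class weights, loss mixing, gating and the train loop."""

import numpy as np
import pytest

from somnoscore import autodiff as ad
from somnoscore.autodiff import Tensor
from somnoscore.network import ModelConfig, TwoBranchNet
from somnoscore.simulator import SimConfig, simulate_split
from somnoscore.trainer import (
    TrainConfig,
    _DataView,
    alpha_at,
    class_weights,
    combined_loss,
    gated_backward,
    predict_dataset,
    sequence_only_loss,
    train,
)
from somnoscore.stages import SAMPLES_PER_EPOCH, STAGES


class TestAlphaSchedule:
    def test_closed_form_values(self):
        assert alpha_at(0, 10) == 1.0
        assert alpha_at(10, 10) == 0.0
        assert alpha_at(5, 10) == 0.75

    def test_trace_non_increasing_from_one_to_zero(self):
        trace = [alpha_at(t, 37) for t in range(38)]
        assert trace[0] == 1.0 and trace[-1] == 0.0
        assert all(a >= b for a, b in zip(trace, trace[1:]))

    @pytest.mark.parametrize("T,T_max", [(-1, 10), (11, 10), (0, 0)])
    def test_domain_errors(self, T, T_max):
        with pytest.raises(ValueError):
            alpha_at(T, T_max)


class TestClassWeights:
    def test_equal_counts_give_unit_weights(self):
        w = class_weights({s: 500 for s in STAGES})
        assert w == pytest.approx(np.ones(5))

    def test_inverse_proportionality(self):
        w = class_weights({"W": 1000, "N1": 100, "N2": 1000, "N3": 1000, "REM": 1000})
        assert np.argmax(w) == 1
        for i in (0, 2, 3, 4):
            assert w[1] / w[i] == pytest.approx(10.0)
        assert w.mean() == pytest.approx(1.0)

    def test_cohort_scale_counts_put_largest_weight_on_n1(self):
        counts = {"W": 1_335_339, "N1": 174_749, "N2": 1_915_026,
                  "N3": 589_641, "REM": 652_788}
        w = class_weights(counts)
        assert STAGES[int(np.argmax(w))] == "N1"

    def test_zero_count_rejected_with_advice(self):
        with pytest.raises(ValueError, match="absent"):
            class_weights({"W": 10, "N1": 0, "N2": 10, "N3": 10, "REM": 10})


def _prob_batch(rng, n=6):
    z = rng.standard_normal((n, 5))
    p = np.exp(z)
    p /= p.sum(axis=1, keepdims=True)
    return Tensor(p)


class TestCombinedLoss:
    def test_degenerate_alphas(self, rng):
        y = rng.integers(0, 5, 6)
        w = np.ones(5)
        p_ep, p_seq = _prob_batch(rng), _prob_batch(rng)
        assert combined_loss(p_ep, p_seq, y, 1.0, w).L.item() == pytest.approx(
            combined_loss(p_ep, p_seq, y, 1.0, w).L_ep.item())
        assert combined_loss(p_ep, p_seq, y, 0.0, w).L.item() == pytest.approx(
            combined_loss(p_ep, p_seq, y, 0.0, w).L_seq.item())

    def test_single_sample_hand_oracle(self):
        """p_ep[y]=0.5, p_seq[y]=0.25, alpha=0.5 -> 0.5 ln2 + 0.5 ln4."""
        p_ep = Tensor(np.array([[0.5, 0.5, 0.0, 0.0, 0.0]]))
        p_seq = Tensor(np.array([[0.25, 0.75, 0.0, 0.0, 0.0]]))
        lc = combined_loss(p_ep, p_seq, np.array([0]), 0.5, np.ones(5))
        expected = 0.5 * np.log(2.0) + 0.5 * np.log(4.0)
        assert lc.L.item() == pytest.approx(expected, abs=1e-9)
        assert lc.L.item() == pytest.approx(1.0397, abs=1e-4)

    def test_conservation_identity(self, rng):
        w = class_weights({s: int(c) for s, c in zip(STAGES, rng.integers(50, 500, 5))})
        for alpha in (0.0, 0.2, 0.5, 0.9, 1.0):
            y = rng.integers(0, 5, 8)
            lc = combined_loss(_prob_batch(rng, 8), _prob_batch(rng, 8), y, alpha, w)
            assert lc.L.item() == alpha * lc.L_ep.item() + (1 - alpha) * lc.L_seq.item()

    def test_weighted_normalisation_by_weight_sum(self, rng):
        y = np.array([1, 1, 0])  # two N1, one W
        w = np.array([1.0, 3.0, 1.0, 1.0, 1.0])
        p = _prob_batch(rng, 3)
        nll = -np.log(p.data[np.arange(3), y])
        expected = (w[y] * nll).sum() / w[y].sum()
        assert sequence_only_loss(p, y, w).item() == pytest.approx(expected, abs=1e-7)

    def test_alpha_domain_checked(self, rng):
        with pytest.raises(ValueError):
            combined_loss(_prob_batch(rng), _prob_batch(rng),
                          np.zeros(6, int), 1.5, np.ones(5))


class TestGradientGating:
    @staticmethod
    def _batch(net, rng, B=3):
        n = 2 * net.cfg.n_context + 1
        Xw = (rng.standard_normal((B, n, 5, SAMPLES_PER_EPOCH)) * 20).astype(np.float32)
        y = rng.integers(0, 5, B)
        return Xw, y

    @staticmethod
    def _forward(net, Xw, y, alpha, weights):
        B, n = Xw.shape[:2]
        ctx = net.features_no_grad(Xw.reshape(B * n, 5, -1))
        feats_c = net.extract_features(Xw[:, n // 2])
        p_ep = net.elb_forward(feats_c)
        p_seq = net.slb_forward(Tensor(ctx.reshape(B, -1)))
        return combined_loss(p_ep, p_seq, y, alpha, weights)

    def test_alpha_zero_leaves_cnn_and_elb_untouched(self, rng):
        net = TwoBranchNet(ModelConfig.tiny(), seed=3).train_mode()
        Xw, y = self._batch(net, rng)
        grads = gated_backward(net, self._forward(net, Xw, y, 0.0, np.ones(5)))
        groups = net.param_groups()
        for name in groups["cnn"] + groups["elb"]:
            assert np.all(grads[name] == 0.0), name
        assert any(np.any(grads[n] != 0) for n in groups["slb"])

    def test_alpha_one_leaves_slb_untouched(self, rng):
        net = TwoBranchNet(ModelConfig.tiny(), seed=3).train_mode()
        Xw, y = self._batch(net, rng)
        grads = gated_backward(net, self._forward(net, Xw, y, 1.0, np.ones(5)))
        groups = net.param_groups()
        for name in groups["slb"]:
            assert np.all(grads[name] == 0.0), name
        assert any(np.any(grads[n] != 0) for n in groups["cnn"])

    def test_cnn_gradients_bitwise_equal_scaled_elb_backward(self, rng):
        """Combined backward vs. a backward of alpha * L_ep alone."""
        net = TwoBranchNet(ModelConfig.tiny(), seed=3).train_mode()
        Xw, y = self._batch(net, rng)
        alpha = 0.5
        grads = gated_backward(net, self._forward(net, Xw, y, alpha, np.ones(5)))

        net.zero_grad()
        B, n = Xw.shape[:2]
        # replay the exact same forward state: BN running stats advanced
        # during the first pass, so rebuild them identically
        net2 = TwoBranchNet(ModelConfig.tiny(), seed=3).train_mode()
        net2.features_no_grad(Xw.reshape(B * n, 5, -1))
        feats_c = net2.extract_features(Xw[:, n // 2])
        p_ep = net2.elb_forward(feats_c)
        nll = ad.mul(ad.log(ad.clip_min(ad.gather_labels(p_ep, y), 1e-12)), -1.0)
        ad.mul(ad.mean(nll), alpha).backward()
        for name in net2.param_groups()["cnn"]:
            g2 = net2.params[name].grad
            g2 = np.zeros_like(net2.params[name].data) if g2 is None else g2
            assert np.array_equal(grads[name], g2), name


@pytest.fixture(scope="module")
def toy_split():
    """Strongly separable conditions (no N1 ambiguity), small records."""
    cfg = SimConfig(n_records=4, epochs_per_record=120, seed=41, ambiguity=0.0)
    return simulate_split(cfg, fractions=(0.5, 0.25, 0.25))


class TestTrainLoop:
    def test_history_contract_and_schedules(self, toy_split):
        tr, va, _ = toy_split
        mcfg = ModelConfig.tiny()
        tcfg = TrainConfig(total_iterations=20, batch_size=8,
                           epochs_per_train_epoch=2, seed=1)
        res = train(tr, va, mcfg, tcfg)
        h = res.history
        # Eq-style quadratic schedule over T_max = 10 training epochs
        expected = [1 - (t / 10) ** 2 for t in range(10) for _ in range(2)]
        assert h["alpha"].tolist() == pytest.approx(expected)
        assert h["lr"].iloc[0] == pytest.approx(tcfg.lr)
        assert h["lr"].iloc[-1] == pytest.approx(0.1 * tcfg.lr)
        np.testing.assert_allclose(
            h["L"], h["alpha"] * h["L_ep"] + (1 - h["alpha"]) * h["L_seq"], rtol=1e-6)
        assert h["val_mf1"].notna().sum() == 10

    def test_same_seed_reproduces_history(self, toy_split):
        tr, va, _ = toy_split
        mcfg = ModelConfig.tiny()
        tcfg = TrainConfig(total_iterations=6, batch_size=8,
                           epochs_per_train_epoch=3, seed=5)
        h1 = train(tr, va, mcfg, tcfg).history
        h2 = train(tr, va, mcfg, tcfg).history
        assert h1.equals(h2)

    def test_regimes_consume_identical_batches(self, toy_split, monkeypatch):
        tr, va, _ = toy_split
        mcfg = ModelConfig.tiny()
        tcfg = TrainConfig(total_iterations=4, batch_size=8,
                           epochs_per_train_epoch=2, seed=9)
        seen: dict[str, list] = {}
        orig = _DataView.batch

        def spy(self, rng, size):
            out = orig(self, rng, size)
            seen.setdefault(current, []).append(out[1].copy())
            return out

        monkeypatch.setattr(_DataView, "batch", spy)
        for current in ("transitive", "none", "weighted"):
            train(tr, va, mcfg, tcfg, regime=current)
        for a, b in zip(seen["transitive"], seen["none"]):
            assert np.array_equal(a, b)
        for a, b in zip(seen["transitive"], seen["weighted"]):
            assert np.array_equal(a, b)

    def test_missing_class_rejected(self, toy_split):
        tr, va, _ = toy_split
        rid = next(iter(tr.records))
        rec = tr.records[rid]
        only_w = type(tr)({rid: type(rec)(X=rec.X[:4],
                                          labels=np.zeros(4, dtype=np.int64))})
        with pytest.raises(ValueError, match="absent"):
            train(only_w, va, ModelConfig.tiny(),
                  TrainConfig(total_iterations=2, batch_size=4,
                              epochs_per_train_epoch=1))


class TestSanityFit:
    def test_learns_separable_stages(self, toy_split):
        """With distinct spectral signatures the net fits its training
        set well above chance within a short optimisation budget."""
        tr, va, _ = toy_split
        mcfg = ModelConfig.tiny()
        tcfg = TrainConfig(total_iterations=120, batch_size=24,
                           epochs_per_train_epoch=12, seed=2)
        res = train(tr, va, mcfg, tcfg, regime="transitive")
        per = predict_dataset(res.net, tr, alpha_test=0.5)
        yt = np.concatenate([t for t, _ in per.values()])
        yp = np.concatenate([p for _, p in per.values()])
        assert np.mean(yt == yp) > 0.9
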