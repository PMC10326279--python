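"""Two-branch sleep-staging network with 1-d channel/temporal attention.

The feature extractor is three cascaded residual blocks.  Each block is
Conv(k=7) -> BN -> ReLU -> Conv(k=7) -> BN producing an intermediate
feature map F of shape (channels C, time T); F is then reweighted by

* a channel attention map  M_C = softmax(MLP(avgpool_t(F)) + MLP(maxpool_t(F)))
  over the channel axis (shared squeeze-and-excitation MLP, bottleneck
  C -> C/r -> C), and
* a temporal attention map  M_T = 1 + softmax_t(maxpool_c(F)),
  whose cascaded softmax bounds the per-step gain strictly inside (1, 2),

followed by a residual addition (1x1 projection where shapes differ)
and ReLU.  A global average pool yields the per-epoch feature vector
(default dimension 256).

Two fully connected heads classify the five AASM stages: the epoch
learning branch (ELB) sees the center epoch's features; the sequential
learning branch (SLB) sees the concatenated features of the 2N+1-epoch
context window (N=2 -> 256x5 = 1280 inputs).  At test time the stage is
the argmax of  p = alpha * p_ep + (1 - alpha) * p_seq  with alpha = 0.5
by default.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import asdict, dataclass
from pathlib import Path
import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .psg_io import ContextWindow
from .stages import CHANNELS, SAMPLES_PER_EPOCH, STAGES

CHECKPOINT_SCHEMA = 1


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    The last residual-block width equals ``feature_dim``; the SLB input
    size is ``feature_dim * (2 * n_context + 1)``.
    """

    feature_dim: int = 256
    block_channels: tuple[int, ...] = (64, 128, 256)
    kernel_width: int = 7
    mlp_reduction_ratio: int = 16
    n_context: int = 2
    n_classes: int = 5
    elb_hidden: tuple[int, ...] = (128,)
    slb_hidden: tuple[int, ...] = (512, 128)
    alpha_test: float = 0.5
    block_strides: tuple[int, ...] = (4, 4, 4)
    bn_eps: float = 1e-5
    bn_momentum: float = 0.1

    def __post_init__(self) -> None:
        if self.block_channels[-1] != self.feature_dim:
            raise ValueError("last block width must equal feature_dim")
        if self.kernel_width % 2 != 1:
            raise ValueError("kernel width must be odd")
        if len(self.block_strides) != len(self.block_channels):
            raise ValueError("one stride per block required")
        if not 0.0 <= self.alpha_test <= 1.0:
            raise ValueError("alpha_test must lie in [0, 1]")

    @property
    def slb_input_dim(self) -> int:
        return self.feature_dim * (2 * self.n_context + 1)

    @classmethod
    def tiny(cls, block_channels=(8, 16, 32), elb_hidden=(16,), slb_hidden=(32, 16), **kw):
        """A desk-scale configuration with the same structure."""
        return cls(
            feature_dim=block_channels[-1],
            block_channels=tuple(block_channels),
            elb_hidden=tuple(elb_hidden),
            slb_hidden=tuple(slb_hidden),
            **kw,
        )


# ---------------------------------------------------------------------
# attention primitives (exposed for direct testing)
# ---------------------------------------------------------------------

def channel_attention(F: Tensor, w1: Tensor, b1: Tensor, w2: Tensor, b2: Tensor) -> Tensor:
    """softmax over channels of MLP(avgpool_t F) + MLP(maxpool_t F).

    One shared bottleneck MLP (C -> C/r -> C, ReLU inside) serves both
    pooling paths.  Output shape (B, C); rows sum to 1 with all entries
    strictly positive.
    """
    avg_d = ad.mean(F, axis=2)
    max_d = ad.amax(F, axis=2)

    def mlp(d):
        return ad.linear(ad.relu(ad.linear(d, w1, b1)), w2, b2)

    return ad.softmax(ad.add(mlp(avg_d), mlp(max_d)), axis=1)


def temporal_attention(F: Tensor) -> Tensor:
    """1 + softmax over time of the channel-wise max; parameter-free.

    Output shape (B, T); every entry lies strictly in (1, 2) and the
    entries minus one sum to 1 per sample.
    """
    m = ad.amax(F, axis=1)  # (B, T)
    return ad.add(ad.softmax(m, axis=1), 1.0)


def _he(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class TwoBranchNet:
    """Feature extractor + ELB/SLB heads with explicit parameter store."""

    def __init__(self, cfg: ModelConfig, seed: int = 0, dtype=np.float32):
        self.cfg = cfg
        self.dtype = np.dtype(dtype)
        self.training = False
        self.capture_attention = False
        self.last_attention: list[dict[str, np.ndarray]] = []
        self.params: dict[str, Tensor] = {}
        self.running: dict[str, np.ndarray] = {}
        self._build(np.random.default_rng(seed))

    # -- construction --------------------------------------------------
    def _add(self, name: str, arr: np.ndarray) -> None:
        self.params[name] = Tensor(arr, requires_grad=True)

    def _build(self, rng: np.random.Generator) -> None:
        cfg, dt = self.cfg, self.dtype
        k = cfg.kernel_width
        c_in = len(CHANNELS)
        # stem normalisation: raw epochs arrive in uV (RMS tens of uV,
        # stage-dependent); without it the residual skip path carries
        # the raw scale past every block and saturates the softmax heads
        self._add("stem_gamma", np.ones(c_in, dt))
        self._add("stem_beta", np.zeros(c_in, dt))
        self.running["stem_mean"] = np.zeros(c_in, dt)
        self.running["stem_var"] = np.ones(c_in, dt)
        for i, c_out in enumerate(cfg.block_channels):
            p = f"block{i}."
            self._add(p + "conv1_w", _he(rng, (c_out, c_in, k), c_in * k, dt))
            self._add(p + "conv1_b", np.zeros(c_out, dt))
            self._add(p + "conv2_w", _he(rng, (c_out, c_out, k), c_out * k, dt))
            self._add(p + "conv2_b", np.zeros(c_out, dt))
            for bn in ("bn1", "bn2"):
                self._add(p + bn + "_gamma", np.ones(c_out, dt))
                self._add(p + bn + "_beta", np.zeros(c_out, dt))
                self.running[p + bn + "_mean"] = np.zeros(c_out, dt)
                self.running[p + bn + "_var"] = np.ones(c_out, dt)
            hidden = max(c_out // cfg.mlp_reduction_ratio, 1)
            self._add(p + "mlp_w1", _he(rng, (c_out, hidden), c_out, dt))
            self._add(p + "mlp_b1", np.zeros(hidden, dt))
            self._add(p + "mlp_w2", _he(rng, (hidden, c_out), hidden, dt))
            self._add(p + "mlp_b2", np.zeros(c_out, dt))
            self._add(p + "proj_w", _he(rng, (c_out, c_in, 1), c_in, dt))
            self._add(p + "proj_b", np.zeros(c_out, dt))
            c_in = c_out
        dims = [cfg.feature_dim, *cfg.elb_hidden, cfg.n_classes]
        for j, (a, b) in enumerate(zip(dims[:-1], dims[1:])):
            self._add(f"elb.w{j}", _he(rng, (a, b), a, dt))
            self._add(f"elb.b{j}", np.zeros(b, dt))
        dims = [cfg.slb_input_dim, *cfg.slb_hidden, cfg.n_classes]
        for j, (a, b) in enumerate(zip(dims[:-1], dims[1:])):
            self._add(f"slb.w{j}", _he(rng, (a, b), a, dt))
            self._add(f"slb.b{j}", np.zeros(b, dt))

    # -- parameter access ----------------------------------------------
    def param_groups(self) -> dict[str, list[str]]:
        """Parameter names grouped into cnn / elb / slb."""
        groups = {"cnn": [], "elb": [], "slb": []}
        for name in self.params:
            if name.startswith("elb."):
                groups["elb"].append(name)
            elif name.startswith("slb."):
                groups["slb"].append(name)
            else:
                groups["cnn"].append(name)
        return groups

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def train_mode(self, flag: bool = True) -> "TwoBranchNet":
        self.training = flag
        return self

    def eval_mode(self) -> "TwoBranchNet":
        return self.train_mode(False)

    # -- layers ---------------------------------------------------------
    def _bn(self, x: Tensor, name: str) -> Tensor:
        """BatchNorm over (batch, time) per feature channel."""
        cfg = self.cfg
        gamma = self.params[name + "_gamma"]
        beta = self.params[name + "_beta"]
        if self.training:
            y, m, v = ad.batchnorm(x, gamma, beta, eps=cfg.bn_eps)
            mom = cfg.bn_momentum
            self.running[name + "_mean"] = (
                (1 - mom) * self.running[name + "_mean"] + mom * m
            ).astype(self.dtype)
            self.running[name + "_var"] = (
                (1 - mom) * self.running[name + "_var"] + mom * v
            ).astype(self.dtype)
            return y
        rm = self.running[name + "_mean"].reshape(1, -1, 1)
        rv = self.running[name + "_var"].reshape(1, -1, 1)
        xhat = ad.div(ad.sub(x, rm), np.sqrt(rv + cfg.bn_eps))
        return ad.add(ad.mul(xhat, ad.reshape(gamma, (1, -1, 1))), ad.reshape(beta, (1, -1, 1)))

    def attention_block(self, x: Tensor, i: int) -> Tensor:
        """One residual 1-d attention block (stride on the first conv)."""
        cfg = self.cfg
        p = f"block{i}."
        pad = cfg.kernel_width // 2
        stride = cfg.block_strides[i]
        h = ad.conv1d(x, self.params[p + "conv1_w"], self.params[p + "conv1_b"], stride=stride, pad=pad)
        h = ad.relu(self._bn(h, p + "bn1"))
        F = self._bn(
            ad.conv1d(h, self.params[p + "conv2_w"], self.params[p + "conv2_b"], stride=1, pad=pad),
            p + "bn2",
        )
        mc = channel_attention(
            F,
            self.params[p + "mlp_w1"], self.params[p + "mlp_b1"],
            self.params[p + "mlp_w2"], self.params[p + "mlp_b2"],
        )
        mt = temporal_attention(F)
        if self.capture_attention:
            self.last_attention.append({"channel": mc.data.copy(), "temporal": mt.data.copy()})
        B, C, T = F.shape
        Fw = ad.mul(ad.mul(F, ad.reshape(mc, (B, C, 1))), ad.reshape(mt, (B, 1, T)))
        if x.shape[1] != C or stride != 1:
            skip = ad.conv1d(x, self.params[p + "proj_w"], self.params[p + "proj_b"], stride=stride, pad=0)
        else:
            skip = x
        return ad.relu(ad.add(Fw, skip))

    def extract_features(self, epochs: np.ndarray | Tensor) -> Tensor:
        """(B, 5, 3750) epoch tensors -> (B, feature_dim) via GAP."""
        x = epochs if isinstance(epochs, Tensor) else Tensor(np.asarray(epochs, dtype=self.dtype))
        if x.shape[1:] != (len(CHANNELS), SAMPLES_PER_EPOCH):
            raise ValueError(
                f"expected (B, {len(CHANNELS)}, {SAMPLES_PER_EPOCH}) input, got {x.shape}"
            )
        if self.capture_attention:
            self.last_attention = []
        x = self._bn(x, "stem")
        for i in range(len(self.cfg.block_channels)):
            x = self.attention_block(x, i)
        return ad.mean(x, axis=2)

    def _head(self, x: Tensor, prefix: str, n_hidden: int) -> Tensor:
        for j in range(n_hidden + 1):
            x = ad.linear(x, self.params[f"{prefix}.w{j}"], self.params[f"{prefix}.b{j}"])
            if j < n_hidden:
                x = ad.relu(x)
        return ad.softmax(x, axis=1)

    def elb_forward(self, feats: Tensor | np.ndarray) -> Tensor:
        """Per-epoch stage probabilities from single-epoch features."""
        f = feats if isinstance(feats, Tensor) else Tensor(np.asarray(feats, dtype=self.dtype))
        if f.shape[-1] != self.cfg.feature_dim:
            raise ValueError(f"ELB expects {self.cfg.feature_dim} features, got {f.shape[-1]}")
        return self._head(f, "elb", len(self.cfg.elb_hidden))

    def slb_forward(self, window_feats: Tensor | np.ndarray) -> Tensor:
        """Stage probabilities from 2N+1 concatenated epoch features."""
        f = (
            window_feats
            if isinstance(window_feats, Tensor)
            else Tensor(np.asarray(window_feats, dtype=self.dtype))
        )
        if f.shape[-1] != self.cfg.slb_input_dim:
            raise ValueError(f"SLB expects {self.cfg.slb_input_dim} inputs, got {f.shape[-1]}")
        return self._head(f, "slb", len(self.cfg.slb_hidden))

    # -- inference -------------------------------------------------------
    def features_no_grad(self, epochs: np.ndarray, batch: int = 128) -> np.ndarray:
        """Eval-mode features for a stack of epochs, without a graph."""
        was_training = self.training
        self.eval_mode()
        out = []
        with ad.no_grad():
            for i in range(0, len(epochs), batch):
                out.append(self.extract_features(epochs[i:i + batch]).data)
        self.train_mode(was_training)
        return np.concatenate(out) if out else np.empty((0, self.cfg.feature_dim), self.dtype)

    def predict_epochs(
        self, epochs: np.ndarray, alpha_test: float | None = None, batch: int = 128
    ) -> tuple[np.ndarray, np.ndarray]:
        """Score one record's consecutive epochs (n, 5, 3750).

        Context windows are built over the given sequence with edge
        replication.  Returns (probabilities (n, 5), integer labels).
        Features are computed once per epoch and shared by both
        branches.
        """
        from .psg_io import window_indices

        alpha = self.cfg.alpha_test if alpha_test is None else alpha_test
        if not 0.0 <= alpha <= 1.0:
            raise ValueError("alpha_test must lie in [0, 1]")
        feats = self.features_no_grad(np.asarray(epochs, dtype=self.dtype), batch=batch)
        with ad.no_grad():
            p_ep = self.elb_forward(feats).data
            idx = window_indices(len(feats), self.cfg.n_context)
            win = feats[idx].reshape(len(feats), -1)
            p_seq = self.slb_forward(win).data
        p = alpha * p_ep + (1.0 - alpha) * p_seq
        return p, np.argmax(p, axis=1)

    def predict(
        self, window: ContextWindow, alpha_test: float | None = None
    ) -> tuple[np.ndarray, str]:
        """Score a single context window; returns (5-probabilities, stage).

        Ties in the argmax resolve to the first stage in W,N1,N2,N3,REM
        order.
        """
        alpha = self.cfg.alpha_test if alpha_test is None else alpha_test
        if not 0.0 <= alpha <= 1.0:
            raise ValueError("alpha_test must lie in [0, 1]")
        if window.n_context != self.cfg.n_context:
            raise ValueError(
                f"window has N={window.n_context}, model expects N={self.cfg.n_context}"
            )
        feats = self.features_no_grad(window.tensors.astype(self.dtype))
        with ad.no_grad():
            p_ep = self.elb_forward(feats[self.cfg.n_context:self.cfg.n_context + 1]).data[0]
            p_seq = self.slb_forward(feats.reshape(1, -1)).data[0]
        p = alpha * p_ep + (1.0 - alpha) * p_seq
        return p, STAGES[int(np.argmax(p))]

    # -- checkpointing ---------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param/{k}": v.data.copy() for k, v in self.params.items()}
        state.update({f"running/{k}": v.copy() for k, v in self.running.items()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            v.data = np.asarray(state[f"param/{k}"], dtype=self.dtype)
        for k in self.running:
            self.running[k] = np.asarray(state[f"running/{k}"], dtype=self.dtype)

    def save(self, path: str | Path) -> None:
        """Single-file checkpoint: npz arrays + JSON config + class order."""
        meta = {
            "schema": CHECKPOINT_SCHEMA,
            "class_order": list(STAGES),
            "config": asdict(self.cfg),
        }
        buf = io.BytesIO()
        np.savez(buf, **self.state_dict())
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("meta.json", json.dumps(meta, indent=1))
            zf.writestr("arrays.npz", buf.getvalue())

    @classmethod
    def load(cls, path: str | Path) -> "TwoBranchNet":
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            if meta["schema"] != CHECKPOINT_SCHEMA:
                raise ValueError(f"unsupported checkpoint schema {meta['schema']}")
            if meta["class_order"] != list(STAGES):
                raise ValueError("checkpoint class order does not match this build")
            arrays = np.load(io.BytesIO(zf.read("arrays.npz")))
            cfgd = meta["config"]
            for key in ("block_channels", "elb_hidden", "slb_hidden", "block_strides"):
                cfgd[key] = tuple(cfgd[key])
            net = cls(ModelConfig(**cfgd))
            net.load_state_dict({k: arrays[k] for k in arrays.files})
        return net
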