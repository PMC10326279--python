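"""Transitive training: alpha-scheduled two-branch loss with gradient gating.

The combined objective is  L = alpha * L_ep + (1 - alpha) * L_seq  where
L_ep is the unweighted cross-entropy of the epoch branch and L_seq the
class-weighted cross-entropy of the sequence branch (weights inversely
proportional to training-set class counts, normalised to mean 1).  The
mixing factor follows  alpha(T) = 1 - (T / T_max)^2  over training
epochs T, so learning shifts smoothly from universal single-epoch
patterns to rebalanced contextual decisions.

L_seq is gated: the SLB consumes *detached* feature vectors, so its
gradient never reaches the feature extractor; CNN gradients equal
alpha * dL_ep/dtheta exactly.

Ablation regimes for the rebalancing comparison drop the ELB entirely
("none" = unweighted sequence loss, "weighted" = class-weighted
sequence loss) and let the sequence loss train the CNN directly.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import autodiff as ad
from .autodiff import Tensor
from .metrics import confusion, metrics_report
from .network import ModelConfig, TwoBranchNet
from .psg_io import EpochedDataset, window_indices
from .stages import STAGES

REGIMES = ("none", "weighted", "transitive")


# ---------------------------------------------------------------------
# schedule, weights, loss
# ---------------------------------------------------------------------

def alpha_at(T: int, T_max: int) -> float:
    """Two-branch mixing factor alpha = 1 - (T / T_max)^2."""
    if T_max <= 0:
        raise ValueError("T_max must be positive")
    if not 0 <= T <= T_max:
        raise ValueError(f"training epoch T={T} outside [0, {T_max}]")
    return 1.0 - (T / T_max) ** 2


def class_weights(counts: Mapping[str, int]) -> np.ndarray:
    """Inverse-frequency stage weights, normalised to mean 1.

    w_c = (1 / n_c) / mean_c(1 / n_c), ordered as W,N1,N2,N3,REM.
    """
    n = np.array([counts.get(s, 0) for s in STAGES], dtype=np.float64)
    if np.any(n <= 0):
        empty = [s for s, c in zip(STAGES, n) if c <= 0]
        raise ValueError(
            f"class(es) {empty} absent from training counts; drop the class "
            "or merge more records before weighting"
        )
    inv = 1.0 / n
    return inv / inv.mean()


@dataclass
class LossComponents:
    """The two branch losses and their alpha-mixture (graph tensors)."""

    L: Tensor
    L_ep: Tensor
    L_seq: Tensor
    alpha: float


def combined_loss(
    p_ep: Tensor,
    p_seq: Tensor,
    y: np.ndarray,
    alpha: float,
    weights: np.ndarray,
    clamp: float = 1e-12,
) -> LossComponents:
    """L = alpha * L_ep + (1 - alpha) * L_seq on one batch.

    L_ep is the plain mean of -log p_ep[y]; L_seq is the weighted mean
    sum_i w_{y_i} * (-log p_seq[y_i]) / sum_i w_{y_i} (weight-sum
    normalisation, unbiased under imbalanced batches).  Probabilities
    are clamped at ``clamp`` before the log.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    y = np.asarray(y)
    nll_ep = ad.mul(ad.log(ad.clip_min(ad.gather_labels(p_ep, y), clamp)), -1.0)
    L_ep = ad.mean(nll_ep)
    w_y = weights[y].astype(p_seq.data.dtype)
    nll_seq = ad.mul(ad.log(ad.clip_min(ad.gather_labels(p_seq, y), clamp)), -1.0)
    L_seq = ad.div(ad.sum_(ad.mul(nll_seq, w_y)), float(w_y.sum()))
    L = ad.add(ad.mul(L_ep, alpha), ad.mul(L_seq, 1.0 - alpha))
    return LossComponents(L=L, L_ep=L_ep, L_seq=L_seq, alpha=alpha)


def sequence_only_loss(
    p_seq: Tensor, y: np.ndarray, weights: np.ndarray | None, clamp: float = 1e-12
) -> Tensor:
    """Cross-entropy of the sequence branch alone (ELB removed)."""
    y = np.asarray(y)
    nll = ad.mul(ad.log(ad.clip_min(ad.gather_labels(p_seq, y), clamp)), -1.0)
    if weights is None:
        return ad.mean(nll)
    w_y = weights[y].astype(p_seq.data.dtype)
    return ad.div(ad.sum_(ad.mul(nll, w_y)), float(w_y.sum()))


def gated_backward(net: TwoBranchNet, loss: LossComponents) -> dict[str, np.ndarray]:
    """Backpropagate the combined loss and return gradients by name.

    Gating is structural: the SLB input features are detached, so
    feature-extractor gradients equal alpha * dL_ep/dtheta exactly and
    ELB/SLB gradients come only from their own branch terms.
    """
    net.zero_grad()
    loss.L.backward()
    return {k: (p.grad if p.grad is not None else np.zeros_like(p.data)) for k, p in net.params.items()}


# ---------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------

class Adam:
    """Adam with a mutable scalar learning rate (for step decay)."""

    def __init__(self, params: Mapping[str, Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = dict(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in self.params.items()}

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * (g * g)
            p.data = p.data - self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)


# ---------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings; defaults are the full-scale recipe."""

    total_iterations: int = 140_000
    batch_size: int = 200
    lr: float = 1e-3
    lr_decay_at_fraction: float = 0.7
    lr_decay_factor: float = 0.1
    epochs_per_train_epoch: int = 3_500
    seed: int = 0
    prob_clamp: float = 1e-12

    def __post_init__(self) -> None:
        if min(self.total_iterations, self.batch_size, self.epochs_per_train_epoch) <= 0:
            raise ValueError("iteration/batch settings must be positive")
        if not 0.0 < self.lr_decay_at_fraction < 1.0:
            raise ValueError("lr_decay_at_fraction must lie in (0, 1)")

    @property
    def t_max(self) -> int:
        """Number of training epochs the alpha schedule spans."""
        return -(-self.total_iterations // self.epochs_per_train_epoch)


class _DataView:
    """Flat arrays over a dataset for fast batch/window assembly."""

    def __init__(self, ds: EpochedDataset, n_context: int):
        Xs, labels, win, offset = [], [], [], 0
        scored_pos = []
        for rid, rec in ds.records.items():
            n = rec.X.shape[0]
            Xs.append(rec.X)
            labels.append(rec.labels)
            win.append(window_indices(n, n_context) + offset)
            scored = np.flatnonzero(rec.labels >= 0) + offset
            scored_pos.append(scored)
            offset += n
        self.X = np.concatenate(Xs)
        self.labels = np.concatenate(labels)
        self.windows = np.concatenate(win)           # (n_all, 2N+1) global idx
        self.scored = np.concatenate(scored_pos)     # global idx of scored epochs
        self.y_scored = self.labels[self.scored]

    def batch(self, rng: np.random.Generator, size: int):
        sel = self.scored[rng.integers(0, len(self.scored), size)]
        w = self.windows[sel]
        return self.X[w], self.labels[sel], w


@dataclass
class TrainResult:
    net: TwoBranchNet
    history: pd.DataFrame
    best: dict = field(default_factory=dict)


def predict_dataset(
    net: TwoBranchNet, ds: EpochedDataset, alpha_test: float | None = None
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-record (y_true, y_pred) integer labels for scored epochs.

    Context windows are built over each record's full raw epoch
    sequence (unscored epochs contribute context but are not scored).
    """
    out = {}
    for rid, rec in ds.records.items():
        probs, pred = net.predict_epochs(rec.X, alpha_test=alpha_test)
        scored = rec.labels >= 0
        out[rid] = (rec.labels[scored], pred[scored])
    return out


def _pooled_metrics(per_record: dict[str, tuple[np.ndarray, np.ndarray]]):
    yt = np.concatenate([t for t, _ in per_record.values()])
    yp = np.concatenate([p for _, p in per_record.values()])
    return metrics_report(confusion(yt, yp))


def train(
    train_ds: EpochedDataset,
    val_ds: EpochedDataset,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    regime: str = "transitive",
) -> TrainResult:
    """Optimise a :class:`TwoBranchNet` and return the best-MF1 checkpoint.

    ``regime`` selects the objective: "transitive" is the full
    two-branch alpha-scheduled loss; "none"/"weighted" drop the ELB and
    train CNN+SLB with an unweighted / class-weighted sequence loss.
    Validation runs at every training-epoch boundary; the checkpoint
    with the highest validation MF1 wins (ties: later epoch).
    """
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}; choose from {REGIMES}")
    if len(train_ds) == 0 or len(val_ds) == 0:
        raise ValueError("datasets must be non-empty")
    weights = class_weights(train_ds.class_counts)
    n_ctx = model_cfg.n_context
    view = _DataView(train_ds, n_ctx)
    net = TwoBranchNet(model_cfg, seed=train_cfg.seed)
    opt = Adam(net.params, lr=train_cfg.lr)
    batch_rng = np.random.default_rng(train_cfg.seed)

    decay_at = int(train_cfg.lr_decay_at_fraction * train_cfg.total_iterations)
    eval_alpha = model_cfg.alpha_test if regime == "transitive" else 0.0
    rows = []
    best_state, best_mf1, best_info = None, -np.inf, {}

    for it in range(train_cfg.total_iterations):
        if it == decay_at:
            opt.lr = train_cfg.lr * train_cfg.lr_decay_factor
        T = it // train_cfg.epochs_per_train_epoch
        alpha = alpha_at(T, train_cfg.t_max)
        Xw, y, w = view.batch(batch_rng, train_cfg.batch_size)
        B = len(y)
        net.train_mode()
        if regime == "transitive":
            # SLB inputs are detached, so they are computed in eval mode:
            # the branch then trains on the same feature distribution it
            # sees at inference (no BatchNorm train/eval shift).
            ctx_feats = net.features_no_grad(
                Xw.reshape(B * (2 * n_ctx + 1), *Xw.shape[2:])
            )
            feats_c = net.extract_features(Xw[:, n_ctx])
            p_ep = net.elb_forward(feats_c)
            p_seq = net.slb_forward(Tensor(ctx_feats.reshape(B, -1)))
            loss = combined_loss(p_ep, p_seq, y, alpha, weights, clamp=train_cfg.prob_clamp)
            net.zero_grad()
            loss.L.backward()
            l_ep, l_seq, l_tot = loss.L_ep.item(), loss.L_seq.item(), loss.L.item()
        else:
            feats = net.extract_features(Xw.reshape(B * (2 * n_ctx + 1), *Xw.shape[2:]))
            p_seq = net.slb_forward(ad.reshape(feats, (B, -1)))
            w_or_none = weights if regime == "weighted" else None
            L = sequence_only_loss(p_seq, y, w_or_none, clamp=train_cfg.prob_clamp)
            net.zero_grad()
            L.backward()
            l_ep, l_seq, l_tot = np.nan, L.item(), L.item()
        opt.step()

        row = {
            "iteration": it,
            "epoch": T,
            "alpha": alpha,
            "L_ep": l_ep,
            "L_seq": l_seq,
            "L": l_tot,
            "lr": opt.lr,
            "val_acc": np.nan,
            "val_kappa": np.nan,
            "val_mf1": np.nan,
        }
        end_of_epoch = (it + 1) % train_cfg.epochs_per_train_epoch == 0
        if end_of_epoch or it + 1 == train_cfg.total_iterations:
            rep = _pooled_metrics(predict_dataset(net.eval_mode(), val_ds, eval_alpha))
            row["val_acc"], row["val_kappa"], row["val_mf1"] = rep.accuracy, rep.kappa, rep.mf1
            if rep.mf1 >= best_mf1:
                best_mf1 = rep.mf1
                best_state = copy.deepcopy(net.state_dict())
                best_info = {"iteration": it, "epoch": T, "val_mf1": rep.mf1,
                             "val_acc": rep.accuracy, "val_kappa": rep.kappa}
        rows.append(row)

    if best_state is not None:
        net.load_state_dict(best_state)
    net.eval_mode()
    return TrainResult(net=net, history=pd.DataFrame(rows), best=best_info)


# ---------------------------------------------------------------------
# rebalancing comparison (scaled ablation experiment)
# ---------------------------------------------------------------------

def run_rebalancing_comparison(
    sim_cfg,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    regimes: Sequence[str] = REGIMES,
    seeds: Sequence[int] = (0, 1, 2),
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
) -> pd.DataFrame:
    """Train every regime on identical synthetic data for each seed.

    For a given seed all regimes share byte-identical datasets and the
    same batch-sampling stream, so differences are attributable to the
    objective alone.  Returns one row per (regime, seed) with overall
    accuracy/kappa/MF1, per-stage recall and the confusion counts.
    """
    from .simulator import simulate_split

    rows = []
    for seed in seeds:
        tr, va, te = simulate_split(
            replace(sim_cfg, seed=sim_cfg.seed + 7919 * seed), fractions=split_fractions
        )
        for regime in regimes:
            res = train(tr, va, model_cfg, replace(train_cfg, seed=train_cfg.seed + seed), regime)
            eval_alpha = model_cfg.alpha_test if regime == "transitive" else 0.0
            per_rec = predict_dataset(res.net, te, eval_alpha)
            yt = np.concatenate([t for t, _ in per_rec.values()])
            yp = np.concatenate([p for _, p in per_rec.values()])
            cm = confusion(yt, yp)
            rep = metrics_report(cm)
            row = {"regime": regime, "seed": seed, "accuracy": rep.accuracy,
                   "kappa": rep.kappa, "mf1": rep.mf1, "n_epochs": rep.n_epochs}
            for s in STAGES:
                row[f"recall_{s}"] = rep.per_class_recall[s]
            row["confusion"] = cm.counts.tolist()
            rows.append(row)
    return pd.DataFrame(rows)


def tradeoff_verdict(table: pd.DataFrame) -> dict:
    """Seed-majority check of the rebalancing trade-off.

    The transitive regime should recall more N1 than the unweighted
    ("none") regime while keeping higher overall accuracy than the
    fully weighted regime.
    """
    by = table.set_index(["regime", "seed"])
    seeds = sorted(table["seed"].unique())
    n1_wins, acc_wins, both = 0, 0, 0
    for s in seeds:
        n1 = by.loc[("transitive", s), "recall_N1"] > by.loc[("none", s), "recall_N1"]
        acc = by.loc[("transitive", s), "accuracy"] > by.loc[("weighted", s), "accuracy"]
        n1_wins += bool(n1)
        acc_wins += bool(acc)
        both += bool(n1 and acc)
    k = len(seeds)
    return {
        "seeds": k,
        "n1_recall_wins": n1_wins,
        "accuracy_wins": acc_wins,
        "both_wins": both,
        "majority": both > k / 2,
    }
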