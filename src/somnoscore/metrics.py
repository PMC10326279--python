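"""Hypnogram agreement metrics: confusion, kappa, macro-F1, stability.

Conventions: confusion matrices are stored as raw counts with
human-scored labels on rows and machine-scored labels on columns, both
in the fixed order W,N1,N2,N3,REM; row-normalised percentages are a
rendering, not the storage format.  UNSCORED epochs must be removed
before any metric is computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .psg_io import Hypnogram
from .stages import STAGE_TO_INDEX, STAGES

N_STAGES = len(STAGES)


@dataclass(frozen=True)
class ConfusionMatrix:
    """5x5 count matrix; rows = human labels, columns = predictions."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (N_STAGES, N_STAGES):
            raise ValueError(f"expected {N_STAGES}x{N_STAGES} counts, got {c.shape}")
        if np.any(c < 0):
            raise ValueError("confusion counts must be non-negative")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_normalized(self) -> np.ndarray:
        """Empirical P(predicted j | truth i); zero rows stay zero."""
        rows = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(rows > 0, self.counts / rows, 0.0)
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(STAGES), columns=list(STAGES))


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    kappa: float
    mf1: float
    per_class_recall: dict[str, float]
    per_class_f1: dict[str, float]
    n_epochs: int

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "kappa": self.kappa,
            "mf1": self.mf1,
            "per_class_recall": self.per_class_recall,
            "per_class_f1": self.per_class_f1,
            "n_epochs": self.n_epochs,
        }


def _as_indices(y: Sequence) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype.kind in "iu":
        if np.any((y < 0) | (y >= N_STAGES)):
            raise ValueError("integer labels must lie in [0, 5)")
        return y.astype(np.int64)
    try:
        return np.array([STAGE_TO_INDEX[s] for s in y], dtype=np.int64)
    except KeyError as e:
        raise ValueError(f"label {e.args[0]!r} is not one of {STAGES}") from None


def confusion(y_true: Sequence, y_pred: Sequence) -> ConfusionMatrix:
    """Count matrix over the five stages; labels may be names or indices."""
    t, p = _as_indices(y_true), _as_indices(y_pred)
    if len(t) != len(p):
        raise ValueError(f"length mismatch: {len(t)} truths vs {len(p)} predictions")
    counts = np.zeros((N_STAGES, N_STAGES), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts)


def accuracy(cm: ConfusionMatrix) -> float:
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def cohens_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement: (p_o - p_e) / (1 - p_e)."""
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(cm.counts) / n
    p_e = float(cm.counts.sum(axis=1) @ cm.counts.sum(axis=0)) / (n * n)
    if p_e >= 1.0 - 1e-15:
        if p_o >= 1.0 - 1e-15:
            return 1.0
        raise ValueError("kappa undefined: expected agreement is 1 with imperfect observed")
    return float((p_o - p_e) / (1.0 - p_e))


def per_class_recall(cm: ConfusionMatrix) -> dict[str, float]:
    """Diagonal over row sums; NaN for stages absent from the truth."""
    rows = cm.counts.sum(axis=1)
    out = {}
    for i, s in enumerate(STAGES):
        out[s] = float(cm.counts[i, i] / rows[i]) if rows[i] > 0 else float("nan")
    return out


def per_class_f1(cm: ConfusionMatrix) -> dict[str, float]:
    """F1 per stage; 0 when precision+recall is 0, NaN when the stage is
    absent from both truth and predictions."""
    rows = cm.counts.sum(axis=1)
    cols = cm.counts.sum(axis=0)
    out = {}
    for i, s in enumerate(STAGES):
        if rows[i] == 0 and cols[i] == 0:
            out[s] = float("nan")
            continue
        denom = rows[i] + cols[i]
        out[s] = float(2.0 * cm.counts[i, i] / denom) if denom > 0 else 0.0
    return out


def macro_f1(cm: ConfusionMatrix, present_only: bool = False) -> float:
    """Unweighted mean of per-stage F1.

    Stages absent from both truth and predictions are always excluded;
    with ``present_only`` stages absent from the truth are excluded as
    well (the per-record reporting convention).
    """
    f1 = per_class_f1(cm)
    rows = cm.counts.sum(axis=1)
    vals = []
    for i, s in enumerate(STAGES):
        if np.isnan(f1[s]):
            continue
        if present_only and rows[i] == 0:
            continue
        vals.append(f1[s])
    if not vals:
        raise ValueError("no stages present in the confusion matrix")
    return float(np.mean(vals))


def metrics_report(cm: ConfusionMatrix, present_only: bool = False) -> MetricsReport:
    return MetricsReport(
        accuracy=accuracy(cm),
        kappa=cohens_kappa(cm),
        mf1=macro_f1(cm, present_only=present_only),
        per_class_recall=per_class_recall(cm),
        per_class_f1=per_class_f1(cm),
        n_epochs=cm.total,
    )


# ---------------------------------------------------------------------
# stable / transitional decomposition
# ---------------------------------------------------------------------

def stability_split(hyp: Hypnogram | Sequence) -> np.ndarray:
    """Boolean stable-flag per epoch of one record's label sequence.

    An epoch is stable iff both temporal neighbours exist within the
    record and carry the same label; first and last epochs are always
    transitional.  The stable and transitional sets partition the
    record exactly.
    """
    labels = np.asarray(hyp.stages if isinstance(hyp, Hypnogram) else hyp)
    n = len(labels)
    stable = np.zeros(n, dtype=bool)
    if n >= 3:
        stable[1:-1] = (labels[1:-1] == labels[:-2]) & (labels[1:-1] == labels[2:])
    return stable


def by_record_metrics(
    per_record: Mapping[str, tuple[Sequence, Sequence]]
) -> pd.DataFrame:
    """One metrics row per record (boxplot-style reporting).

    Stages absent from a record's human scoring get NaN recall/F1 and
    are excluded from that record's MF1.
    """
    if not per_record:
        raise ValueError("need at least one record")
    rows = []
    for rid, (yt, yp) in per_record.items():
        cm = confusion(yt, yp)
        rep = metrics_report(cm, present_only=True)
        truth_rows = cm.counts.sum(axis=1)
        row = {"record_id": rid, "n_epochs": rep.n_epochs, "accuracy": rep.accuracy,
               "kappa": rep.kappa, "mf1": rep.mf1}
        for i, s in enumerate(STAGES):
            absent = truth_rows[i] == 0
            row[f"recall_{s}"] = float("nan") if absent else rep.per_class_recall[s]
            row[f"f1_{s}"] = float("nan") if absent else rep.per_class_f1[s]
        rows.append(row)
    return pd.DataFrame(rows)
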