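"""Reading, preprocessing and epoching of five-channel PSG recordings.

The pipeline mirrors standard sleep-lab practice: EEG/EOG are band-pass
filtered 0.3-35 Hz and chin EMG high-pass filtered at 10 Hz (zero-phase
windowed FIR via mne), amplitudes are saturated at +/-500 uV, and all
channels are resampled to a common 125 Hz before being cut into 30-s
epochs of shape 5 x 3750 aligned with a hypnogram.

EDF reading is delegated to mne; hypnograms use a small
``epoch,stage`` CSV dialect with AASM tokens W/N1/N2/N3/REM/UNSCORED.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import yaml
from scipy import signal as sps

from .stages import (
    CHANNELS,
    EEG_EOG_CHANNELS,
    EPOCH_LENGTH_S,
    SAMPLES_PER_EPOCH,
    STAGE_TO_INDEX,
    STAGES,
    TARGET_RATE_HZ,
    UNSCORED,
    VALID_TOKENS,
)

_UNSCORED_CODE = -1

#: EDF physical-dimension strings accepted as voltage, with scale to uV
_VOLTAGE_UNITS = {"uv": 1.0, "µv": 1.0, "μv": 1.0, "mv": 1e3, "v": 1e6}


# ---------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------

@dataclass
class PSGRecord:
    """A five-channel PSG recording in uV, channels in canonical order."""

    record_id: str
    channels: list[np.ndarray]  # one 1-d float array per canonical channel
    sampling_rates: tuple[float, ...]  # Hz, per channel
    start_time: object | None = None

    def __post_init__(self) -> None:
        if len(self.channels) != len(CHANNELS):
            raise ValueError(f"expected {len(CHANNELS)} channels, got {len(self.channels)}")
        if len(self.sampling_rates) != len(CHANNELS):
            raise ValueError("one sampling rate per channel required")
        for lbl, rate in zip(CHANNELS, self.sampling_rates):
            if not rate > 0:
                raise ValueError(f"non-positive sampling rate for {lbl}")

    @property
    def uniform_rate(self) -> float:
        """Common sampling rate; raises if channels disagree."""
        rates = set(self.sampling_rates)
        if len(rates) != 1:
            raise ValueError(f"channels have mixed sampling rates: {sorted(rates)}")
        return rates.pop()

    def as_array(self) -> np.ndarray:
        """Stack channels into a (5, n) array; requires uniform rate/length."""
        self.uniform_rate
        lengths = {len(c) for c in self.channels}
        if len(lengths) != 1:
            raise ValueError("channels have unequal lengths")
        return np.stack(self.channels)


@dataclass(frozen=True)
class Hypnogram:
    """Per-30-s-epoch stage labels."""

    stages: tuple[str, ...]
    epoch_length_s: float = EPOCH_LENGTH_S

    def __post_init__(self) -> None:
        if len(self.stages) < 1:
            raise ValueError("hypnogram must contain at least one epoch")
        bad = set(self.stages) - VALID_TOKENS
        if bad:
            raise ValueError(f"unknown stage tokens: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.stages)


@dataclass(frozen=True)
class ContextWindow:
    """A center epoch plus N neighbors on each side (2N+1 tensors)."""

    center_index: int
    tensors: np.ndarray  # (2N+1, 5, 3750)
    n_context: int

    def __post_init__(self) -> None:
        if self.tensors.shape[0] != 2 * self.n_context + 1:
            raise ValueError("context window must hold 2N+1 epochs")


@dataclass
class _RecordEpochs:
    """All raw epochs of one record; unscored epochs kept for context."""

    X: np.ndarray       # (n_epochs, 5, 3750) float32, uV
    labels: np.ndarray  # (n_epochs,) int; -1 marks UNSCORED


@dataclass
class EpochedDataset:
    """Aligned (5x3750 tensor, stage) pairs across one or more records.

    Unscored epochs are excluded from the scored index and class counts
    but remain available as raw context for their temporal neighbors.
    """

    records: dict[str, _RecordEpochs] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._reindex()

    def _reindex(self) -> None:
        idx: list[tuple[str, int]] = []
        for rid, rec in self.records.items():
            for j in np.flatnonzero(rec.labels >= 0):
                idx.append((rid, int(j)))
        self._index = idx

    # -- scored-epoch views -------------------------------------------
    @property
    def index(self) -> list[tuple[str, int]]:
        """(record_id, epoch_index) of every scored epoch, in order."""
        return self._index

    def __len__(self) -> int:
        return len(self._index)

    def __iter__(self) -> Iterator[tuple[np.ndarray, str, str, int]]:
        for rid, j in self._index:
            rec = self.records[rid]
            yield rec.X[j], STAGES[rec.labels[j]], rid, j

    @property
    def y(self) -> np.ndarray:
        """Integer stage labels of the scored epochs."""
        return np.array([self.records[r].labels[j] for r, j in self._index], dtype=np.int64)

    def tensor(self, record_id: str, epoch_index: int) -> np.ndarray:
        return self.records[record_id].X[epoch_index]

    @property
    def class_counts(self) -> dict[str, int]:
        counts = dict.fromkeys(STAGES, 0)
        for rid, rec in self.records.items():
            lab, cnt = np.unique(rec.labels[rec.labels >= 0], return_counts=True)
            for li, c in zip(lab, cnt):
                counts[STAGES[li]] += int(c)
        return counts

    def merged_with(self, other: "EpochedDataset") -> "EpochedDataset":
        overlap = set(self.records) & set(other.records)
        if overlap:
            raise ValueError(f"duplicate record ids: {sorted(overlap)}")
        return EpochedDataset({**self.records, **other.records})


@dataclass(frozen=True)
class PreprocessConfig:
    """Filter/clip/resample settings; defaults are the standard pipeline."""

    eeg_band: tuple[float, float] = (0.3, 35.0)
    emg_highpass: float = 10.0
    clip_uv: float = 500.0
    target_rate: float = TARGET_RATE_HZ

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PreprocessConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown preprocess keys: {sorted(unknown)}")
        if "eeg_band" in raw:
            raw["eeg_band"] = tuple(raw["eeg_band"])
        return cls(**raw)


# ---------------------------------------------------------------------
# EDF / CSV loading
# ---------------------------------------------------------------------

def _edf_signal_units(path: Path) -> dict[str, str]:
    """Channel label -> physical dimension, straight from the EDF header."""
    with open(path, "rb") as fh:
        header = fh.read(256)
        ns = int(header[252:256].decode("ascii").strip())
        sig = fh.read(ns * 256)
    labels = [sig[16 * i:16 * (i + 1)].decode("ascii", "replace").strip() for i in range(ns)]
    off = ns * (16 + 80)
    units = [sig[off + 8 * i:off + 8 * (i + 1)].decode("ascii", "replace").strip() for i in range(ns)]
    return dict(zip(labels, units))


def load_edf(path: str | Path, channel_map: Mapping[str, str] | None = None) -> PSGRecord:
    """Read an EDF/EDF+ file into a canonical-order :class:`PSGRecord`.

    ``channel_map`` maps EDF channel labels (aliases such as
    ``"EEG C3-A2"``) to canonical names C3/C4/EOGL/EOGR/EMG; identity
    mapping is assumed for labels that already are canonical.
    """
    import mne

    path = Path(path)
    units = _edf_signal_units(path)
    channel_map = dict(channel_map or {})
    alias_of: dict[str, str] = {}
    for alias, canon in channel_map.items():
        if canon not in CHANNELS:
            raise ValueError(f"channel_map target {canon!r} is not canonical")
        alias_of[canon] = alias
    for canon in CHANNELS:  # identity fallback
        alias_of.setdefault(canon, canon)

    available = list(units)
    missing = [c for c in CHANNELS if alias_of[c] not in units]
    if missing:
        raise ValueError(
            f"EDF is missing canonical channel(s) {missing}; available labels: {available}"
        )
    for canon in CHANNELS:
        u = units[alias_of[canon]].lower()
        if u not in _VOLTAGE_UNITS:
            raise ValueError(
                f"channel {alias_of[canon]!r} has non-voltage unit {units[alias_of[canon]]!r}"
            )

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data()  # volts for voltage-typed channels
    chans = []
    for canon in CHANNELS:
        i = raw.ch_names.index(alias_of[canon])
        chans.append(np.asarray(data[i], dtype=np.float64) * 1e6)  # -> uV
    rate = float(raw.info["sfreq"])
    return PSGRecord(
        record_id=path.stem,
        channels=chans,
        sampling_rates=(rate,) * len(CHANNELS),
        start_time=raw.info.get("meas_date"),
    )


def load_hypnogram(path: str | Path) -> Hypnogram:
    """Read the ``epoch,stage`` CSV dialect into a :class:`Hypnogram`."""
    path = Path(path)
    stages: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty hypnogram file") from None
        if [h.strip() for h in header] != ["epoch", "stage"]:
            raise ValueError(f"{path}: expected header 'epoch,stage', got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 2:
                raise ValueError(f"{path}:{lineno}: expected two fields, got {row}")
            idx_s, tok = row[0].strip(), row[1].strip()
            try:
                idx = int(idx_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer epoch index {idx_s!r}") from None
            if idx != len(stages):
                raise ValueError(f"{path}:{lineno}: epoch index {idx}, expected {len(stages)}")
            if tok not in VALID_TOKENS:
                raise ValueError(f"{path}:{lineno}: unknown stage token {tok!r}")
            stages.append(tok)
    if not stages:
        raise ValueError(f"{path}: hypnogram has no epochs")
    return Hypnogram(tuple(stages))


def write_hypnogram_csv(hyp: Hypnogram, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["epoch", "stage"])
        for i, s in enumerate(hyp.stages):
            writer.writerow([i, s])


# ---------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------

def _resample_fraction(rate: float, target: float) -> Fraction:
    return Fraction(target / rate).limit_denominator(1000)


def preprocess(rec: PSGRecord, cfg: PreprocessConfig | None = None) -> PSGRecord:
    """Filter, clip and resample a record to the common analysis rate.

    EEG and EOG channels are zero-phase band-pass filtered (default
    0.3-35 Hz), EMG is high-pass filtered (default 10 Hz), all samples
    are hard-saturated at +/-``clip_uv`` and every channel is resampled
    (polyphase) to ``target_rate``.  No normalisation or artifact
    rejection is applied.

    Filtering uses MNE's windowed-FIR design (linear phase, delay
    compensated): forward-backward IIR at a 0.3 Hz cutoff rings for
    seconds past any amplitude step or recording edge, while the FIR
    response is compactly supported, which keeps transient morphology
    (K-complexes, spindles) and recording edges clean.  The saturation
    is re-applied after resampling so the +/-``clip_uv`` bound survives
    interpolation overshoot.
    """
    from mne.filter import filter_data

    cfg = cfg or PreprocessConfig()
    out_channels: list[np.ndarray] = []
    for label, x, rate in zip(CHANNELS, rec.channels, rec.sampling_rates):
        if not np.all(np.isfinite(x)):
            raise ValueError(f"channel {label} contains non-finite samples")
        if rate < 2 * cfg.eeg_band[1]:
            raise ValueError(
                f"channel {label}: sampling rate {rate} Hz too low for "
                f"{cfg.eeg_band[1]} Hz content (need >= {2 * cfg.eeg_band[1]} Hz)"
            )
        if label in EEG_EOG_CHANNELS:
            l_freq, h_freq = cfg.eeg_band
        else:
            l_freq, h_freq = cfg.emg_highpass, None
        y = filter_data(np.asarray(x, dtype=np.float64), rate, l_freq, h_freq,
                        verbose="error")
        y = np.clip(y, -cfg.clip_uv, cfg.clip_uv)
        frac = _resample_fraction(rate, cfg.target_rate)
        if frac != 1:
            y = sps.resample_poly(y, frac.numerator, frac.denominator)
            y = np.clip(y, -cfg.clip_uv, cfg.clip_uv)
        out_channels.append(np.asarray(y, dtype=np.float64))
    n = min(len(c) for c in out_channels)
    out_channels = [c[:n] for c in out_channels]
    return PSGRecord(
        record_id=rec.record_id,
        channels=out_channels,
        sampling_rates=(cfg.target_rate,) * len(CHANNELS),
        start_time=rec.start_time,
    )


# ---------------------------------------------------------------------
# epoching and context windows
# ---------------------------------------------------------------------

def epoch_record(rec: PSGRecord, hyp: Hypnogram) -> EpochedDataset:
    """Cut a preprocessed record into labelled 30-s epochs.

    Epoch ``i`` covers samples ``[i*3750, (i+1)*3750)``.  A hypnogram
    longer than the signal is truncated with a warning; UNSCORED epochs
    are retained as raw context but excluded from the scored index.
    """
    rate = rec.uniform_rate
    if abs(rate - TARGET_RATE_HZ) > 1e-9:
        raise ValueError(f"record must be preprocessed to {TARGET_RATE_HZ} Hz, got {rate}")
    x = rec.as_array()
    n_sig = x.shape[1] // SAMPLES_PER_EPOCH
    n = min(len(hyp), n_sig)
    if len(hyp) > n_sig:
        warnings.warn(
            f"{rec.record_id}: hypnogram has {len(hyp)} epochs but signal only "
            f"{n_sig}; truncating",
            stacklevel=2,
        )
    if n == 0:
        raise ValueError(f"{rec.record_id}: signal shorter than one epoch")
    X = (
        x[:, : n * SAMPLES_PER_EPOCH]
        .reshape(len(CHANNELS), n, SAMPLES_PER_EPOCH)
        .transpose(1, 0, 2)
        .astype(np.float32)
    )
    labels = np.array(
        [STAGE_TO_INDEX.get(s, _UNSCORED_CODE) for s in hyp.stages[:n]], dtype=np.int64
    )
    if not np.any(labels >= 0):
        raise ValueError(f"{rec.record_id}: no scored epochs retained")
    return EpochedDataset({rec.record_id: _RecordEpochs(X=X, labels=labels)})


def context_window(
    ds: EpochedDataset, record_id: str, epoch_index: int, n_context: int = 2
) -> ContextWindow:
    """The 2N+1 raw epoch tensors around one epoch of one record.

    Neighbors follow raw temporal adjacency (unscored epochs included);
    indices past either record boundary replicate the edge epoch.
    """
    if n_context < 0:
        raise ValueError("n_context must be non-negative")
    rec = ds.records[record_id]
    n = rec.X.shape[0]
    if not 0 <= epoch_index < n:
        raise IndexError(f"epoch {epoch_index} outside record {record_id} (n={n})")
    idx = np.clip(np.arange(epoch_index - n_context, epoch_index + n_context + 1), 0, n - 1)
    return ContextWindow(center_index=epoch_index, tensors=rec.X[idx], n_context=n_context)


def window_indices(n_epochs: int, n_context: int) -> np.ndarray:
    """(n_epochs, 2N+1) neighbor indices with edge replication."""
    base = np.arange(n_epochs)[:, None] + np.arange(-n_context, n_context + 1)[None, :]
    return np.clip(base, 0, n_epochs - 1)
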