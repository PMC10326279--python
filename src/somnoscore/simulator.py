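"""Synthetic polysomnography: Markov hypnograms + stage-conditioned signals.

The hypnogram generator samples a five-state Markov chain whose default
transition matrix is built by detailed balance from a symmetric
inter-stage "flow" structure (W<->N1<->N2<->N3, REM entered from N2,
brief N1 bouts), so its stationary distribution equals the target
overnight stage proportions *exactly*: W 28.7%, N1 3.7%, N2 41.0%,
N3 12.6%, REM 14.0% (typical of large adult cohort studies).

Signals are deliberately simple: per stage and channel, sums of
band-limited Gaussian noise (FFT-shaped), plus scheduled transients
(sleep spindles and K-complexes in N2, slow eye movements in N1, rapid
eye movements in REM) and a stage-ordered chin-EMG tone
(W > N1 > N2 > N3 > REM).

The ambiguity dial ``lambda`` in [0, 1] makes N1 the low-resource,
context-dependent class: each N1 epoch's spectral profile is blended
toward the profile of a neighbouring W or N2 "disguise" stage, so at
lambda = 1 single-epoch features of N1 approach chance while the
surrounding stage sequence stays informative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.fft import irfft, rfft, rfftfreq
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .edf import write_edf
from .psg_io import EpochedDataset, Hypnogram, _RecordEpochs
from .stages import CHANNELS, STAGE_TO_INDEX, STAGES, TARGET_RATE_HZ

#: target stationary stage proportions (W, N1, N2, N3, REM)
DEFAULT_STATIONARY = np.array([0.287, 0.037, 0.410, 0.126, 0.140])


# ---------------------------------------------------------------------
# transition structure
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic 5x5 stage transition matrix + initial distribution."""

    P: np.ndarray
    initial: np.ndarray

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=np.float64)
        init = np.asarray(self.initial, dtype=np.float64)
        if P.shape != (5, 5) or init.shape != (5,):
            raise ValueError("need a 5x5 matrix and a length-5 initial distribution")
        if np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("rows must be non-negative and sum to 1")
        if not np.isclose(init.sum(), 1.0, atol=1e-9):
            raise ValueError("initial distribution must sum to 1")
        object.__setattr__(self, "P", P)
        object.__setattr__(self, "initial", init)


def default_transition_matrix() -> TransitionMatrix:
    """The calibrated default chain.

    Built from symmetric stage-pair flows F (probability mass exchanged
    per step) with P[i, j] = F[i, j] / pi[i]; detailed balance then
    makes ``pi`` = DEFAULT_STATIONARY the exact stationary
    distribution.  Flow sizes encode sleep macro-structure: N1 is a
    short-lived gateway between W and N2, N3 and REM are entered almost
    exclusively from N2.
    """
    pi = DEFAULT_STATIONARY
    F = np.zeros((5, 5))
    pairs = {
        ("W", "N1"): 0.0100,
        ("N1", "N2"): 0.0080,
        ("W", "N2"): 0.0060,
        ("N2", "N3"): 0.0110,
        ("N2", "REM"): 0.0100,
        ("W", "REM"): 0.0040,
        ("N3", "W"): 0.0010,
        ("N1", "REM"): 0.0005,
    }
    for (a, b), f in pairs.items():
        i, j = STAGE_TO_INDEX[a], STAGE_TO_INDEX[b]
        F[i, j] = F[j, i] = f
    np.fill_diagonal(F, pi - F.sum(axis=1))
    if np.any(np.diag(F) < 0):
        raise ValueError("flow structure exceeds stationary mass")
    P = F / pi[:, None]
    return TransitionMatrix(P=P, initial=pi.copy())


def stationary_distribution(tm: TransitionMatrix) -> np.ndarray:
    """Unique stationary distribution (left eigenvector for eigenvalue 1)."""
    n_comp, _ = connected_components(csr_matrix(tm.P > 0), connection="strong")
    if n_comp != 1:
        raise ValueError("transition matrix is reducible; no unique stationary distribution")
    vals, vecs = np.linalg.eig(tm.P.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    v = np.real(vecs[:, k])
    v = np.abs(v)
    return v / v.sum()


def simulate_hypnogram(
    tm: TransitionMatrix, n_epochs: int, seed: int | np.random.Generator
) -> Hypnogram:
    """Sample a stage sequence of ``n_epochs`` 30-s epochs."""
    if n_epochs < 1:
        raise ValueError("need at least one epoch")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cum = np.cumsum(tm.P, axis=1)
    u = rng.random(n_epochs)
    states = np.empty(n_epochs, dtype=np.int64)
    s = int(np.searchsorted(np.cumsum(tm.initial), u[0], side="right"))
    states[0] = min(s, 4)
    for t in range(1, n_epochs):
        states[t] = min(int(np.searchsorted(cum[states[t - 1]], u[t], side="right")), 4)
    return Hypnogram(tuple(STAGES[i] for i in states))


# ---------------------------------------------------------------------
# stage-conditioned signal profiles
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelBands:
    """Band-noise components: (center Hz, bandwidth Hz, RMS uV)."""

    eeg: tuple[tuple[float, float, float], ...]
    eog: tuple[tuple[float, float, float], ...]
    emg_rms: float
    spindle_rate: float = 0.0    # bursts per 30 s (N2)
    kcomplex_rate: float = 0.0   # waves per 30 s (N2)
    sem_rate: float = 0.0        # slow eye movements per 30 s (N1)
    rem_rate: float = 0.0        # rapid eye movements per 30 s (REM)


@dataclass(frozen=True)
class StageSignalProfile:
    """Per-stage synthesis parameters for all five channels."""

    stages: Mapping[str, ChannelBands]

    def __post_init__(self) -> None:
        missing = set(STAGES) - set(self.stages)
        if missing:
            raise ValueError(f"profile missing stages: {sorted(missing)}")
        for s, cb in self.stages.items():
            for f0, bw, rms in (*cb.eeg, *cb.eog):
                if rms < 0:
                    raise ValueError(f"{s}: negative component amplitude")
                if f0 + bw / 2 >= TARGET_RATE_HZ / 2:
                    raise ValueError(f"{s}: component at {f0} Hz exceeds Nyquist")

    @classmethod
    def default(cls) -> "StageSignalProfile":
        return cls(
            stages={
                "W": ChannelBands(
                    eeg=((10.0, 2.5, 30.0), (20.0, 8.0, 10.0)),
                    eog=((0.8, 0.6, 14.0), (3.0, 2.0, 6.0)),
                    emg_rms=30.0,
                ),
                "N1": ChannelBands(
                    eeg=((6.0, 2.0, 26.0), (10.0, 2.5, 7.0)),
                    eog=((0.9, 0.7, 8.0),),
                    emg_rms=18.0,
                    sem_rate=4.0,
                ),
                "N2": ChannelBands(
                    eeg=((6.0, 2.5, 18.0), (2.0, 1.5, 15.0)),
                    eog=((1.0, 0.8, 5.0),),
                    emg_rms=10.0,
                    spindle_rate=3.0,
                    kcomplex_rate=1.0,
                ),
                "N3": ChannelBands(
                    eeg=((1.2, 0.9, 80.0), (5.0, 2.0, 12.0)),
                    eog=((1.0, 0.8, 4.0),),
                    emg_rms=6.0,
                ),
                "REM": ChannelBands(
                    eeg=((5.5, 2.5, 18.0), (22.0, 8.0, 6.0)),
                    eog=((1.2, 1.0, 5.0),),
                    emg_rms=3.0,
                    rem_rate=8.0,
                ),
            }
        )


def _blend(a: ChannelBands, b: ChannelBands, lam: float) -> ChannelBands:
    """(1-lam) * a + lam * b: amplitudes and event rates interpolate."""
    scale = lambda comps, w: tuple((f0, bw, rms * w) for f0, bw, rms in comps)
    return ChannelBands(
        eeg=scale(a.eeg, 1 - lam) + scale(b.eeg, lam),
        eog=scale(a.eog, 1 - lam) + scale(b.eog, lam),
        emg_rms=(1 - lam) * a.emg_rms + lam * b.emg_rms,
        spindle_rate=(1 - lam) * a.spindle_rate + lam * b.spindle_rate,
        kcomplex_rate=(1 - lam) * a.kcomplex_rate + lam * b.kcomplex_rate,
        sem_rate=(1 - lam) * a.sem_rate + lam * b.sem_rate,
        rem_rate=(1 - lam) * a.rem_rate + lam * b.rem_rate,
    )


# ---------------------------------------------------------------------
# waveform synthesis
# ---------------------------------------------------------------------

def _band_noise(n: int, rate: float, f0: float, bw: float, rms: float,
                rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise spectrally shaped to a Gaussian band, exact RMS."""
    if rms == 0.0:
        return np.zeros(n)
    spec = rfft(rng.standard_normal(n))
    f = rfftfreq(n, 1.0 / rate)
    spec *= np.exp(-0.5 * ((f - f0) / max(bw / 2.0, 1e-3)) ** 2)
    y = irfft(spec, n)
    sd = y.std()
    return y * (rms / sd) if sd > 0 else y


def _burst(n: int, rate: float, f0: float, dur_s: float, amp: float,
           t0: int) -> np.ndarray:
    """A Hann-windowed oscillatory burst starting at sample t0."""
    m = int(dur_s * rate)
    t = np.arange(m) / rate
    w = amp * np.hanning(m) * np.sin(2 * np.pi * f0 * t)
    out = np.zeros(n)
    end = min(t0 + m, n)
    out[t0:end] = w[: end - t0]
    return out


def _biphasic(n: int, rate: float, amp: float, t0: int) -> np.ndarray:
    """K-complex-like biphasic wave (~1 s derivative-of-Gaussian)."""
    m = int(1.0 * rate)
    t = np.linspace(-2.5, 2.5, m)
    w = -amp * t * np.exp(0.5 - 0.5 * t * t)
    out = np.zeros(n)
    end = min(t0 + m, n)
    out[t0:end] = w[: end - t0]
    return out


def simulate_epoch(
    stage: str,
    profile: StageSignalProfile,
    rng: np.random.Generator,
    rate: float = TARGET_RATE_HZ,
    bands: ChannelBands | None = None,
) -> np.ndarray:
    """One 30-s five-channel epoch (5, 30*rate) in uV for ``stage``.

    ``bands`` overrides the stage's profile entry (used for
    ambiguity-blended N1 epochs).
    """
    cb = bands if bands is not None else profile.stages[stage]
    n = int(round(30.0 * rate))
    out = np.zeros((len(CHANNELS), n))
    # EEG channels (C3, C4): independent noise realisations per channel
    for ch in (0, 1):
        for f0, bw, rms in cb.eeg:
            out[ch] += _band_noise(n, rate, f0, bw, rms, rng)
        for _ in range(rng.poisson(cb.spindle_rate)):
            out[ch] += _burst(n, rate, 13.0, 0.8, 25.0, int(rng.integers(0, n)))
        for _ in range(rng.poisson(cb.kcomplex_rate)):
            out[ch] += _biphasic(n, rate, 110.0, int(rng.integers(0, n)))
    # EOG: shared (mirrored) eye-movement component + independent noise
    eye = np.zeros(n)
    for _ in range(rng.poisson(cb.sem_rate)):
        eye += _burst(n, rate, 0.3, 2.5, 45.0, int(rng.integers(0, n)))
    for _ in range(rng.poisson(cb.rem_rate)):
        eye += _burst(n, rate, 1.5, 0.5, 60.0, int(rng.integers(0, n)))
    for ch, sign in ((2, 1.0), (3, -1.0)):
        noise = np.zeros(n)
        for f0, bw, rms in cb.eog:
            noise += _band_noise(n, rate, f0, bw, rms, rng)
        out[ch] = sign * eye + noise
    # chin EMG: broadband tone
    out[4] = _band_noise(n, rate, 35.0, 40.0, cb.emg_rms, rng)
    return np.clip(out, -500.0, 500.0)


# ---------------------------------------------------------------------
# records and datasets
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Study conditions for dataset synthesis.

    ``ambiguity`` is the N1 context-dependence dial lambda in [0, 1];
    at the default 0.8 most of each N1 epoch's spectral content matches
    a neighbouring W or N2 epoch.
    """

    n_records: int = 30
    epochs_per_record: int = 840
    seed: int = 0
    ambiguity: float = 0.8
    signal_rate: float = TARGET_RATE_HZ
    transition: TransitionMatrix = field(default_factory=default_transition_matrix)
    profile: StageSignalProfile = field(default_factory=StageSignalProfile.default)

    def __post_init__(self) -> None:
        if not 0.0 <= self.ambiguity <= 1.0:
            raise ValueError("ambiguity must lie in [0, 1]")
        if self.n_records < 1 or self.epochs_per_record < 1:
            raise ValueError("need at least one record and one epoch")


def _disguise_stage(stages: Sequence[str], i: int, rng: np.random.Generator) -> str:
    """Nearest non-N1 neighbour stage in {W, N2}, else a coin flip."""
    for j in range(i - 1, -1, -1):
        if stages[j] != "N1":
            if stages[j] in ("W", "N2"):
                return stages[j]
            break
    for j in range(i + 1, len(stages)):
        if stages[j] != "N1":
            if stages[j] in ("W", "N2"):
                return stages[j]
            break
    return "W" if rng.random() < 0.5 else "N2"


def simulate_record(
    cfg: SimConfig, record_index: int
) -> tuple[np.ndarray, Hypnogram]:
    """One record's (5, n_samples) signal and hypnogram, seed-derived."""
    rng = np.random.default_rng([cfg.seed, record_index])
    hyp = simulate_hypnogram(cfg.transition, cfg.epochs_per_record, rng)
    n_ep = int(round(30.0 * cfg.signal_rate))
    x = np.empty((len(CHANNELS), cfg.epochs_per_record * n_ep))
    for i, stage in enumerate(hyp.stages):
        bands = None
        if stage == "N1" and cfg.ambiguity > 0:
            d = _disguise_stage(hyp.stages, i, rng)
            bands = _blend(cfg.profile.stages["N1"], cfg.profile.stages[d], cfg.ambiguity)
        x[:, i * n_ep:(i + 1) * n_ep] = simulate_epoch(
            stage, cfg.profile, rng, rate=cfg.signal_rate, bands=bands
        )
    return x, hyp


def simulate_dataset(cfg: SimConfig) -> tuple[EpochedDataset, dict[str, Hypnogram]]:
    """All records of a configuration as an epoch-aligned dataset.

    Signals are synthesised directly at the 125 Hz analysis rate, so
    the returned tensors are (5, 3750) per epoch with no resampling
    step.  Fully deterministic in ``cfg.seed``.
    """
    if cfg.signal_rate != TARGET_RATE_HZ:
        raise ValueError("dataset synthesis runs at the 125 Hz analysis rate")
    records: dict[str, _RecordEpochs] = {}
    hyps: dict[str, Hypnogram] = {}
    n_ep = int(round(30.0 * cfg.signal_rate))
    for r in range(cfg.n_records):
        rid = f"sim{cfg.seed:05d}r{r:03d}"
        x, hyp = simulate_record(cfg, r)
        X = (
            x.reshape(len(CHANNELS), cfg.epochs_per_record, n_ep)
            .transpose(1, 0, 2)
            .astype(np.float32)
        )
        labels = np.array([STAGE_TO_INDEX[s] for s in hyp.stages], dtype=np.int64)
        records[rid] = _RecordEpochs(X=X, labels=labels)
        hyps[rid] = hyp
    return EpochedDataset(records), hyps


def simulate_split(
    cfg: SimConfig, fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
) -> tuple[EpochedDataset, EpochedDataset, EpochedDataset]:
    """Record-level train/validation/test split of one simulation."""
    ds, _ = simulate_dataset(cfg)
    rids = list(ds.records)
    n = len(rids)
    n_val = max(1, int(round(fractions[1] * n)))
    n_test = max(1, int(round(fractions[2] * n)))
    if n_val + n_test >= n:
        raise ValueError(f"{n} records are too few for a three-way split")
    test = rids[:n_test]
    val = rids[n_test:n_test + n_val]
    train = rids[n_test + n_val:]
    pick = lambda ids: EpochedDataset({r: ds.records[r] for r in ids})
    return pick(train), pick(val), pick(test)


def write_record_edf(
    signals: np.ndarray,
    rate: float,
    path: str | Path,
    physical_range_uv: tuple[float, float] = (-1000.0, 1000.0),
) -> None:
    """Export one simulated record's signals as EDF (uV, canonical labels)."""
    write_edf(path, signals, rate, CHANNELS, physical_range_uv=physical_range_uv)


# ---------------------------------------------------------------------
# spectral features (probe utilities)
# ---------------------------------------------------------------------

#: canonical EEG analysis bands, Hz
BANDS = {
    "delta": (0.5, 2.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 12.0),
    "sigma": (12.0, 14.0),
    "beta": (15.0, 30.0),
}


def epoch_bandpowers(epoch: np.ndarray, rate: float = TARGET_RATE_HZ) -> np.ndarray:
    """Log band powers per channel plus EMG RMS: a simple epoch feature.

    Returns a vector of len(CHANNELS) * len(BANDS) + 1 features; used by
    the linear separability probes that quantify how context-dependent
    the simulated N1 epochs are.
    """
    from scipy.signal import welch

    f, p = welch(epoch, fs=rate, nperseg=min(512, epoch.shape[-1]), axis=-1)
    feats = []
    for lo, hi in BANDS.values():
        sel = (f >= lo) & (f < hi)
        feats.append(np.log(p[:, sel].mean(axis=-1) + 1e-12))
    out = np.concatenate(feats)
    return np.append(out, np.sqrt(np.mean(epoch[4] ** 2)))
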