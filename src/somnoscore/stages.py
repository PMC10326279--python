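"""AASM five-class stage vocabulary and fixed orderings shared package-wide."""

STAGES = ("W", "N1", "N2", "N3", "REM")
STAGE_TO_INDEX = {s: i for i, s in enumerate(STAGES)}
UNSCORED = "UNSCORED"
VALID_TOKENS = frozenset(STAGES) | {UNSCORED}

#: canonical channel order: two central EEGs, both EOGs, chin EMG
CHANNELS = ("C3", "C4", "EOGL", "EOGR", "EMG")
EEG_EOG_CHANNELS = ("C3", "C4", "EOGL", "EOGR")

EPOCH_LENGTH_S = 30.0
TARGET_RATE_HZ = 125.0
SAMPLES_PER_EPOCH = 3750  # 30 s x 125 Hz
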