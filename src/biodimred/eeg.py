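"""EEG preprocessing chain for single-trial P300 classification.

The chain, applied in order:

1. re-reference every channel to the average of O1, OZ, O2;
2. low-pass Butterworth filter (default 7th order, 0–9 Hz), applied
   zero-phase (forward–backward) so the P300 latency is not shifted —
   note this doubles the effective filter order;
3. polyphase rational resampling to 128 Hz (2048 -> 128 is a factor 1/16);
4. stimulus-locked epoching into 1 s segments (128 samples at 128 Hz);
5. channel-configuration selection and per-trial concatenation.

The reference channels O1/OZ/O2 and the temporal channels T7/T8 carry no
P300 information and may never appear in a channel configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.signal import butter, resample_poly, sosfiltfilt

from .records import PatternMatrix, SignalRecord
from .synth_eeg import MONTAGE_32

__all__ = [
    "ChannelConfig",
    "preprocess_record",
    "epoch_stimulus_locked",
    "select_and_concatenate",
]

log = logging.getLogger(__name__)

REFERENCE_CHANNELS = ("O1", "OZ", "O2")
EXCLUDED_CHANNELS = REFERENCE_CHANNELS + ("T7", "T8")

# Default configurations.  The 4- and 8-channel sets are a minimal midline
# set and a midline + centro/parieto-occipital set; the 23-channel set is
# every admissible electrode except the blink-prone frontopolar row
# (FP1, FP2, AF3, AF4).  All are overridable via custom configs.
_PRESET_CONFIGS: dict[str, tuple[str, ...]] = {
    "cfg4": ("FZ", "CZ", "PZ", "P4"),
    "cfg8": ("FZ", "CZ", "CP1", "CP2", "P3", "PZ", "P4", "PO3"),
    "cfg23": tuple(
        ch for ch in MONTAGE_32
        if ch not in EXCLUDED_CHANNELS
        and ch not in ("FP1", "FP2", "AF3", "AF4")
    ),
}


@dataclass(frozen=True)
class ChannelConfig:
    """Named, ordered electrode subset used for classification."""

    name: str
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        unknown = [c for c in self.channels if c not in MONTAGE_32]
        if unknown:
            raise ValueError(f"channels not in the 32-electrode montage: {unknown}")
        banned = [c for c in self.channels if c in EXCLUDED_CHANNELS]
        if banned:
            raise ValueError(
                f"reference/temporal channels may not be selected: {banned}"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel configuration contains duplicates")

    @classmethod
    def preset(cls, name: str) -> "ChannelConfig":
        if name not in _PRESET_CONFIGS:
            raise ValueError(
                f"unknown preset {name!r}; available: {sorted(_PRESET_CONFIGS)}"
            )
        return cls(name, _PRESET_CONFIGS[name])

    def __len__(self) -> int:
        return len(self.channels)


def preprocess_record(
    record: SignalRecord,
    order: int = 7,
    cutoff: float = 9.0,
    out_fs: float = 128.0,
) -> SignalRecord:
    """Re-reference, low-pass filter and resample a multichannel record.

    Every channel gets the sample-wise mean of (O1, OZ, O2) subtracted,
    is low-pass filtered with a zero-phase Butterworth filter of the given
    order and cutoff, and is resampled to ``out_fs`` by polyphase rational
    resampling.  Event indices are rescaled by ``out_fs / fs`` with
    rounding to nearest.
    """
    missing = [c for c in REFERENCE_CHANNELS if c not in record.channel_names]
    if missing:
        raise ValueError(f"missing reference channel(s): {missing}")
    if record.fs <= 2 * cutoff:
        raise ValueError(
            f"sampling rate {record.fs} Hz must exceed twice the cutoff {cutoff} Hz"
        )

    ref = np.mean([record.channel(c) for c in REFERENCE_CHANNELS], axis=0)
    data = record.data - ref[np.newaxis, :]

    sos = butter(order, cutoff, btype="low", fs=record.fs, output="sos")
    data = sosfiltfilt(sos, data, axis=1)

    ratio = Fraction(out_fs / record.fs).limit_denominator(10_000)
    data = resample_poly(data, ratio.numerator, ratio.denominator, axis=1)

    scale = out_fs / record.fs
    n_out = data.shape[1]
    events = [
        (min(n_out - 1, int(round(i * scale))), code) for i, code in record.events
    ]
    return SignalRecord(
        data=data,
        fs=out_fs,
        channel_names=list(record.channel_names),
        events=events,
        meta={**record.meta, "preprocessed": True, "filter_order": order,
              "cutoff_hz": cutoff},
    )


def epoch_stimulus_locked(
    record: SignalRecord, duration: float = 1.0
) -> dict[str, PatternMatrix]:
    """Cut one epoch per event per channel, starting at the event sample.

    Returns a mapping channel name -> PatternMatrix whose rows (one per
    surviving event, in event order) are ``duration * fs`` samples and
    whose labels are the event codes.  Events too close to the record end
    are dropped with a log entry.
    """
    if duration <= 0:
        raise ValueError(f"epoch duration must be positive, got {duration}")
    if not record.events:
        raise ValueError("record has no events to epoch around")
    n_len_f = duration * record.fs
    n_len = int(round(n_len_f))
    if abs(n_len_f - n_len) > 1e-9:
        raise ValueError(
            f"duration x fs must be an integer sample count, got {n_len_f}"
        )

    keep, labels = [], []
    for i, code in record.events:
        if i + n_len > record.n_samples:
            log.warning("dropping event at sample %d: too close to record end", i)
            continue
        keep.append(i)
        labels.append(code)
    if not keep:
        raise ValueError("no event leaves room for a full epoch")
    labels_arr = np.asarray(labels, dtype=object)

    idx = np.asarray(keep)[:, np.newaxis] + np.arange(n_len)[np.newaxis, :]
    out = {}
    for ch, name in enumerate(record.channel_names):
        out[name] = PatternMatrix(
            record.data[ch][idx],
            labels_arr.copy(),
            meta={"channel": name, "fs": record.fs, "duration_s": duration},
        )
    return out


def select_and_concatenate(
    epochs: dict[str, PatternMatrix], cfg: ChannelConfig
) -> PatternMatrix:
    """Concatenate per-channel epochs into one feature vector per trial.

    Feature blocks follow ``cfg`` channel order; the output has
    ``len(cfg) * epoch_length`` features per row and preserves labels.
    """
    missing = [c for c in cfg.channels if c not in epochs]
    if missing:
        raise ValueError(f"channels absent from the epoch set: {missing}")
    first = epochs[cfg.channels[0]]
    for c in cfg.channels[1:]:
        if not np.array_equal(
            epochs[c].labels.astype(str), first.labels.astype(str)
        ):
            raise ValueError(f"label track of channel {c!r} disagrees")
    X = np.hstack([epochs[c].X for c in cfg.channels])
    return PatternMatrix(
        X,
        first.labels.copy(),
        meta={
            "kind": "eeg-trials",
            "config": cfg.name,
            "channels": list(cfg.channels),
            "epoch_len": first.n_features,
        },
    )
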