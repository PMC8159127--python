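"""Synthetic stimulus-locked 32-channel EEG with P300-like deflections.

Emulates an oddball/speller recording: stimuli are flashed for
``flash_ms`` with a ``pause_ms`` pause (defaults 100/100 ms, i.e. a 200 ms
stimulus-onset asynchrony); each trial is independently a *target* with
probability ``target_fraction``.  Target trials receive a positive
Gaussian-shaped deflection peaking ``p300_latency`` seconds (default
0.3 s) after stimulus onset, spatially weighted toward centro-parietal
electrodes (maximum weight 1.0 at PZ).

Background activity is a minimal colored-noise model: white noise shaped
to a 1/f-like spectrum plus a 10 Hz sinusoidal (alpha-band) component with
a random phase per channel.  Both survive a 0–9 Hz low-pass nontrivially.

Stimulus onsets and per-trial labels ("target"/"nontarget") are stored in
``SignalRecord.events``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import rng_from
from .records import SignalRecord

__all__ = ["MONTAGE_32", "P300Config", "generate_p300_record"]

#: the 32-electrode montage, in recording order
MONTAGE_32 = [
    "FP1", "FP2", "AF3", "AF4", "F7", "F3", "FZ", "F4", "F8",
    "FC1", "FC5", "FC6", "FC2", "T7", "C3", "CZ", "C4", "T8",
    "CP1", "CP5", "CP6", "CP2", "P7", "P3", "PZ", "P4", "P8",
    "PO3", "PO4", "O1", "OZ", "O2",
]

#: spatial weighting of the P300 deflection (unlisted channels get 0)
P300_TOPOGRAPHY = {
    "PZ": 1.0, "CP1": 0.9, "CP2": 0.9, "CZ": 0.8,
    "P3": 0.7, "P4": 0.7, "PO3": 0.6, "PO4": 0.6,
    "CP5": 0.5, "CP6": 0.5, "C3": 0.4, "C4": 0.4,
    "P7": 0.3, "P8": 0.3, "FZ": 0.2,
}

_EPOCH_S = 1.0  # nominal trial duration (s)


@dataclass
class P300Config:
    """Parameters of the synthetic oddball recording.

    noise_model keys: ``sd`` (µV, total background SD), ``slope``
    (spectral exponent of the 1/f-like component), ``alpha_amplitude``
    (µV) and ``alpha_freq`` (Hz).
    """

    n_trials: int = 120
    target_fraction: float = 1.0 / 6.0
    p300_amplitude: float = 5.0     # µV at the PZ peak
    p300_latency: float = 0.3       # s after stimulus onset
    p300_width: float = 0.08        # Gaussian sigma, s
    flash_ms: float = 100.0
    pause_ms: float = 100.0
    noise_model: dict = field(default_factory=lambda: {
        "sd": 4.0, "slope": 1.0, "alpha_amplitude": 2.0, "alpha_freq": 10.0,
    })
    fs: float = 2048.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_fraction < 1.0:
            raise ValueError(
                f"target_fraction must lie in (0, 1), got {self.target_fraction}"
            )
        if not self.p300_latency < _EPOCH_S:
            raise ValueError("p300_latency must be shorter than the 1 s epoch")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


def _one_over_f_noise(rng: np.random.Generator, n: int, slope: float,
                      sd: float) -> np.ndarray:
    """White Gaussian noise spectrally shaped to ~1/f**slope power."""
    white = rng.standard_normal(n)
    if slope <= 0 or sd <= 0:
        return sd * white
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]  # keep DC finite
    spec *= f ** (-slope / 2.0)
    x = np.fft.irfft(spec, n)
    x *= sd / x.std()
    return x


def generate_p300_record(cfg: P300Config) -> SignalRecord:
    """Generate the 32-channel stimulus-locked record described by ``cfg``.

    Deterministic given ``cfg.seed``.  ``meta`` records the realized
    target/non-target counts of the binomial label draw.
    """
    rng = rng_from(cfg.seed)
    fs = cfg.fs
    soa = (cfg.flash_ms + cfg.pause_ms) / 1000.0
    onsets = (0.5 + soa * np.arange(cfg.n_trials))
    onset_samples = np.round(onsets * fs).astype(int)
    n = int(onset_samples[-1] + round((_EPOCH_S + 0.2) * fs))

    is_target = rng.random(cfg.n_trials) < cfg.target_fraction
    t = np.arange(n) / fs

    nm = cfg.noise_model
    data = np.empty((len(MONTAGE_32), n))
    # P300 kernel, shared across channels up to the topography weight
    kernel_len = int(round(_EPOCH_S * fs))
    kt = np.arange(kernel_len) / fs
    kernel = np.exp(-((kt - cfg.p300_latency) ** 2) / (2 * cfg.p300_width ** 2))

    p300_track = np.zeros(n)
    for s, tgt in zip(onset_samples, is_target):
        if tgt:
            hi = min(n, s + kernel_len)
            p300_track[s:hi] += kernel[: hi - s]

    for ch, name in enumerate(MONTAGE_32):
        x = _one_over_f_noise(rng, n, nm.get("slope", 1.0), nm.get("sd", 0.0))
        alpha_amp = nm.get("alpha_amplitude", 0.0)
        if alpha_amp > 0:
            x = x + alpha_amp * np.sin(
                2 * np.pi * nm.get("alpha_freq", 10.0) * t
                + rng.uniform(0, 2 * np.pi)
            )
        weight = P300_TOPOGRAPHY.get(name, 0.0)
        if weight > 0 and cfg.p300_amplitude != 0:
            x = x + weight * cfg.p300_amplitude * p300_track
        data[ch] = x

    events = [
        (int(s), "target" if tgt else "nontarget")
        for s, tgt in zip(onset_samples, is_target)
    ]
    return SignalRecord(
        data=data,
        fs=fs,
        channel_names=list(MONTAGE_32),
        events=events,
        meta={
            "kind": "synthetic-p300",
            "n_trials": cfg.n_trials,
            "n_targets": int(is_target.sum()),
            "n_nontargets": int((~is_target).sum()),
            "target_fraction": cfg.target_fraction,
            "p300_amplitude": cfg.p300_amplitude,
            "p300_latency": cfg.p300_latency,
            "seed": int(cfg.seed),
        },
    )
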