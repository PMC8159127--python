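"""Synthetic single-lead ECG generator with eight beat-morphology classes.

The generator emulates the statistical structure of an annotated arrhythmia
Holter recording: a 360 Hz single-lead trace containing beats of eight
classes — normal (N), atrial premature (A), left and right bundle branch
block (L, R), premature ventricular contraction (V), fusion of ventricular
and normal (F), paced ("/") and fusion of paced and normal (f).

Each beat is a sum of five Gaussian components standing in for the P, Q, R,
S and T waves; class identity is expressed as documented parameter deltas
(widened QRS for V/L/"/", a narrow pacing spike for "/" and "f", attenuated
P and a shortened preceding RR for A, discordant T for bundle-branch
blocks).  This keeps beats smooth, fully controllable and free of external
template files.  Controllable degradations: additive white noise, RR
jitter, per-beat amplitude/width jitter and sinusoidal baseline wander.

Ground-truth R positions (one event per beat, coded with the beat class)
are always carried in ``SignalRecord.events`` so downstream detection and
segmentation can be scored against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import child_seeds, rng_from
from .records import PatternMatrix, SignalRecord

__all__ = [
    "BeatTemplate",
    "DEFAULT_TEMPLATES",
    "BEAT_CLASSES",
    "generate_ecg_record",
    "make_ecg_pattern_set",
]

#: canonical class order (seven pathological classes + normal)
BEAT_CLASSES = ("N", "A", "L", "R", "V", "F", "/", "f")

#: accepted aliases for the paced-beat label
_ALIASES = {"paced": "/", "P": "/"}


@dataclass(frozen=True)
class BeatTemplate:
    """One beat morphology: five Gaussian components P, Q, R, S, T.

    ``wave_params`` holds ``(amplitude_mV, center_s, width_s)`` triples with
    centers relative to the R peak at 0.  ``rr_scale`` is the relative
    length of the RR interval *preceding* the beat (premature beats < 1).
    """

    class_label: str
    wave_params: tuple[tuple[float, float, float], ...]
    rr_scale: float = 1.0

    def __post_init__(self) -> None:
        amps = [abs(a) for a, _, _ in self.wave_params]
        if any(w <= 0 for _, _, w in self.wave_params):
            raise ValueError(f"{self.class_label}: component widths must be > 0")
        r = abs(self.r_amplitude)
        if any(a >= r for i, a in enumerate(amps) if i != self._r_index):
            raise ValueError(
                f"{self.class_label}: R component must have strictly the "
                "largest absolute amplitude"
            )

    @property
    def _r_index(self) -> int:
        amps = [abs(a) for a, _, _ in self.wave_params]
        return int(np.argmax(amps))

    @property
    def r_amplitude(self) -> float:
        """Signed amplitude of the dominant (R) component."""
        return self.wave_params[self._r_index][0]

    def waveform(self, t: np.ndarray, amp_scale: float = 1.0,
                 width_scale: float = 1.0) -> np.ndarray:
        """Evaluate the beat on time axis ``t`` (seconds, R at t=0)."""
        y = np.zeros_like(t)
        for a, c, w in self.wave_params:
            w = w * width_scale
            y += a * amp_scale * np.exp(-((t - c) ** 2) / (2.0 * w * w))
        return y


# Morphology registry.  Amplitudes in mV, times in seconds.  Components are
# in P, Q, R, S, T order; for paced beats the P slot carries the narrow
# pacing spike.  Values are stylized textbook morphologies, not fits to any
# recording.
DEFAULT_TEMPLATES: dict[str, BeatTemplate] = {
    "N": BeatTemplate("N", (
        (0.15, -0.22, 0.030), (-0.12, -0.045, 0.012), (1.20, 0.0, 0.014),
        (-0.28, 0.040, 0.013), (0.38, 0.26, 0.070)), rr_scale=1.0),
    # atrial premature: ectopic low P, shortened preceding RR
    "A": BeatTemplate("A", (
        (0.05, -0.16, 0.020), (-0.10, -0.045, 0.012), (1.15, 0.0, 0.014),
        (-0.25, 0.040, 0.013), (0.33, 0.24, 0.065)), rr_scale=0.72),
    # LBBB: broad R, slurred S, discordant (negative) T
    "L": BeatTemplate("L", (
        (0.14, -0.24, 0.030), (-0.05, -0.075, 0.020), (1.10, 0.0, 0.032),
        (-0.20, 0.090, 0.030), (-0.45, 0.30, 0.090)), rr_scale=1.0),
    # RBBB: deep wide S, inverted T
    "R": BeatTemplate("R", (
        (0.14, -0.22, 0.030), (-0.10, -0.050, 0.012), (1.05, 0.0, 0.014),
        (-0.55, 0.060, 0.025), (-0.30, 0.27, 0.080)), rr_scale=1.0),
    # PVC: no P, wide bizarre QRS, large discordant T, premature
    "V": BeatTemplate("V", (
        (0.0, -0.20, 0.030), (-0.30, -0.060, 0.035), (1.35, 0.0, 0.045),
        (-0.40, 0.080, 0.040), (-0.50, 0.30, 0.080)), rr_scale=0.85),
    # fusion of ventricular and normal: intermediate morphology
    "F": BeatTemplate("F", (
        (0.07, -0.21, 0.030), (-0.20, -0.050, 0.020), (1.25, 0.0, 0.030),
        (-0.33, 0.060, 0.025), (-0.10, 0.29, 0.080)), rr_scale=0.95),
    # paced: pacing spike then wide ventricular complex
    "/": BeatTemplate("/", (
        (0.45, -0.090, 0.005), (-0.15, -0.050, 0.020), (1.15, 0.0, 0.030),
        (-0.35, 0.090, 0.030), (-0.40, 0.30, 0.090)), rr_scale=1.0),
    # fusion of paced and normal: attenuated spike, narrower complex
    "f": BeatTemplate("f", (
        (0.35, -0.090, 0.005), (-0.13, -0.048, 0.016), (1.18, 0.0, 0.026),
        (-0.30, 0.050, 0.020), (0.10, 0.28, 0.080)), rr_scale=1.0),
}

#: window (s) around each R within which a beat's components are evaluated
_BEAT_SUPPORT = 0.6


def _template(label: str) -> BeatTemplate:
    label = _ALIASES.get(label, label)
    if label not in DEFAULT_TEMPLATES:
        raise ValueError(
            f"unknown beat class label {label!r}; known: "
            + ", ".join(DEFAULT_TEMPLATES)
        )
    return DEFAULT_TEMPLATES[label]


def generate_ecg_record(
    classes: list[str] | tuple[str, ...],
    fs: float = 360.0,
    rr_mean: float = 0.8,
    rr_jitter: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    amp_jitter: float = 0.0,
    baseline_mv: float = 0.0,
) -> SignalRecord:
    """Generate a single-lead ECG with one beat per requested class label.

    Parameters
    ----------
    classes:
        Beat class label per beat, in temporal order.
    fs:
        Sampling rate (Hz); must resolve the narrowest template component.
    rr_mean:
        Mean RR interval (s); each beat's preceding interval is
        ``rr_mean * template.rr_scale`` plus Gaussian jitter.
    rr_jitter:
        Standard deviation (s) of RR jitter.
    noise_sd:
        Standard deviation (mV) of additive white measurement noise.
    seed:
        Integer seed; the record is a pure function of all arguments.
    amp_jitter:
        Relative SD of a per-beat amplitude scale and (half of it) a
        per-beat width scale — beat-to-beat morphology variability.
    baseline_mv:
        Amplitude (mV) of a 0.33 Hz sinusoidal baseline wander.

    Returns
    -------
    SignalRecord
        One channel ``MLII``; ``events`` holds the ground-truth R sample
        index and class code of every beat.
    """
    if len(classes) == 0:
        raise ValueError("classes must be non-empty")
    templates = [_template(c) for c in classes]
    min_width = min(w for tpl in templates for _, _, w in tpl.wave_params)
    if fs < 1.0 / min_width:
        raise ValueError(
            f"fs={fs} Hz cannot resolve template components of width "
            f"{min_width} s (need >= {1.0 / min_width:.0f} Hz)"
        )
    rng = rng_from(seed)

    # R positions: record starts mid-RR, each interval scaled by the class
    # of the beat it precedes.
    r_samples: list[int] = []
    t_r = 0.5 * rr_mean
    for i, tpl in enumerate(templates):
        if i > 0:
            rr = rr_mean * tpl.rr_scale + rng.normal(0.0, rr_jitter)
            rr = max(rr, 0.25 * rr_mean)
            t_r = t_r + rr
        r_samples.append(int(round(t_r * fs)))

    n = r_samples[-1] + int(round(0.6 * rr_mean * fs)) + 1
    x = np.zeros(n)
    t = np.arange(n) / fs
    amp_scales = 1.0 + amp_jitter * rng.standard_normal(len(templates))
    width_scales = 1.0 + 0.5 * amp_jitter * rng.standard_normal(len(templates))
    amp_scales = np.clip(amp_scales, 0.3, 2.0)
    width_scales = np.clip(width_scales, 0.5, 1.6)
    for tpl, r, a_s, w_s in zip(templates, r_samples, amp_scales, width_scales):
        lo = max(0, r - int(_BEAT_SUPPORT * fs))
        hi = min(n, r + int(_BEAT_SUPPORT * fs) + 1)
        x[lo:hi] += tpl.waveform(t[lo:hi] - r / fs, a_s, w_s)
    if baseline_mv > 0:
        x += baseline_mv * np.sin(2 * np.pi * 0.33 * t + rng.uniform(0, 2 * np.pi))
    if noise_sd > 0:
        x += rng.normal(0.0, noise_sd, n)

    events = [(r, _ALIASES.get(c, c)) for r, c in zip(r_samples, classes)]
    return SignalRecord(
        data=x[np.newaxis, :],
        fs=fs,
        channel_names=["MLII"],
        events=events,
        meta={
            "kind": "synthetic-ecg",
            "rr_mean": rr_mean,
            "rr_jitter": rr_jitter,
            "noise_sd": noise_sd,
            "amp_jitter": amp_jitter,
            "baseline_mv": baseline_mv,
            "seed": int(seed),
        },
    )


# Defaults below are the study conditions for every synthetic-ECG
# experiment in this package: enough beat-to-beat variability and noise
# that the eight classes are distinguishable but genuinely intertwined.
ECG_SET_DEFAULTS = dict(
    fs=360.0,
    rr_mean=0.8,
    rr_jitter=0.05,
    noise_sd=0.08,
    amp_jitter=0.10,
    baseline_mv=0.05,
)


def make_ecg_pattern_set(
    per_class: int,
    seed: int = 0,
    *,
    segmentation_spec=None,
    **generator_overrides,
) -> PatternMatrix:
    """Build a balanced R-centered heartbeat pattern set.

    Generates one synthetic record per class (with ``per_class + 4`` beats
    to allow for the discarded boundary half-cycles), runs R-peak detection
    and R-centered segmentation from :mod:`biodimred.segmentation`, keeps
    the first ``per_class`` cycles of each class and shuffles the pooled
    rows deterministically by ``seed``.

    Returns
    -------
    PatternMatrix
        ``8 * per_class`` rows of ``target_len`` (default 301) samples.
    """
    from .segmentation import SegmentationSpec, detect_r_peaks, segment_r_centered

    if per_class < 1:
        raise ValueError("per_class must be >= 1")
    spec = segmentation_spec or SegmentationSpec()
    params = {**ECG_SET_DEFAULTS, **generator_overrides}
    seeds = child_seeds(seed, len(BEAT_CLASSES) + 1)

    blocks, labels = [], []
    for cls, cls_seed in zip(BEAT_CLASSES, seeds):
        record = generate_ecg_record(
            [cls] * (per_class + 4), seed=cls_seed, **params
        )
        peaks = detect_r_peaks(record, spec)
        patterns = segment_r_centered(record, peaks, spec)
        if patterns.n_patterns < per_class:
            raise ValueError(
                f"class {cls!r}: only {patterns.n_patterns} usable beats "
                f"segmented, {per_class} requested"
            )
        blocks.append(patterns.X[:per_class])
        labels.extend([cls] * per_class)

    X = np.vstack(blocks)
    labels_arr = np.asarray(labels, dtype=object)
    order = rng_from(seeds[-1]).permutation(X.shape[0])
    return PatternMatrix(
        X[order],
        labels_arr[order],
        meta={"kind": "ecg-patterns", "per_class": per_class, "seed": int(seed),
              **params},
    )
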