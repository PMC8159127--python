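# Methods

This note documents the models, parameter choices and numerical details
behind `biodimred`, and what its synthetic benchmarks do and do not show.

## Synthetic ECG

Each beat is the sum of five Gaussian components standing for the P, Q,
R, S and T waves; a beat class is a fixed parameter set
(amplitude mV, center s relative to R, width s).  The eight classes —
normal (N), atrial premature (A), left/right bundle branch block (L, R),
premature ventricular contraction (V), ventricular-normal fusion (F),
paced (`/`) and paced-normal fusion (f) — differ by documented deltas:
widened QRS for V/L/`/`, a narrow ~5 ms pacing spike for `/` and `f`,
attenuated P and a shortened preceding RR (factor 0.72) for A, deep wide
S for R, discordant (negative) T for the wide-QRS classes.  Component
parameters are stylized textbook morphologies balanced so that the summed
waveform attains its absolute maximum exactly on the R-component sample
at 360 Hz — the generator's ground-truth events are therefore exact
targets for the detector.

A record is assembled beat by beat: the RR interval preceding beat *i* is
`rr_mean * rr_scale(class_i) + N(0, rr_jitter²)`, clipped below at
`0.25 rr_mean`; the record starts and ends mid-interval.  Controllable
degradations, all off by default in `generate_ecg_record` and enabled at
the documented study conditions by `make_ecg_pattern_set`:

| parameter | default (pattern sets) | meaning |
|---|---|---|
| `noise_sd` | 0.08 mV | additive white measurement noise |
| `rr_jitter` | 0.05 s | RR-interval variability |
| `amp_jitter` | 0.10 | per-beat amplitude scale SD (half of it as width scale SD) |
| `baseline_mv` | 0.05 mV | 0.33 Hz sinusoidal baseline wander |

These values were fixed once, as what a desk-scale emulation of annotated
Holter data plausibly looks like: classes clearly learnable in the full
301-sample space yet overlapping enough in low-dimensional projections
that reduction methods can be meaningfully ranked.  What the generator
does *not* model: phase-oscillator ECG dynamics, electrode artifacts,
ectopic timing patterns, inter-patient variability.  Passing benchmarks
here demonstrate correct algorithmic behavior and the direction of the
qualitative trends, not clinical performance.

## Heartbeat segmentation

Detection: the rectified signal is smoothed with a ~30 ms moving average
(suppressing noise-induced local maxima on T-wave tails), thresholded at
0.5 × a rolling 95th percentile of the smoothed amplitude (~2 s blocks; a
short trailing block is folded into its predecessor so a baseline-only
tail cannot collapse the threshold), and peaks at least `min_rr = 0.4 s`
apart are kept, each refined to the raw-amplitude argmax of its
neighborhood.  On noiseless input the refinement makes detection exact.

Segmentation: cycle *i* spans midpoint(R[i−1], R[i]) → midpoint(R[i],
R[i+1]); the first and last half-cycles have no midpoint and are
discarded, so n peaks yield n−2 cycles.  Each half-cycle is resampled by
linear interpolation over a uniform grid — the pre-R part to 150 samples
ending at the untouched R sample, the post-R part to 151 samples — giving
301-sample cycles with R on the 150-th 1-based sample (array index 149;
all reports use 1-based positions).  Linear interpolation is chosen for
exactness at the anchors and easy testability.  Row labels come from the
nearest ground-truth/annotation event within half a refractory period.

## EEG chain

The synthetic oddball recording flashes stimuli at a 200 ms onset
asynchrony (100 ms flash + 100 ms pause); each trial is a target with
probability 1/6.  Targets add a Gaussian bump (σ = 80 ms) peaking 300 ms
after onset, weighted by a fixed centro-parietal topography (maximum 1.0
at PZ).  Background noise is white noise shaped to a 1/f spectrum
(4 µV SD) plus a 10 Hz sinusoid (2 µV) with per-channel random phase —
the minimal colored-noise model that survives the 0–9 Hz low-pass
nontrivially.  No eye-blink/EMG artifacts are simulated (artifact
rejection is out of scope).

Preprocessing subtracts the O1/OZ/O2 average, low-pass filters with a
7th-order Butterworth at 9 Hz applied forward–backward (zero phase, so
the P300 latency is not shifted; the effective magnitude order doubles),
and resamples 2048 → 128 Hz by polyphase rational resampling.  Epochs are
1 s (128 samples) from each stimulus onset.  Channel configurations:
`cfg4` = {FZ, CZ, PZ, P4}; `cfg8` = {FZ, CZ, CP1, CP2, P3, PZ, P4, PO3}
(midline + centro-parieto-occipital, where the simulated P300 lives);
`cfg23` = all montage channels except the references, T7/T8 and the
blink-prone frontopolar row (FP1, FP2, AF3, AF4).  All are overridable;
the 23-channel membership in particular is a configuration choice, since
only its size is canonical.

## Dimensionality reduction

**Graph.** Symmetrized k-nearest-neighbor rule (edge if either endpoint
lists the other; ties at the k-th distance are all included, so
coincident points always share neighborhoods), or an ε-ball on squared
distances.  Weights `w_ij = exp(-||x_i−x_j||²/2σ²)`; `σ = "auto"` takes
the median distance over connected pairs.  Defaults `k = 10`,
`σ = auto` — neither is canonical, both are exposed.  A disconnected
graph is an error by default; `on_disconnected="largest"` embeds the
giant component and records dropped nodes.

**Laplacian eigenmaps.** `L f = λ D f` is solved via the symmetric
reduction `D^{-1/2} L D^{-1/2}` (dense LAPACK up to 1200 nodes, then
shift-invert Lanczos).  The constant eigenvector at λ = 0 is discarded; a
numerically repeated zero eigenvalue is reported as disconnection.
Coordinates are D-orthonormal; each eigenvector's sign is fixed by making
its largest-absolute entry positive, so repeated runs produce identical
tables.  Out-of-sample points are embedded transductively (train and test
jointly, test labels never consulted); a Nyström extension is explicitly
out of scope.

**LPP.** `X L Xᵀ a = λ (X D Xᵀ + ridge·I) a`, smallest-λ directions
first, default ridge `1e-8 · tr(X D Xᵀ)/p`.  The problem is solved in a
principal subspace of the training patterns retaining 98% of their
squared norm and mapped back (`energy=1.0` disables the truncation).
This is the customary LPP preprocessing and it matters: in the raw
p > n regime the smallest-eigenvalue directions chase noise and the
projection collapses to chance-level class information.  Requesting more
directions than the retained rank is an error naming the rank.

**CS.** `y = Φx`, with Φ drawn once per seed — i.i.d. Gaussian scaled by
`1/√M` (so `E‖Φx‖² = ‖x‖²`) or symmetric Bernoulli `±1/√M`.  The same Φ
is applied to any later test rows; equal seeds give bit-identical Φ.

## Classifier harness

The 24 presets follow the familiar GUI tiers their names imply: trees
with 100/20/4 splits; k-NN with k = 1/10/100 plus cosine, cubic
(Minkowski p=3) and distance-weighted variants (large k is clipped to the
training size); SVMs linear/quadratic/cubic (coef0 = 1, one-vs-one
multiclass) and Gaussian with kernel scale `√p/4`, `√p`, `4√p`
(γ = 1/scale²); ensembles of 30 learners — AdaBoost and random-forest
bagging over medium trees, random-subspace LDA and 1-NN on half the
features, and RUSBoost (per-round undersampling of every class to the
minority count, weighted sampling by the boosting weights, SAMME
reweighting).  Three estimators are implemented in-package because no
installed library provides them: kernel (per-feature Gaussian-KDE) naive
Bayes with Silverman bandwidths, RUSBoost, and a ridge-shrunk quadratic
discriminant (`S_c + 0.1·tr(S_c)/p·I`) that stays defined when a class
has fewer members than features.  Features are not standardized — the
Gaussian kernel-scale formulas operate on raw sample amplitudes.

Protocol: stratified 5-fold cross-validation by default, the common
default of the GUI tool family these presets mirror; the original study
protocol is not documented, so this is a package decision and is recorded
in every report row.  All variants and all representations share one fold
assignment (paired comparisons); reduction is fitted per fold on training
rows only, LE transductively.  Inside the grid, a disconnected graph is
handled by doubling k until connected — a fold-level failure would
otherwise abort the whole benchmark; the dimred API itself keeps the
error-by-default contract.  Accuracy is percent correct pooled over
held-out predictions; per-class recalls (which average, weighted, to the
accuracy) are serialized alongside.

## Problem sizes

The shipped benchmarks run at desk scale, chosen so the full suite and
the acceptance script each complete in minutes on one CPU: 60 beats per
class (480 patterns of 301 samples) across 5 seeds for the ECG trend
study, 300 trials for the EEG benchmark, a 12-variant classifier subset
spanning every family for the trend comparisons.  At this scale the
observed pattern mirrors the full-size study qualitatively — spectral
embedding dominates at 2–3 dimensions, random projections catch up to
within a few points of the original space above ~10 dimensions, and
linear LPP sits between — but absolute accuracies are not comparable to
results on real recordings.

## Known limitations

* LE quality degrades when class clusters are so well separated that the
  k-NN graph fragments; the harness's k-doubling fallback then coarsens
  the graph toward completeness.
* The heat-kernel weight underflows for inter-cluster distances many σ
  apart; numerically this is indistinguishable from disconnection and is
  reported as such.
* The kernel-density naive Bayes is O(n_train · n_test · p) per class and
  is the slowest preset on the 301-sample patterns.
* The P300 generator treats trials as independent; real oddball
  experiments have sequential structure (refractory P300 amplitude,
  blocked flash patterns) that is not modeled.
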