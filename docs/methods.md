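# Methods

This note documents the models, conventions, and numerical choices behind
`nirsbci`, in the order the data flows.

## Signal model and units

A recording is a continuous series of optical-density changes ΔOD at
wavelengths (780, 805, 830) nm over 16 prefrontal channels, or — after
conversion — hemoglobin concentration changes (ΔHbO, ΔHbR) in mM·cm.
The modified Beer–Lambert law is a fixed linear map (coefficients in
`preprocess.MBLL_MATRIX`); its rows produce (ΔHbR, ΔHbO) while the package
stores chromophores in the order (HbO, HbR) everywhere. The matrix is
wide (2×3), so it has a family of right inverses; the synthetic OD fixture
uses the minimum-norm right inverse, which makes
`mbll_convert(make_od_fixture(x)) == x` to numerical precision.

For SNIRF files carrying raw continuous-wave intensity, ΔOD is defined as
`−log10(I / mean(I))` per channel, the standard convention; any fixed
reference intensity only shifts ΔOD by a constant that the band-pass
filter removes.

## Sampling rate and the epoch grid

The nominal device rate "13.3 Hz" is stored as exactly 40/3 Hz: a [0, 15] s
epoch *inclusive of both endpoints* then contains exactly
`round(15·40/3) + 1 = 201` samples, which is the input length the CNN
architecture is built around. Baseline correction subtracts the mean over
samples in [−1, 0) s — 13 samples at this rate; the onset sample belongs to
the epoch, not the baseline, so no sample is counted twice.

## Filtering

Band-pass 0.01–0.09 Hz, Butterworth of design order 6, applied
forward–backward (`scipy.signal.sosfiltfilt`): zero phase and an effective
magnitude response equal to the squared design response (~order 12). The
0.09 Hz upper edge excludes Mayer waves (~0.1 Hz), respiration (~0.25 Hz)
and cardiac pulsation (~1 Hz); the 0.01 Hz lower edge removes drift.
Attenuation at 1 Hz exceeds 40 dB analytically
(`preprocess.bandpass_response_db` evaluates the doubled response, and
tests measure it in the time domain by projecting onto the probe tone,
which keeps slow filtfilt edge transients out of the measurement).
Recordings shorter than three pad lengths are rejected rather than
filtered badly.

A note on response-energy retention: a *single* isolated task response
(10 s boxcar convolved with the HRF) carries roughly a quarter of its
energy below 0.01 Hz — that component is irretrievable through any
high-pass at that edge and is equally removed by per-epoch baseline
correction. Measured against the demeaned template, the filter retains
~94% of the energy (a periodic trial train retains ~91%), which is the
sense in which the response "fits inside the band".

## Feature extraction and the linear decoders

Features are temporal means per channel, chromophore, and window
(0–5, 5–10, 10–15 s), ordered window-major → chromophore (HbO block, HbR
block) → channel: 96 features for the 16-channel montage. Window samples
come from [a, b) seconds; the final window also takes the last epoch
sample so the three windows tile the epoch exactly.

Shrinkage LDA regularizes the pooled within-class covariance (population
divisor n, a fixed convention so tests can be exact) toward `ν·I` with ν
the average diagonal: `Σ̃ = (1−γ)Σ̂ + γνI`, `w = Σ̃⁻¹(μ₁−μ₀)`,
`b = −wᵀ(μ₁+μ₀)/2`. With `shrinkage="analytic"` the intensity is the
Ledoit–Wolf estimate (via scikit-learn) clipped to [0, 1]; a fixed γ is
also accepted, and γ = 0.1 is the regularized-LDA setting used inside the
ensemble. Class encoding is fixed package-wide as IS = 0, MA = 1; the
decision rule is `sign(wᵀx + b)` with exact zeros resolved to IS and
counted in the model diagnostics.

The bagging ensemble trains 50 such learners on with-replacement resamples
of the full training-set size; a resample missing a class (or with fewer
than two samples of one class) is redrawn and the redraw counted. The vote
is majority; a 25–25 tie breaks by the sign of the mean decision score —
deterministic and using the available information. All resampling comes
from one seeded generator, so ensembles are bit-reproducible.

## Neural decoders

Both networks run on the package's own NumPy layer framework (`_nn.py`):
forward passes and analytic backward passes for every layer, verified
against central finite differences in the test suite, with the Adamax
optimizer. Activations are computed in float32 for speed; all randomness
(initialization, dropout, shuffling, splits) flows from explicit seeds, so
training is bit-reproducible on a given platform.

**Temporal EvoNorm CNN.** Input (201, 32) — time × (16 HbO + 16 HbR
channels, channel-major). Graph: EvoNorm → dropout 0.5 → conv(32 filters,
kernel 13, stride 9, valid) → EvoNorm → dropout → conv(32, 6, 4, valid) →
EvoNorm → dropout → flatten(128) → dense(2, softmax). He-Normal
initialization. The parameter count (20 066) is asserted in tests to
freeze the architecture against drift.

*EvoNorm variant.* The S0 (sample-based) variant is used:
`y = x·σ(v∘x)/group_std(x) · γ + β`, with the group standard deviation
taken per sample over time and the channels of each group (8 groups over
32 channels; the group count must divide the channel count). S0 is
batch-size independent, hence identical in training and inference and
robust to the small-dataset regime; the published alternative (B0) depends
on batch statistics. The 1D adaptation treats time as the spatial axis.
With v = 0, γ = 1, β = 0 and one group the transform reduces to
`0.5·x/std(x)`, which the tests assert. An ablation flag
(`ProposedCnnConfig(normalization="batchnorm_relu")`) swaps every EvoNorm
for BatchNorm + ReLU; both variants build and train.

**EEGNet.** Input (32, 201, 1) — measurement channels × time. Temporal
'same' convolution (kernel (1, 6), half the sampling rate; F1 = 8) →
BatchNorm → depthwise convolution spanning all 32 rows (depth 2, unit
max-norm per filter, bias-free as in the original formulation) →
BatchNorm → ELU → average pool (1, 4) → dropout 0.25 → separable
convolution (kernel (1, 2) along time, F2 = 16) → BatchNorm → ELU →
average pool (1, 8) → dropout → flatten(96) → dense(2, softmax). The
separable kernel is oriented along the time axis — the only orientation
under which the published shape arithmetic (201 → 50 → 6, flatten 96)
works. No max-norm is applied to the dense layer. Glorot initialization,
Keras-convention BatchNorm (momentum 0.99, ε = 10⁻³).

**Training recipe (both networks).** Adamax, learning rate 5·10⁻⁴ with
legacy per-update decay `lr/(1 + 5·10⁻⁸·t)`, batch size 100 (a smaller
dataset trains as one batch, logged, not an error), categorical
cross-entropy on z-scored epochs (per trial and channel over time,
population standard deviation, ε-guard mapping constant channels to
zeros; double normalization is a contract error). A stratified random 10%
of the training trials forms the validation set (seeded; a random rather
than tail split, because trials are time-ordered and a tail split would
confound with session fatigue). Early stopping monitors validation loss
with patience 20 and restores the best weights. `max_epochs` (default
500) is an explicit cap; the evaluation harnesses in the examples and
acceptance tests use 80–200 epochs, matched to their problem sizes.

## Evaluation

LOSO cross-validation trains on all subjects but one and tests on the
holdout, one fold per subject; per-subject accuracy is the primary
aggregate (mean ± SD over subjects), with the pooled confusion matrix kept
for consistency checks. Everything fold-specific — feature fitting,
normalization, validation splitting — happens inside the fold on training
subjects only; a SHA-1 fingerprint audit of trial tensors asserts that no
test trial enters training. With 18 subjects × 60 trials this yields the
1020-train/60-test folds of the full design.

The pseudo-online simulation takes, per subject and per class, the
chronologically first N trials for training and the remaining 30 − N for
testing, using shrinkage LDA and no other subject's data; N = 12 therefore
means 24 training and 36 test trials per subject.

The Wilcoxon signed-rank test drops zero differences, mid-ranks ties, and
computes the exact two-sided p by full enumeration of the sign-assignment
distribution (dynamic programming over doubled ranks) for n ≤ 25 — an
18-subject comparison is always exact — falling back to the normal
approximation with continuity and tie corrections above.

## Synthetic data generator

The generator emulates the statistical structure of the block paradigm,
not its optics. Per trial: 2 s instruction, 10 s task (event marker at
task onset), 16–18 s uniform rest; 30 MA + 30 IS trials in seeded random
order; 20 s pre/post-roll so every epoch fits. The MA response is a 10 s
boxcar convolved with a canonical double-gamma HRF (modes at 6 s and 16 s,
undershoot ratio 1/6; gamma shape a = mode + 1 at unit rate), peak-
normalized, scaled by the effect amplitude, a per-subject log-normal gain
(σ = 0.4), and a per-channel spatial weight (smooth medial-frontal bump
plus per-subject Gaussian jitter, clipped to [0, 1]). ΔHbR mirrors ΔHbO
at −1/3 amplitude — the anti-correlation is qualitative physiology; the
ratio is a configuration knob, not a claim. IS trials evoke nothing.

Noise per channel and chromophore: sinusoids near 0.1 Hz (Mayer),
0.25 Hz (respiration), 1.1 Hz (cardiac) with random phase and 10% relative
frequency jitter; a 1/f-amplitude-spectrum drift; white noise. Default
amplitudes (0.03/0.015/0.01 mM·cm, drift sd 0.03, white sd 0.01) are
plausible for prefrontal recordings in these units.

**Default effect size.** The peak MA amplitude defaults to 0.0035 mM·cm, a
one-time calibration chosen so that shrinkage LDA under LOSO at the full
18 × 60 scale operates near 68% — the realistic 60–75% regime for
subject-independent prefrontal fNIRS decoding. This is a convenience
calibration of the simulator, not a reproduction of any measured dataset.

**What passing tests do and do not show.** The generator has linear,
stationary, Gaussian-ish noise, no motion artifacts, no coupling between
channels beyond the shared response, and inter-subject variability reduced
to gain and topography jitter. Pipeline tests on it validate the
*machinery* (conversion, filtering, bookkeeping, training, leakage
control) and the *qualitative* behavior of decoders under known effect
sizes; they say nothing about absolute accuracies on real recordings.

**Acceptance study conditions.** The stochastic acceptance checks use two
simulated conditions sized for a single CPU: a zero-effect cohort
(6 subjects × 24 trials; every decoder must stay inside the 95% binomial
band around 50%) and a strong-effect cohort (6 subjects × 20 trials,
amplitude 0.05 mM·cm ≈ 14× default with inter-subject variability removed;
every decoder must exceed 90%). Removing the variability is part of the
condition's definition: "signal far above noise" must include
between-subject variation, otherwise the subject-independent Bayes ceiling
itself sits below 90% no matter how large the amplitude — with full
default variability even an amplitude an order of magnitude above the
noise floor caps LOSO accuracy near 85%, because the decoder must
extrapolate to an unseen gain/topography. The strong-effect condition
therefore probes decoder machinery at high SNR, while cross-subject
transfer under realistic variability is what the default-condition
examples show.

For the networks, the strong-effect harness holds the *effective*
early-stopping patience of the full-scale recipe constant: patience counts
epochs, an epoch at full scale is ~11 parameter updates (1020 trials,
batch 100) but only one update at desk scale, so the harness uses
patience 220 epochs (= the recipe's ~220 updates of patience) with a
350-epoch cap. With the nominal patience of 20 one-update epochs, training
stops an order of magnitude earlier than the recipe intends, long before
convergence.

## Known limitations

- SNIRF support is a documented subset (single data block, uniform rate,
  per-channel source–detector pairs), sufficient for interchange of this
  pipeline's data, not a general SNIRF implementation.
- The loader for externally deposited MATLAB-format datasets is a
  best-effort adapter (`io_formats.load_figshare_mat`) returning raw
  variables; the deposit's internal structure is not standardized, so the
  adapter is excluded from the tested surface.
- Training is CPU-only and float32; no GPU, mixed precision, fine-tuning,
  or recurrent architectures.
- The exact EvoNorm variant/group count and sample-level baseline-interval
  endpoints of the original tooling are unspecified upstream; the choices
  here (S0, 8 groups; [−1, 0) baseline) are documented fixed conventions.
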