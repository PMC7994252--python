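"""Signal conditioning: MBLL conversion, band-pass filtering, epoching, features.

The processing chain mirrors standard practice for prefrontal fNIRS
classification work:

1. optical-density changes at (780, 805, 830) nm are mapped to hemoglobin
   concentration changes (ΔHbR, ΔHbO, in mM·cm) through the modified
   Beer–Lambert law with fixed published coefficients;
2. both chromophores are band-pass filtered at 0.01–0.09 Hz with a 6th-order
   zero-phase (forward–backward) Butterworth filter, suppressing drift,
   Mayer waves sit just above the band edge, respiration and cardiac
   pulsation well outside it;
3. the continuous series is cut into task-locked epochs covering [0, 15] s
   after each onset (201 samples at 40/3 Hz, both endpoints included) and
   baseline-corrected with the mean over [-1, 0) s;
4. optionally, per-trial z-scoring over time (population convention) for the
   neural models, or windowed temporal-mean features (0–5 / 5–10 / 10–15 s)
   for the linear models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .io_formats import (HBO, HBR, CHROMOPHORES, HemodynamicRecording,
                         OpticalDensityRecording)

__all__ = [
    "MBLL_MATRIX",
    "SAMPLING_RATE_HZ",
    "FilterSpec",
    "EpochSpec",
    "EpochSet",
    "FeatureMatrix",
    "mbll_convert",
    "bandpass",
    "epoch",
    "zscore_time",
    "extract_mean_features",
    "DEFAULT_FEATURE_WINDOWS",
]

logger = logging.getLogger(__name__)

#: MBLL coefficients, mM·cm per unit ΔOD.  Rows map to (ΔHbR, ΔHbO),
#: columns to ΔOD at (780, 805, 830) nm.  Immutable package constant.
MBLL_MATRIX = np.array([[1.8545, -0.2394, -1.4887],
                        [-1.0947, 0.5970, 1.4847]])
MBLL_MATRIX.setflags(write=False)

#: nominal sampling rate; a [0, 15] s epoch inclusive of both endpoints is
#: exactly 201 samples at 40/3 Hz (printed as 13.3 Hz on device spec sheets)
SAMPLING_RATE_HZ = 40.0 / 3.0

DEFAULT_FEATURE_WINDOWS = ((0.0, 5.0), (5.0, 10.0), (10.0, 15.0))


def mbll_convert(od: OpticalDensityRecording) -> HemodynamicRecording:
    """Convert ΔOD at three wavelengths to (ΔHbO, ΔHbR) via the MBLL matrix.

    The matrix rows produce (ΔHbR, ΔHbO); the output recording stores the
    package chromophore order (HbO, HbR).
    """
    if not isinstance(od, OpticalDensityRecording):
        raise TypeError("mbll_convert expects an OpticalDensityRecording")
    # od: (n_samples, n_channels, 3) x matrix.T (3, 2) -> (n_samples, n_channels, 2)
    hbr_hbo = od.od @ MBLL_MATRIX.T
    hb = np.empty_like(hbr_hbo)
    hb[..., HBO] = hbr_hbo[..., 1]
    hb[..., HBR] = hbr_hbo[..., 0]
    return HemodynamicRecording(od.subject_id, od.sampling_rate_hz, hb,
                                list(od.events), list(od.channel_names))


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase Butterworth band-pass: design order 6, applied forward-backward."""

    order: int = 6
    band_hz: tuple[float, float] = (0.01, 0.09)

    def validate(self, fs: float):
        low, high = self.band_hz
        if not (0 < low < high < fs / 2):
            raise ValueError(
                f"band {self.band_hz} Hz must satisfy 0 < low < high < Nyquist ({fs / 2} Hz)")


def _design_sos(spec: FilterSpec, fs: float):
    spec.validate(fs)
    return signal.butter(spec.order, spec.band_hz, btype="bandpass", fs=fs,
                         output="sos")


def bandpass(rec: HemodynamicRecording, spec: FilterSpec = FilterSpec()) -> HemodynamicRecording:
    """Band-pass filter both chromophores, zero phase, appending to filter_log."""
    sos = _design_sos(spec, rec.sampling_rate_hz)
    # sosfiltfilt needs > 3x the pad length for stable edge handling
    padlen = 3 * (2 * sos.shape[0] + 1)
    if rec.n_samples <= 3 * padlen:
        raise ValueError(
            f"recording of {rec.n_samples} samples too short for stable zero-phase "
            f"filtering (need > {3 * padlen}); pad or record longer")
    flat = rec.hb.reshape(rec.n_samples, -1)
    out = signal.sosfiltfilt(sos, flat, axis=0).reshape(rec.hb.shape)
    log = list(rec.filter_log)
    log.append({"type": "butter_bandpass_zerophase", "order": spec.order,
                "band_hz": list(spec.band_hz)})
    return HemodynamicRecording(rec.subject_id, rec.sampling_rate_hz, out,
                                list(rec.events), list(rec.channel_names), log)


def bandpass_response_db(spec: FilterSpec, fs: float, freq_hz: float) -> float:
    """Magnitude response (dB) of the zero-phase filter at one frequency.

    Forward–backward application squares the magnitude response of the
    designed order-6 filter; useful as an analytic oracle for attenuation.
    """
    sos = _design_sos(spec, fs)
    _, h = signal.sosfreqz(sos, worN=[freq_hz], fs=fs)
    return 20.0 * np.log10(np.abs(h[0]) ** 2)


@dataclass(frozen=True)
class EpochSpec:
    """Task-locked epoch window and baseline interval, in seconds.

    The window is inclusive of both endpoints: [0, 15] s at 40/3 Hz gives
    201 samples.  Baseline samples lie in [-1, 0) s — the onset sample
    belongs to the epoch, not the baseline.
    """

    window_s: tuple[float, float] = (0.0, 15.0)
    baseline_s: tuple[float, float] = (-1.0, 0.0)

    def __post_init__(self):
        if self.window_s[1] <= self.window_s[0]:
            raise ValueError("epoch window must have positive length")
        if self.baseline_s[1] > self.window_s[0]:
            raise ValueError("baseline interval must precede the epoch window")

    def n_samples(self, fs: float) -> int:
        return int(round((self.window_s[1] - self.window_s[0]) * fs)) + 1


@dataclass
class EpochSet:
    """Trials × time × (channels·chromophores) tensor with labels.

    The wide axis is channel-major: indices ``0..n_channels-1`` are HbO for
    channels 1..n, indices ``n_channels..2n-1`` are HbR.  Labels are encoded
    IS=0, MA=1 (:data:`nirsbci.io_formats.CLASSES` order).
    """

    data: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    sampling_rate_hz: float
    spec: EpochSpec = field(default_factory=EpochSpec)
    normalized: bool = False
    n_dropped: int = 0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.subject_ids = np.asarray(self.subject_ids)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_time, n_channels*2)")
        if self.data.shape[2] % 2:
            raise ValueError("wide axis must be n_channels * 2 chromophores")
        if len(self.labels) != self.n_trials or len(self.subject_ids) != self.n_trials:
            raise ValueError("labels/subject_ids length must equal n_trials")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_time(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2] // 2

    def select(self, mask_or_idx) -> "EpochSet":
        return EpochSet(self.data[mask_or_idx], self.labels[mask_or_idx],
                        self.subject_ids[mask_or_idx], self.sampling_rate_hz,
                        self.spec, self.normalized, 0)

    @staticmethod
    def concatenate(parts: list["EpochSet"]) -> "EpochSet":
        first = parts[0]
        if any(p.normalized != first.normalized for p in parts):
            raise ValueError("cannot mix normalized and raw epoch sets")
        return EpochSet(np.concatenate([p.data for p in parts]),
                        np.concatenate([p.labels for p in parts]),
                        np.concatenate([p.subject_ids for p in parts]),
                        first.sampling_rate_hz, first.spec, first.normalized,
                        sum(p.n_dropped for p in parts))


def epoch(rec: HemodynamicRecording, spec: EpochSpec = EpochSpec()) -> EpochSet:
    """Segment a continuous recording into baseline-corrected epochs.

    Events without a full baseline before onset or a full window after are
    dropped with a logged warning; the drop count is stored on the result.
    Epoch count plus drop count always equals the event count.
    """
    fs = rec.sampling_rate_hz
    n_win = spec.n_samples(fs)
    start_off = int(round(spec.window_s[0] * fs))
    base_lo = int(round(spec.baseline_s[0] * fs))   # e.g. -13
    base_hi = int(round(spec.baseline_s[1] * fs))   # 0; exclusive
    n_ch = rec.n_channels

    from .io_formats import CLASSES
    trials, labels = [], []
    dropped = 0
    for onset, label in rec.events:
        lo = onset + min(base_lo, start_off)
        hi = onset + start_off + n_win
        if lo < 0 or hi > rec.n_samples:
            dropped += 1
            logger.warning("dropping event at sample %d (%s): needs [%d, %d) of %d samples",
                           onset, label, lo, hi, rec.n_samples)
            continue
        seg = rec.hb[onset + start_off: onset + start_off + n_win]  # (n_win, n_ch, 2)
        base = rec.hb[onset + base_lo: onset + base_hi].mean(axis=0)  # (n_ch, 2)
        seg = seg - base
        # channel-major wide layout: HbO block then HbR block
        wide = np.concatenate([seg[:, :, HBO], seg[:, :, HBR]], axis=1)
        trials.append(wide)
        labels.append(CLASSES.index(label))

    data = (np.stack(trials) if trials
            else np.empty((0, n_win, 2 * n_ch)))
    return EpochSet(data, np.asarray(labels, dtype=int),
                    np.full(len(trials), rec.subject_id, dtype=object),
                    fs, spec, normalized=False, n_dropped=dropped)


def zscore_time(ep: EpochSet, eps: float = 1e-12) -> EpochSet:
    """Z-score each trial and channel over the time axis (population std).

    Constant channels map to all-zeros via the epsilon guard.  Applying to an
    already-normalized set is a contract error.
    """
    if ep.normalized:
        raise ValueError("EpochSet is already z-scored; refusing double normalization")
    mean = ep.data.mean(axis=1, keepdims=True)
    std = ep.data.std(axis=1, keepdims=True)  # population convention, divisor n
    out = np.where(std > eps, (ep.data - mean) / np.maximum(std, eps), 0.0)
    return EpochSet(out, ep.labels.copy(), ep.subject_ids.copy(),
                    ep.sampling_rate_hz, ep.spec, normalized=True,
                    n_dropped=ep.n_dropped)


@dataclass
class FeatureMatrix:
    """Trials × features matrix of windowed temporal means, with names."""

    values: np.ndarray
    labels: np.ndarray
    feature_names: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("features contain NaN/Inf")
        if self.values.shape[0] != len(self.labels):
            raise ValueError("labels length must equal n_trials")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def extract_mean_features(ep: EpochSet,
                          windows_s=DEFAULT_FEATURE_WINDOWS) -> FeatureMatrix:
    """Per-window temporal-mean amplitudes, concatenated window-major.

    Feature order: for each window, for each chromophore (HbO then HbR), for
    each channel — giving ``n_windows × 2 × n_channels`` features (96 for the
    16-channel montage with three windows).  Window samples are taken from
    ``[a, b)`` seconds relative to epoch start, except the last window which
    also includes the final epoch sample.
    """
    fs = ep.sampling_rate_hz
    t0 = ep.spec.window_s[0]
    n_ch = ep.n_channels
    cols, names = [], []
    for wi, (a, b) in enumerate(windows_s):
        if a < ep.spec.window_s[0] - 1e-9 or b > ep.spec.window_s[1] + 1e-9:
            raise ValueError(f"window ({a}, {b}) s lies outside the epoch "
                             f"window {ep.spec.window_s}")
        lo = int(round((a - t0) * fs))
        hi = int(round((b - t0) * fs))
        if wi == len(windows_s) - 1 and abs(b - ep.spec.window_s[1]) < 1e-9:
            hi += 1  # closing window keeps the final epoch sample
        seg = ep.data[:, lo:hi, :].mean(axis=1)  # (n_trials, 2*n_ch)
        cols.append(seg)
        for chrom in CHROMOPHORES:
            for ch in range(n_ch):
                names.append(f"w{a:g}-{b:g}s_{chrom}_ch{ch + 1}")
    values = np.concatenate(cols, axis=1)
    return FeatureMatrix(values, ep.labels.copy(), names)
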