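"""Convenience chains tying the processing stages together."""

from __future__ import annotations

from .io_formats import HemodynamicRecording, OpticalDensityRecording
from .preprocess import (EpochSet, EpochSpec, FilterSpec, bandpass, epoch,
                         mbll_convert)

__all__ = ["preprocess_recording", "epochs_from_recordings"]


def preprocess_recording(rec: OpticalDensityRecording | HemodynamicRecording,
                         filter_spec: FilterSpec = FilterSpec(),
                         epoch_spec: EpochSpec = EpochSpec()) -> EpochSet:
    """Full conditioning of one recording: (MBLL) → band-pass → epochs.

    Optical-density input is converted to hemoglobin first; hemodynamic
    input (e.g. simulated data) goes straight to filtering.
    """
    if isinstance(rec, OpticalDensityRecording):
        rec = mbll_convert(rec)
    return epoch(bandpass(rec, filter_spec), epoch_spec)


def epochs_from_recordings(recordings,
                           filter_spec: FilterSpec = FilterSpec(),
                           epoch_spec: EpochSpec = EpochSpec()) -> EpochSet:
    """Preprocess every subject identically and pool the epochs."""
    return EpochSet.concatenate(
        [preprocess_recording(r, filter_spec, epoch_spec) for r in recordings])
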