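"""Simulate one fNIRS subject and walk the signal through preprocessing.

Builds a single synthetic session (30 mental-arithmetic + 30 idle trials),
band-pass filters it, cuts task-locked epochs, and prints the tensor shapes
and peak response amplitude at every stage.
"""

import nirsbci as nb

cfg = nb.SimulationConfig(n_subjects=1, rng_seed=0)
rec, truth = nb.simulate_subject(cfg, 0)
print(f"continuous recording: {rec.hb.shape} samples x channels x (HbO, HbR), "
      f"{rec.n_samples / rec.sampling_rate_hz / 60:.1f} min at "
      f"{rec.sampling_rate_hz:.3f} Hz, {len(rec.events)} task onsets")

filtered = nb.bandpass(rec)
print(f"after 0.01-0.09 Hz zero-phase Butterworth: filter_log={filtered.filter_log}")

ep = nb.epoch(filtered)
print(f"epochs: {ep.data.shape} trials x time x (16 HbO + 16 HbR), "
      f"{ep.n_dropped} dropped")

ma = ep.data[ep.labels == 1]
is_ = ep.data[ep.labels == 0]
# grand-average HbO response over channels; MA should rise, IS stay flat
print(f"mean peak HbO, MA trials: {ma[:, :, :16].mean(axis=(0, 2)).max():.4f} mM*cm")
print(f"mean peak HbO, IS trials: {is_[:, :, :16].mean(axis=(0, 2)).max():.4f} mM*cm")
print("The MA average shows the hemodynamic rise (peak a few seconds after "
      "onset); the IS average is an order of magnitude smaller - residual noise.")
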