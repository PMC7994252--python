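"""MBLL conversion, band-pass filtering, epoching, normalization, features."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nirsbci as nb
from nirsbci.preprocess import bandpass_response_db

FS = nb.SAMPLING_RATE_HZ


def _od_from(arr, fs=FS, events=()):
    return nb.OpticalDensityRecording("s", fs, np.asarray(arr, dtype=float),
                                      list(events))


class TestMbll:
    @pytest.mark.parametrize("od_vec, hbr, hbo", [
        ((1.0, 0.0, 0.0), 1.8545, -1.0947),
        ((0.0, 1.0, 0.0), -0.2394, 0.5970),
        ((0.0, 0.0, 1.0), -1.4887, 1.4847),
        ((0.0, 0.0, 0.0), 0.0, 0.0),
        ((1.0, 1.0, 1.0), 0.1264, 0.9870),  # row sums of the printed matrix
    ])
    def test_unit_vectors_map_through_printed_matrix(self, od_vec, hbr, hbo):
        rec = _od_from(np.array(od_vec)[None, None, :])
        hb = nb.mbll_convert(rec).hb
        assert hb[0, 0, nb.HBR] == pytest.approx(hbr, abs=1e-12)
        assert hb[0, 0, nb.HBO] == pytest.approx(hbo, abs=1e-12)

    def test_linearity(self, rng):
        x = rng.standard_normal((30, 4, 3))
        y = rng.standard_normal((30, 4, 3))
        a, b = 2.5, -1.25
        left = nb.mbll_convert(_od_from(a * x + b * y)).hb
        right = (a * nb.mbll_convert(_od_from(x)).hb
                 + b * nb.mbll_convert(_od_from(y)).hb)
        np.testing.assert_allclose(left, right, atol=1e-12)

    def test_wrong_wavelength_count_rejected(self, rng):
        with pytest.raises((ValueError, TypeError)):
            nb.mbll_convert(nb.HemodynamicRecording("s", FS,
                                                    rng.standard_normal((10, 2, 2))))


class TestBandpass:
    def _sine_rec(self, freq, n_seconds=600, amp=1.0):
        t = np.arange(int(n_seconds * FS)) / FS
        hb = amp * np.sin(2 * np.pi * freq * t)[:, None, None] * np.ones((1, 2, 2))
        return nb.HemodynamicRecording("s", FS, hb)

    def test_dc_removed(self):
        n = int(600 * FS)
        rec = nb.HemodynamicRecording("s", FS, np.full((n, 2, 2), 5.0))
        out = nb.bandpass(rec)
        core = out.hb[n // 4: -n // 4]
        assert np.max(np.abs(core)) < 1e-6

    def test_passband_sine_preserved_within_oracle(self):
        # oracle: the designed filter's squared magnitude response at 0.05 Hz
        gain_db = bandpass_response_db(nb.FilterSpec(), FS, 0.05)
        assert gain_db > -0.5  # 0.05 Hz sits mid-band
        rec = self._sine_rec(0.05)
        out = nb.bandpass(rec)
        n = rec.n_samples
        core = slice(n // 4, 3 * n // 4)
        ratio = out.hb[core, 0, 0].std() / rec.hb[core, 0, 0].std()
        assert abs(ratio - 10 ** (gain_db / 20)) < 0.05

    def test_cardiac_band_attenuated_40db(self):
        gain_db = bandpass_response_db(nb.FilterSpec(), FS, 1.0)
        assert gain_db <= -40.0
        rec = self._sine_rec(1.0, n_seconds=300)
        out = nb.bandpass(rec)
        n = rec.n_samples
        core = slice(n // 4, 3 * n // 4)
        # project onto the 1 Hz tone to isolate it from slow edge transients
        t = np.arange(n)[core] / FS
        phasor = np.exp(2j * np.pi * 1.0 * t)
        amp_in = 2 * np.abs(rec.hb[core, 0, 0] @ phasor) / t.size
        amp_out = 2 * np.abs(out.hb[core, 0, 0] @ phasor) / t.size
        assert 20 * np.log10(amp_out / amp_in) <= -40.0

    def test_zero_phase_no_lag(self):
        rec = self._sine_rec(0.05)
        out = nb.bandpass(rec)
        n = rec.n_samples
        core = slice(n // 4, 3 * n // 4)
        x = rec.hb[core, 0, 0]
        y = out.hb[core, 0, 0]
        lags = np.arange(-40, 41)
        xc = [np.dot(x, np.roll(y, l)) for l in lags]
        assert lags[int(np.argmax(xc))] == 0

    def test_filter_log_appends_each_application(self):
        rec = self._sine_rec(0.05)
        once = nb.bandpass(rec)
        twice = nb.bandpass(once)
        assert len(once.filter_log) == 1
        assert len(twice.filter_log) == 2
        assert twice.filter_log[0] == twice.filter_log[1]

    def test_too_short_recording_advises_padding(self):
        rec = nb.HemodynamicRecording("s", FS, np.zeros((30, 1, 2)))
        with pytest.raises(ValueError, match="pad"):
            nb.bandpass(rec)

    def test_band_above_nyquist_rejected(self):
        rec = self._sine_rec(0.05)
        with pytest.raises(ValueError, match="Nyquist"):
            nb.bandpass(rec, nb.FilterSpec(band_hz=(0.01, 7.0)))


class TestEpoch:
    def _rec_with_events(self, rng, n_events=6, n_channels=3):
        fs = FS
        spacing = int(25 * fs)
        onsets = [int(20 * fs) + i * spacing for i in range(n_events)]
        n = onsets[-1] + int(20 * fs)
        hb = rng.standard_normal((n, n_channels, 2))
        events = [(o, "MA" if i % 2 else "IS") for i, o in enumerate(onsets)]
        return nb.HemodynamicRecording("s", fs, hb, events)

    def test_shapes_and_counts(self, rng):
        rec = self._rec_with_events(rng)
        ep = nb.epoch(rec)
        assert ep.data.shape == (6, 201, 6)
        assert ep.n_dropped == 0
        assert len(ep.labels) == 6

    def test_epoch_plus_dropped_equals_events(self, rng):
        rec = self._rec_with_events(rng)
        # event at sample 3: no 1 s baseline available
        events = sorted(rec.events + [(3, "MA")])
        rec2 = nb.HemodynamicRecording("s", rec.sampling_rate_hz, rec.hb, events)
        ep = nb.epoch(rec2)
        assert ep.n_trials + ep.n_dropped == len(events)
        assert ep.n_dropped == 1

    def test_constant_signal_zero_after_baseline(self):
        fs = FS
        n = int(60 * fs)
        hb = np.tile(np.array([2.0, -3.0]), (n, 4, 1))
        rec = nb.HemodynamicRecording("s", fs, hb, [(int(20 * fs), "MA")])
        ep = nb.epoch(rec)
        np.testing.assert_allclose(ep.data, 0.0, atol=1e-12)

    def test_wide_axis_layout_hbo_block_then_hbr_block(self):
        fs = FS
        n = int(60 * fs)
        hb = np.zeros((n, 2, 2))
        hb[:, 0, nb.HBO] = 1.0   # constant -> removed by baseline
        t = np.arange(n) / fs
        hb[:, 1, nb.HBR] = t     # ramp survives baseline as a ramp
        rec = nb.HemodynamicRecording("s", fs, hb, [(int(20 * fs), "MA")])
        ep = nb.epoch(rec)
        # channel-major: 0..1 HbO ch1..2, 2..3 HbR ch1..2
        assert ep.data.shape[2] == 4
        np.testing.assert_allclose(ep.data[0, :, 0], 0.0, atol=1e-12)
        assert ep.data[0, -1, 3] > ep.data[0, 0, 3]

    def test_labels_encoded_is0_ma1(self, rng):
        rec = self._rec_with_events(rng)
        ep = nb.epoch(rec)
        want = [0 if l == "IS" else 1 for _, l in rec.events]
        assert ep.labels.tolist() == want


class TestZscore:
    def test_mean_zero_sd_one(self, small_epochs):
        z = nb.zscore_time(small_epochs)
        np.testing.assert_allclose(z.data.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.data.std(axis=1), 1.0, atol=1e-9)

    def test_constant_channel_guard(self):
        data = np.zeros((2, 10, 2))
        data[:, :, 1] = np.linspace(0, 1, 10)
        ep = nb.EpochSet(data, [0, 1], ["a", "a"], FS)
        z = nb.zscore_time(ep)
        assert np.all(np.isfinite(z.data))
        np.testing.assert_allclose(z.data[:, :, 0], 0.0)

    def test_hand_computed_example(self):
        data = np.repeat(np.array([1.0, 2.0, 3.0]).reshape(1, 3, 1), 2, axis=2)
        ep = nb.EpochSet(data, [0], ["a"], FS)
        z = nb.zscore_time(ep)
        np.testing.assert_allclose(z.data[0, :, 0],
                                   [-1.2247448, 0.0, 1.2247448], atol=1e-6)

    def test_double_normalization_rejected(self, small_epochs):
        z = nb.zscore_time(small_epochs)
        with pytest.raises(ValueError, match="already"):
            nb.zscore_time(z)

    def test_idempotent_within_guard(self, small_epochs):
        z = nb.zscore_time(small_epochs)
        z2 = nb.zscore_time(nb.EpochSet(z.data, z.labels, z.subject_ids,
                                        z.sampling_rate_hz, z.spec, False))
        np.testing.assert_allclose(z2.data, z.data, atol=1e-9)


class TestFeatures:
    def test_dimension_96_for_16_channel_montage(self, small_epochs):
        feats = nb.extract_mean_features(small_epochs)
        assert feats.n_features == 96
        assert len(feats.feature_names) == 96

    def test_constant_epoch_gives_constant_features(self):
        data = np.full((3, 201, 4), 1.75)
        ep = nb.EpochSet(data, [0, 1, 0], list("aaa"), FS)
        feats = nb.extract_mean_features(ep)
        np.testing.assert_allclose(feats.values, 1.75, atol=1e-12)

    def test_ramp_window_means(self):
        # linear ramp 0 -> 1 over [0, 15] s: window means near 1/6, 1/2, 5/6
        ramp = np.linspace(0.0, 1.0, 201)
        ep = nb.EpochSet(ramp.reshape(1, 201, 1) * np.ones((1, 1, 2)),
                         [0], ["a"], FS)
        feats = nb.extract_mean_features(ep)
        hbo_means = feats.values[0, [0, 2, 4]]  # HbO feature of each window
        np.testing.assert_allclose(hbo_means, [1 / 6, 1 / 2, 5 / 6], atol=0.01)

    def test_window_outside_epoch_rejected(self, small_epochs):
        with pytest.raises(ValueError, match="outside"):
            nb.extract_mean_features(small_epochs, windows_s=[(0, 20)])

    def test_rows_follow_trial_permutation(self, small_epochs):
        perm = np.random.default_rng(0).permutation(small_epochs.n_trials)
        f1 = nb.extract_mean_features(small_epochs)
        f2 = nb.extract_mean_features(small_epochs.select(perm))
        np.testing.assert_allclose(f2.values, f1.values[perm], atol=1e-12)


@settings(max_examples=25, deadline=None)
@given(st.lists(st.floats(-10, 10), min_size=3, max_size=3),
       st.lists(st.floats(-10, 10), min_size=3, max_size=3),
       st.floats(-3, 3), st.floats(-3, 3))
def test_mbll_linearity_property(v1, v2, a, b):
    """The conversion is a linear map on OD vectors."""
    x = np.array(v1)[None, None, :]
    y = np.array(v2)[None, None, :]
    left = nb.mbll_convert(_od_from(a * x + b * y)).hb
    right = (a * nb.mbll_convert(_od_from(x)).hb
             + b * nb.mbll_convert(_od_from(y)).hb)
    np.testing.assert_allclose(left, right, atol=1e-9)
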