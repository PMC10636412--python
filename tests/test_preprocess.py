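import numpy as np
import pytest

from neurodyad import EEGRecording
from neurodyad.montage import build_grid_montage
from neurodyad.preprocess import (
    ActionEpoch,
    PreprocessError,
    SegmentExclusion,
    bandpass_filter,
    detect_bad_channels,
    eliminate_amplitude_artifacts,
    interpolate_channels,
    notch_filter,
    rereference_average,
    segment_epochs,
)

from conftest import fast_params
from neurodyad import build_schedule, generate_session

RATE = 1000.0


def _sine_recording(freq, amp=10.0, rate=RATE, seconds=4.0, n_channels=2):
    t = np.arange(int(rate * seconds)) / rate
    sig = amp * np.sin(2 * np.pi * freq * t)
    data = np.tile(sig, (n_channels, 1))
    return EEGRecording(data, rate, [f"E{i + 1}" for i in range(n_channels)])


def _interior(x, frac=0.1):
    k = int(len(x) * frac)
    return x[k:-k]


class TestNotchFilter:
    def test_60hz_attenuated_to_below_1uv(self):
        rec = notch_filter(_sine_recording(60.0, amp=10.0))
        rms = np.sqrt(np.mean(_interior(rec.data[0]) ** 2))
        assert rms <= 1.0

    def test_8hz_preserved_within_5pct(self):
        rec = notch_filter(_sine_recording(8.0, amp=10.0))
        amp = np.abs(_interior(rec.data[0])).max()
        assert abs(amp - 10.0) / 10.0 < 0.05

    def test_10hz_ripple_below_1db(self):
        rec = notch_filter(_sine_recording(10.0, amp=10.0))
        rms_in = 10.0 / np.sqrt(2)
        rms_out = np.sqrt(np.mean(_interior(rec.data[0]) ** 2))
        assert abs(20 * np.log10(rms_out / rms_in)) <= 1.0

    def test_zero_in_zero_out(self):
        rec = notch_filter(EEGRecording(np.zeros((2, 1000)), RATE, ["A", "B"]))
        np.testing.assert_allclose(rec.data, 0.0, atol=1e-12)

    def test_rate_too_low(self):
        with pytest.raises(PreprocessError):
            notch_filter(EEGRecording(np.zeros((1, 100)), 100.0, ["A"]))


class TestBandpassFilter:
    def test_dc_removed(self):
        rec = bandpass_filter(
            EEGRecording(np.full((1, 8000), 100.0), RATE, ["A"])
        )
        assert np.abs(_interior(rec.data[0], 0.2)).max() < 1.0

    @pytest.mark.parametrize("freq", [8.0, 200.0])
    def test_gain_matches_analytic_butterworth(self, freq):
        # zero-phase order-1 Butterworth bandpass: measured power gain must
        # equal the squared analog magnitude response at the prewarped
        # frequency (bilinear design identity)
        low, high = 0.3, 40.0
        rec = bandpass_filter(_sine_recording(freq, amp=1.0, seconds=20.0), low, high, order=1)
        measured = np.sqrt(np.mean(_interior(rec.data[0], 0.25) ** 2)) * np.sqrt(2)

        def prewarp(f):
            return RATE / np.pi * np.tan(np.pi * f / RATE)

        w = 2 * np.pi * prewarp(freq)
        w1, w2 = 2 * np.pi * prewarp(low), 2 * np.pi * prewarp(high)
        bw = w2 - w1
        h = (bw * w) / np.sqrt((w1 * w2 - w**2) ** 2 + (bw * w) ** 2)
        expected = h**2  # forward-backward pass squares the magnitude
        assert measured == pytest.approx(expected, rel=0.02)

    def test_invalid_band(self):
        with pytest.raises(PreprocessError):
            bandpass_filter(_sine_recording(8.0), 40.0, 0.3)

    def test_linearity_of_filter_chain(self, rng):
        a = EEGRecording(rng.normal(size=(2, 4000)), RATE, ["A", "B"])
        b = EEGRecording(rng.normal(size=(2, 4000)), RATE, ["A", "B"])
        ab = EEGRecording(a.data + b.data, RATE, ["A", "B"])
        chain = lambda r: bandpass_filter(notch_filter(r)).data
        np.testing.assert_allclose(
            chain(ab), chain(a) + chain(b), rtol=1e-6, atol=1e-9
        )


class TestRereferenceAverage:
    def test_two_channel_toy(self):
        rec = EEGRecording(np.array([[3.0], [1.0]]), 250.0, ["A", "B"])
        out = rereference_average(rec)
        np.testing.assert_allclose(out.data, [[1.0], [-1.0]])
        assert out.reference == "average"

    def test_column_means_zero(self, rng):
        rec = EEGRecording(rng.normal(size=(5, 300)), 250.0, list("ABCDE"))
        out = rereference_average(rec)
        np.testing.assert_allclose(out.data.mean(axis=0), 0.0, atol=1e-9)

    def test_idempotent(self, rng):
        rec = EEGRecording(rng.normal(size=(5, 300)), 250.0, list("ABCDE"))
        once = rereference_average(rec)
        twice = rereference_average(once)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-12)

    def test_bad_channels_excluded_from_mean(self):
        data = np.array([[1.0], [3.0], [500.0]])
        rec = EEGRecording(data, 250.0, ["A", "B", "C"], bad_channels={"C"})
        out = rereference_average(rec)
        np.testing.assert_allclose(out.data[:2, 0], [-1.0, 1.0])

    def test_all_bad_raises(self):
        rec = EEGRecording(np.zeros((2, 10)), 250.0, ["A", "B"], bad_channels={"A", "B"})
        with pytest.raises(PreprocessError):
            rereference_average(rec)


class TestDetectBadChannels:
    def test_flat_channel_detected(self, rng):
        data = rng.normal(0, 5, size=(4, 1000))
        data[2] = 0.0
        rec = EEGRecording(data, 250.0, ["A", "B", "C", "D"])
        assert detect_bad_channels(rec) == {"C"}

    def test_railed_channel_detected(self, rng):
        data = rng.normal(0, 5, size=(3, 1000))
        data[1] = 500.0 * np.sign(rng.normal(size=1000))  # railed, high variance
        rec = EEGRecording(data, 250.0, ["A", "B", "C"])
        assert "B" in detect_bad_channels(rec)

    def test_clean_channels_pass(self, rng):
        rec = EEGRecording(rng.normal(0, 5, size=(4, 1000)), 250.0, list("ABCD"))
        assert detect_bad_channels(rec) == set()


class TestInterpolateChannels:
    def setup_method(self):
        self.montage = build_grid_montage(4, 12)

    def _recording(self, rng):
        data = rng.normal(0, 5, size=(48, 500))
        return EEGRecording(data, 250.0, list(self.montage.labels))

    def test_bad_channel_replaced_by_neighbor_mean(self, rng):
        rec = self._recording(rng)
        label = "E15"
        nbrs = self.montage.neighbors(label)
        for n in nbrs:
            rec.data[rec.channel_index(n)] = 5.0
        out = interpolate_channels(rec, {label}, self.montage)
        np.testing.assert_allclose(out.data[out.channel_index(label)], 5.0)

    def test_good_channels_untouched(self, rng):
        rec = self._recording(rng)
        out = interpolate_channels(rec, {"E15"}, self.montage)
        others = [i for i, l in enumerate(rec.channel_labels) if l != "E15"]
        np.testing.assert_array_equal(out.data[others], rec.data[others])

    def test_empty_bad_set_is_identity(self, rng):
        rec = self._recording(rng)
        out = interpolate_channels(rec, set(), self.montage)
        np.testing.assert_array_equal(out.data, rec.data)

    def test_over_35_bad_raises_exclusion(self, rng):
        rec = self._recording(rng)
        bad = set(list(self.montage.labels)[:36])
        with pytest.raises(SegmentExclusion, match="35"):
            interpolate_channels(rec, bad, self.montage)

    def test_exactly_35_bad_is_interpolated(self, rng):
        rec = self._recording(rng)
        bad = set(list(self.montage.labels)[:35])
        out = interpolate_channels(rec, bad, self.montage)
        assert out is not None


class TestSegmentEpochs:
    def test_full_session_yields_16_epochs_4_per_action(self, clean_session, montage48):
        params, rec, sched, _ = clean_session
        epochs = segment_epochs(rec, sched)
        assert len(epochs) == 16
        for action in (1, 2, 3, 4):
            assert sum(e.action_id == action for e in epochs) == 4

    def test_epoch_sample_count(self, clean_session):
        params, rec, sched, _ = clean_session
        epochs = segment_epochs(rec, sched)
        assert all(e.n_samples == int(10 * params.sample_rate) for e in epochs)

    def test_truncated_epoch_unusable(self, rng):
        from neurodyad.io import Event, EventSchedule

        rec = EEGRecording(rng.normal(size=(2, 2000)), 250.0, ["A", "B"])
        sched = EventSchedule([Event(0, 1, 1, 1, 1), Event(1000, 2, 1, 1, 1)])
        epochs = segment_epochs(rec, sched)
        assert not epochs[1].usable and epochs[1].unusable_reason == "truncated"

    def test_counts_invariant_under_channel_permutation(self, clean_session, rng):
        params, rec, sched, _ = clean_session
        perm = rng.permutation(rec.n_channels)
        shuffled = EEGRecording(
            rec.data[perm],
            rec.sample_rate,
            [rec.channel_labels[i] for i in perm],
        )
        epochs = segment_epochs(shuffled, sched)
        assert len(epochs) == 16
        for action in (1, 2, 3, 4):
            assert sum(e.action_id == action for e in epochs) == 4


class TestEliminateAmplitudeArtifacts:
    def _epoch(self, data, rate=1000.0):
        return ActionEpoch(
            data=data,
            sample_rate=rate,
            channel_labels=[f"E{i + 1}" for i in range(data.shape[0])],
            action_id=1,
            iteration=1,
            run=1,
            trial=1,
        )

    def test_clean_epoch_unmasked(self, rng):
        ep = self._epoch(rng.normal(0, 10, size=(3, 10_000)))
        out = eliminate_amplitude_artifacts(ep)
        assert out.masked_fraction == 0.0 and out.usable

    def test_300ms_artifact_masks_5pct(self):
        data = np.zeros((1, 10_000))
        data[0, 5000:5300] = 200.0
        out = eliminate_amplitude_artifacts(self._epoch(data))
        # 300 ms excursion + 100 ms pad each side = 500 ms of 10 s
        assert out.masked_fraction == pytest.approx(0.05, abs=0.001)

    def test_railed_epoch_unusable(self):
        out = eliminate_amplitude_artifacts(self._epoch(np.full((1, 10_000), 500.0)))
        assert out.masked_fraction == 1.0 and not out.usable

    def test_scope_restricts_channels(self):
        data = np.zeros((2, 10_000))
        data[1, 100:200] = 300.0  # artifact on out-of-scope channel
        out = eliminate_amplitude_artifacts(self._epoch(data), scope_labels=["E1"])
        assert out.masked_fraction == 0.0
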