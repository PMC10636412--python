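import numpy as np
import pytest

from neurodyad.envelope import (
    EnvelopeError,
    alpha_filter,
    cluster_average,
    compute_cluster_envelope,
    global_field_power,
    hilbert_envelope,
)
from neurodyad.montage import Montage, build_grid_montage
from neurodyad.preprocess import ActionEpoch

RATE = 250.0


def _epoch(data, rate=RATE, labels=None):
    labels = labels or [f"E{i + 1}" for i in range(data.shape[0])]
    return ActionEpoch(
        data=data,
        sample_rate=rate,
        channel_labels=labels,
        action_id=1,
        iteration=1,
        run=1,
        trial=1,
    )


def _sine(freq, amp=1.0, seconds=10.0, rate=RATE, phase=0.0):
    t = np.arange(int(rate * seconds)) / rate
    return amp * np.sin(2 * np.pi * freq * t + phase)


def _interior(x, frac=0.1):
    k = int(len(x) * frac)
    return x[k:-k]


def _analytic_gain(freq, low, high, order, rate):
    """Closed-form zero-phase Butterworth bandpass power gain with bilinear
    prewarping (the independent oracle for the measured sinusoid gains)."""
    prewarp = lambda f: rate / np.pi * np.tan(np.pi * f / rate)
    w = 2 * np.pi * prewarp(freq)
    w1, w2 = 2 * np.pi * prewarp(low), 2 * np.pi * prewarp(high)
    bw, w0sq = w2 - w1, w1 * w2
    h2 = 1.0 / (1.0 + ((w**2 - w0sq) / (bw * w)) ** (2 * order))
    return h2  # filtfilt: |H|^2


class TestAlphaFilter:
    def test_7p5hz_preserved(self):
        ep = _epoch(_sine(7.5)[None, :])
        out = alpha_filter(ep)
        assert np.abs(_interior(out.data[0])).max() == pytest.approx(1.0, rel=0.05)

    @pytest.mark.parametrize("freq,max_residual", [(3.0, 0.10), (20.0, 0.10)])
    def test_out_of_band_attenuated(self, freq, max_residual):
        ep = _epoch(_sine(freq)[None, :])
        out = alpha_filter(ep)
        assert np.abs(_interior(out.data[0])).max() <= max_residual

    def test_gain_matches_analytic_response(self):
        for freq in (7.5, 20.0):
            ep = _epoch(_sine(freq, seconds=40.0)[None, :])
            out = alpha_filter(ep)
            measured = np.mean(_interior(out.data[0], 0.25) ** 2) * 2  # power gain
            expected = _analytic_gain(freq, 6.0, 9.0, 4, RATE)
            assert abs(measured - expected) <= max(0.02, 0.02 * expected)

    def test_zero_in_zero_out(self):
        out = alpha_filter(_epoch(np.zeros((2, 2500))))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_invalid_band(self):
        with pytest.raises(EnvelopeError):
            alpha_filter(_epoch(np.zeros((1, 2500))), 9.0, 6.0)


class TestClusterAverage:
    def setup_method(self):
        self.montage = build_grid_montage(4, 12)

    def _epoch48(self, fill=0.0):
        return _epoch(np.full((48, 100), fill), labels=list(self.montage.labels))

    def test_identical_channels_give_that_value(self):
        ep = self._epoch48(fill=3.0)
        left, right = cluster_average(ep, self.montage)
        np.testing.assert_allclose(left, 3.0)
        np.testing.assert_allclose(right, 3.0)

    def test_one_hot_channel_diluted_sevenfold(self):
        ep = self._epoch48()
        ep.data[ep.channel_labels.index(self.montage.left_cluster[0])] = 7.0
        left, right = cluster_average(ep, self.montage)
        np.testing.assert_allclose(left, 1.0)
        np.testing.assert_allclose(right, 0.0)

    def test_six_label_cluster_rejected(self):
        m = self.montage
        bad = Montage(
            name="bad",
            labels=m.labels,
            left_cluster=m.left_cluster[:6] + (m.left_cluster[5],),
            right_cluster=m.right_cluster,
            adjacency={},
        )
        # construction itself enforces 7 distinct entries via duplicate labels
        with pytest.raises(Exception):
            Montage(
                name="bad2",
                labels=m.labels,
                left_cluster=m.left_cluster[:6],
                right_cluster=m.right_cluster,
                adjacency={},
            )

    def test_missing_cluster_channel_is_config_error(self):
        ep = _epoch(np.zeros((4, 100)), labels=["X1", "X2", "X3", "X4"])
        with pytest.raises(EnvelopeError, match="missing"):
            cluster_average(ep, self.montage)


class TestHilbertEnvelope:
    def test_sinusoid_amplitude_recovered(self):
        env = hilbert_envelope(_sine(7.5, amp=3.0))
        assert np.abs(_interior(env, 0.05) - 3.0).max() / 3.0 < 0.02

    def test_tracks_slow_modulator(self):
        t = np.arange(int(RATE * 10)) / RATE
        mod = 1.5 + np.sin(2 * np.pi * 0.2 * t)  # slow, positive
        sig = mod * np.sin(2 * np.pi * 7.5 * t)
        env = hilbert_envelope(sig)
        rel_err = np.abs(_interior(env, 0.1) - _interior(mod, 0.1)) / _interior(mod, 0.1)
        assert np.median(rel_err) < 0.03

    def test_zero_signal_zero_envelope(self):
        np.testing.assert_allclose(hilbert_envelope(np.zeros(1000)), 0.0, atol=1e-12)

    def test_sign_flip_invariant(self, rng):
        x = rng.normal(size=2000)
        np.testing.assert_allclose(hilbert_envelope(x), hilbert_envelope(-x), atol=1e-9)

    def test_all_masked_raises(self):
        with pytest.raises(EnvelopeError):
            hilbert_envelope(np.zeros(100), mask=np.ones(100, dtype=bool))

    def test_nonnegative(self, rng):
        assert (hilbert_envelope(rng.normal(size=3000)) >= 0).all()


class TestGlobalFieldPower:
    def test_identical_channels_after_average_ref_give_zero(self):
        # identical channels re-referenced to average are all zero
        data = np.zeros((5, 200))
        assert np.allclose(global_field_power(_epoch(data)), 0.0)

    def test_antisymmetric_pair(self):
        a = np.abs(np.random.default_rng(0).normal(size=300)) + 0.1
        data = np.vstack([a, -a])
        np.testing.assert_allclose(global_field_power(_epoch(data)), a, atol=1e-12)

    def test_permutation_invariant(self, rng):
        data = rng.normal(size=(6, 500))
        g1 = global_field_power(_epoch(data))
        g2 = global_field_power(_epoch(data[rng.permutation(6)]))
        np.testing.assert_allclose(g1, g2, atol=1e-12)

    def test_common_offset_then_rereference_invariant(self, rng):
        from neurodyad import EEGRecording
        from neurodyad.preprocess import rereference_average

        data = rng.normal(size=(6, 500))
        labels = [f"E{i}" for i in range(6)]
        base = rereference_average(EEGRecording(data, RATE, labels))
        shifted = rereference_average(EEGRecording(data + 42.0, RATE, labels))
        g1 = global_field_power(_epoch(base.data, labels=labels))
        g2 = global_field_power(_epoch(shifted.data, labels=labels))
        np.testing.assert_allclose(g1, g2, atol=1e-9)

    def test_too_few_channels(self):
        with pytest.raises(EnvelopeError):
            global_field_power(_epoch(np.zeros((1, 100))))

    def test_gfp_peak_near_injected_burst_center(self, clean_session, montage48):
        from neurodyad.preprocess import preprocess_recording, segment_epochs

        params, rec, sched, truth = clean_session
        clean, _ = preprocess_recording(rec, montage48)
        epochs = segment_epochs(clean, sched)
        rate = params.sample_rate
        hits, total = 0, 0
        for ep in epochs:
            env = compute_cluster_envelope(ep, montage48)
            a, it = ep.action_id - 1, ep.iteration - 1
            center_ms = truth.true_lags_ms[a, it] + truth.burst_durations_ms[a, it] / 2.0
            center_ms = min(center_ms, 10_000.0)
            # smooth GFP to suppress the 2f rectification ripple before argmax
            kernel = np.ones(int(rate * 0.4)) / int(rate * 0.4)
            smooth = np.convolve(env.gfp, kernel, mode="same")
            peak_ms = np.argmax(smooth) / rate * 1000.0
            total += 1
            expected_peak = min(center_ms, 10_000 - 500)
            if abs(peak_ms - expected_peak) <= 100.0:
                hits += 1
        assert hits / total >= 0.8


class TestEnvelopeProperties:
    def test_envelope_of_mean_below_mean_of_envelopes(self, rng):
        sigs = rng.normal(size=(7, 2000))
        from scipy.signal import butter, filtfilt

        b, a = butter(4, [6, 9], btype="bandpass", fs=RATE)
        sigs = filtfilt(b, a, sigs, axis=1)
        mean_env = hilbert_envelope(sigs.mean(axis=0))
        env_mean = np.mean([hilbert_envelope(s) for s in sigs], axis=0)
        interior = slice(100, -100)
        assert (mean_env[interior] <= env_mean[interior] + 1e-9).all()
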