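"""Preprocessing chain: filters, ocular regression, reference, segmentation."""

import numpy as np
import pytest

from conftest import make_recording, zeros_recording
from fpvs.config import ConditionSpec
from fpvs.montage import nearest_neighbors
from fpvs.preprocessing import (
    bandpass,
    downsample,
    eog_correct,
    interpolate_channel,
    notch,
    rereference_average,
    segment_epochs,
    segment_trial,
)
from fpvs.recording import SCALP, Recording
from fpvs.simulate import blink_train


def sinusoid_recording(freq: float, fs: float = 1024.0, seconds: float = 4.0):
    t = np.arange(round(seconds * fs)) / fs
    wave = np.sin(2 * np.pi * freq * t)
    return make_recording(np.tile(wave, (68, 1)), fs=fs)


def steady_amplitude(rec, freq: float, channel: int = 0) -> float:
    """Amplitude at `freq` over the central half of the recording."""
    n = rec.n_samples
    seg = rec.data[channel, n // 4 : n // 4 + n // 2]
    spec = np.abs(np.fft.rfft(seg)) / len(seg) * 2
    freqs = np.fft.rfftfreq(len(seg), 1 / rec.fs)
    return float(spec[np.argmin(np.abs(freqs - freq))])


class TestInterpolation:
    def test_constant_neighbors(self):
        rec = zeros_recording(1.0)
        for label in nearest_neighbors("Cz", 3):
            rec.data[rec.index(label)] = 7.0
        out = interpolate_channel(rec, "Cz")
        np.testing.assert_allclose(out.data[rec.index("Cz")], 7.0)

    def test_mean_of_three_neighbors(self):
        rec = zeros_recording(1.0)
        for value, label in zip((1.0, 2.0, 3.0), nearest_neighbors("Oz", 3)):
            rec.data[rec.index(label)] = value
        out = interpolate_channel(rec, "Oz")
        np.testing.assert_allclose(out.data[rec.index("Oz")], 2.0)

    def test_ocular_channel_rejected(self):
        with pytest.raises(ValueError):
            interpolate_channel(zeros_recording(1.0), "VEOG_U")

    def test_other_channels_untouched(self):
        rng = np.random.default_rng(0)
        rec = make_recording(rng.normal(size=(68, 512)))
        out = interpolate_channel(rec, "Fp1")
        mask = np.ones(68, bool)
        mask[rec.index("Fp1")] = False
        np.testing.assert_array_equal(out.data[mask], rec.data[mask])


class TestDownsample:
    def test_constant_preserved(self):
        rec = make_recording(np.full((68, 4096), 5.0))
        out = downsample(rec, 4)
        assert out.fs == 256.0
        np.testing.assert_allclose(out.data, 5.0, rtol=1e-9)

    def test_passband_sinusoid_preserved(self):
        out = downsample(sinusoid_recording(10.0), 4)
        assert steady_amplitude(out, 10.0) == pytest.approx(1.0, rel=0.01)

    def test_alias_band_suppressed(self):
        out = downsample(sinusoid_recording(200.0), 4)
        n = out.n_samples
        # central half: keeps the check clear of filter edge transients
        assert np.abs(out.data[0, n // 4 : 3 * n // 4]).max() < 0.05

    def test_event_indices_rescaled(self):
        rec = make_recording(np.zeros((68, 4096)), events=[(1001, 1)])
        assert downsample(rec, 4).events == [(250, 1)]

    def test_non_divisible_rate_rejected(self):
        with pytest.raises(ValueError):
            downsample(make_recording(np.zeros((68, 1000)), fs=1000.0), 3.5)  # type: ignore[arg-type]


class TestNotch:
    def test_line_frequency_removed(self):
        out = notch(sinusoid_recording(50.0, fs=256.0), centers=(50.0,))
        assert steady_amplitude(out, 50.0) <= 0.1

    def test_passband_preserved(self):
        out = notch(sinusoid_recording(10.0, fs=256.0), centers=(50.0, 100.0))
        assert steady_amplitude(out, 10.0) == pytest.approx(1.0, abs=0.05)

    def test_dc_unchanged(self):
        rec = make_recording(np.full((68, 1024), 3.0), fs=256.0)
        out = notch(rec, centers=(50.0,))
        np.testing.assert_allclose(out.data, 3.0, rtol=1e-6)

    def test_center_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            notch(zeros_recording(1.0, fs=256.0), centers=(150.0,))

    def test_linearity(self):
        rec = sinusoid_recording(30.0, fs=256.0)
        scaled = rec.with_data(3.0 * rec.data)
        centers = (50.0, 100.0)
        np.testing.assert_allclose(
            notch(scaled, centers=centers).data,
            3.0 * notch(rec, centers=centers).data,
            atol=1e-9,
        )


class TestBandpass:
    def test_passband_amplitude(self):
        out = bandpass(sinusoid_recording(10.0, fs=256.0))
        assert steady_amplitude(out, 10.0) == pytest.approx(1.0, abs=0.02)

    def test_stopband_attenuation(self):
        out = bandpass(sinusoid_recording(120.0))
        assert steady_amplitude(out, 120.0) < 0.3

    def test_zero_input_zero_output(self):
        out = bandpass(zeros_recording(2.0))
        assert np.abs(out.data).max() == 0.0

    def test_bad_cutoffs_rejected(self):
        with pytest.raises(ValueError):
            bandpass(zeros_recording(1.0, fs=256.0), low=0.05, high=130.0)


class TestEogCorrection:
    def test_silent_eog_leaves_scalp_untouched(self):
        rng = np.random.default_rng(1)
        rec = make_recording(rng.normal(size=(68, 2048)))
        rec.data[64:] = 0.0
        out = eog_correct(rec)
        np.testing.assert_array_equal(out.data[:64], rec.data[:64])

    def test_blink_propagation_removed_exactly(self):
        rec = zeros_recording(8.0)
        blinks = blink_train(8.0, rate=30.0, amp=100.0, seed=4)
        rec.data[rec.index("VEOG_U")] = blinks
        rec.data[rec.index("Fp1")] = 0.4 * blinks
        out = eog_correct(rec)
        corrected = out.data[rec.index("Fp1")]
        # mean-centered regression leaves a DC offset; blink *fluctuation*
        # must be gone (DC is irrelevant to amplitude spectra past 0 Hz)
        residual = np.abs(corrected - corrected.mean()).max()
        assert residual < 0.01 * 0.4 * np.abs(blinks).max()

    def test_residual_correlation_near_zero_on_noisy_data(self):
        rng = np.random.default_rng(7)
        rec = make_recording(rng.normal(size=(68, 4096)))
        blinks = blink_train(4.0, rate=40.0, amp=80.0, seed=2)
        rec.data[rec.index("VEOG_U")] += blinks
        rec.data[:64] += np.outer(np.linspace(0.5, 0.0, 64), blinks)
        out = eog_correct(rec)
        veog = out.data[out.index("VEOG_U")] - out.data[out.index("VEOG_L")]
        for ch in range(64):
            r = np.corrcoef(out.data[ch], veog)[0, 1]
            assert abs(r) < 0.05

    def test_missing_ocular_channel_rejected(self):
        rec = zeros_recording(1.0)
        clipped = Recording(
            data=rec.data[:66],
            fs=rec.fs,
            channel_labels=rec.channel_labels[:66],
            channel_roles=rec.channel_roles[:66],
        )
        with pytest.raises(ValueError, match="ocular"):
            eog_correct(clipped)


class TestAverageReference:
    def test_scalp_mean_is_zero(self):
        rng = np.random.default_rng(5)
        out = rereference_average(make_recording(rng.normal(size=(68, 1000))))
        assert np.abs(out.data[:64].mean(axis=0)).max() < 1e-9

    def test_common_mode_invariance(self):
        rng = np.random.default_rng(6)
        rec = make_recording(rng.normal(size=(68, 500)))
        shifted = rec.with_data(rec.data.copy())
        shifted.data[:64] += 3.0
        np.testing.assert_allclose(
            rereference_average(shifted).data[:64],
            rereference_average(rec).data[:64],
            atol=1e-12,
        )

    def test_two_channel_toy(self):
        rec = Recording(
            data=np.array([[1.0], [3.0]]),
            fs=256.0,
            channel_labels=["P1", "P2"],
            channel_roles=[SCALP, SCALP],
        )
        np.testing.assert_allclose(
            rereference_average(rec).data, [[-1.0], [1.0]]
        )

    def test_idempotent(self):
        rng = np.random.default_rng(8)
        rec = make_recording(rng.normal(size=(68, 300)))
        once = rereference_average(rec)
        twice = rereference_average(once)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-12)

    def test_ocular_channels_left_alone(self):
        rng = np.random.default_rng(9)
        rec = make_recording(rng.normal(size=(68, 300)))
        out = rereference_average(rec)
        np.testing.assert_array_equal(out.data[64:], rec.data[64:])


class TestSegmentation:
    def make_processed(self, n_seconds: float, onset_s: float = 1.0):
        rec = make_recording(
            np.arange(68 * round(n_seconds * 256), dtype=float).reshape(68, -1),
            fs=256.0,
            events=[(round(onset_s * 256), 1)],
        )
        return rec

    def test_identity_discrimination_window_length(self):
        cond = ConditionSpec(
            name="b6", base_freq=6, oddball_freq=1, sequence_s=60,
            ramp_s=2, steady_samples=14337, anchor="ramp_end",
        )
        seg = segment_trial(self.make_processed(64.0), cond)
        assert seg.data.shape == (68, 14337)

    def test_duty_cycle_window_length(self):
        cond = ConditionSpec(
            name="d10", base_freq=10, oddball_freq=1, sequence_s=90,
            ramp_s=3, steady_samples=23041, anchor="onset",
        )
        seg = segment_trial(self.make_processed(94.0), cond)
        assert seg.data.shape == (68, 23041)

    def test_anchor_offsets_window_by_ramp(self):
        cond_onset = ConditionSpec(
            name="a", base_freq=6, oddball_freq=1, sequence_s=8,
            ramp_s=1, steady_samples=512, anchor="onset",
        )
        cond_ramp = ConditionSpec(
            name="b", base_freq=6, oddball_freq=1, sequence_s=8,
            ramp_s=1, steady_samples=512, anchor="ramp_end",
        )
        rec = self.make_processed(12.0)
        a = segment_trial(rec, cond_onset)
        b = segment_trial(rec, cond_ramp)
        assert b.data[0, 0] - a.data[0, 0] == 256  # one ramp at 256 Hz

    def test_short_recording_reports_deficit(self):
        cond = ConditionSpec(
            name="b6", base_freq=6, oddball_freq=1, sequence_s=60,
            ramp_s=2, steady_samples=14337, anchor="ramp_end",
        )
        with pytest.raises(ValueError, match="deficit"):
            segment_trial(self.make_processed(10.0), cond)

    def test_no_event_rejected(self):
        cond = ConditionSpec(
            name="b6", base_freq=6, oddball_freq=1, sequence_s=8,
            ramp_s=1, steady_samples=512,
        )
        rec = make_recording(np.zeros((68, 4096)), fs=256.0)
        with pytest.raises(ValueError, match="event"):
            segment_trial(rec, cond)

    @pytest.mark.parametrize(
        "n_samples,n_epochs", [(14337, 56), (23041, 90), (256, 1)]
    )
    def test_epoch_counts(self, n_samples, n_epochs):
        cond = ConditionSpec(
            name="x", base_freq=6, oddball_freq=1, sequence_s=91,
            ramp_s=0, steady_samples=n_samples,
        )
        rec = make_recording(
            np.zeros((68, n_samples + 256)), fs=256.0, events=[(0, 1)]
        )
        epochs = segment_epochs(segment_trial(rec, cond))
        assert epochs.epochs.shape == (n_epochs, 68, 256)
        assert len(epochs.labels) == n_epochs

    def test_sub_second_segment_rejected(self):
        from fpvs.preprocessing import TrialSegment

        seg = TrialSegment(
            data=np.zeros((68, 100)), fs=256.0,
            channel_labels=[f"c{i}" for i in range(68)],
            channel_roles=[SCALP] * 68,
        )
        with pytest.raises(ValueError):
            segment_epochs(seg)

    def test_epochs_partition_segment_in_order(self):
        cond = ConditionSpec(
            name="x", base_freq=6, oddball_freq=1, sequence_s=3,
            ramp_s=0, steady_samples=600,
        )
        rec = make_recording(
            np.tile(np.arange(768.0), (68, 1)), fs=256.0, events=[(0, 1)]
        )
        epochs = segment_epochs(segment_trial(rec, cond))
        # 600 samples -> 2 epochs, 88 samples discarded
        assert epochs.epochs.shape[0] == 2
        np.testing.assert_array_equal(epochs.epochs[1, 0], np.arange(256, 512.0))
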