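"""Preprocessing chain: resampling, filtering, referencing, epoching,
baseline, artifact rejection — each against a closed-form or simulation oracle."""

import numpy as np
import pandas as pd
import pytest

import fernpipe as fp
from fernpipe.containers import ContinuousEEG, EpochSet
from fernpipe.preprocessing import (
    PreprocConfig,
    bandpass,
    baseline_correct,
    downsample,
    extract_epochs,
    preprocess,
    reject_artifacts,
    rereference_mastoids,
)


def _raw(toy_montage, data, fs=1024.0, events=None):
    if events is None:
        events = pd.DataFrame({"sample": [], "condition": []})
    return ContinuousEEG(data=data, fs=fs, montage=toy_montage, events=events)


class TestDownsample:
    def test_1024_to_256_quarters_the_samples(self, toy_montage):
        raw = _raw(toy_montage, np.random.default_rng(0).normal(size=(3, 4096)))
        out = downsample(raw, 256.0)
        assert out.fs == 256.0
        assert out.n_samples == 1024

    def test_constant_signal_stays_constant(self, toy_montage):
        raw = _raw(toy_montage, np.full((3, 4096), 5.0))
        out = downsample(raw, 256.0)
        assert np.allclose(out.data, 5.0, atol=1e-6)

    def test_event_sample_remap_within_one_output_sample(self, toy_montage):
        ev = pd.DataFrame({"sample": [1024], "condition": ["x"]})
        raw = _raw(toy_montage, np.zeros((3, 4096)), events=ev)
        out = downsample(raw, 256.0)
        assert abs(int(out.events["sample"].iloc[0]) - 256) <= 1

    def test_upsampling_request_rejected(self, toy_montage):
        raw = _raw(toy_montage, np.zeros((3, 1024)))
        with pytest.raises(ValueError):
            downsample(raw, 2048.0)


class TestBandpass:
    @pytest.mark.parametrize(
        "freq, min_gain, max_gain",
        [(10.0, 0.95, 1.05), (50.0, 0.0, 0.05)],
    )
    def test_frequency_response_oracle(self, toy_montage, freq, min_gain, max_gain):
        fs = 256.0
        t = np.arange(int(fs * 30)) / fs
        sig = np.sin(2 * np.pi * freq * t)
        raw = _raw(toy_montage, np.tile(sig, (3, 1)), fs=fs)
        out = bandpass(raw, 0.5, 20.0)
        mid = slice(len(t) // 4, 3 * len(t) // 4)
        gain = out.data[0, mid].std() / sig[mid].std()
        assert min_gain <= gain <= max_gain

    def test_zero_signal_stays_zero(self, toy_montage):
        raw = _raw(toy_montage, np.zeros((3, 2048)))
        assert np.allclose(bandpass(raw, 0.5, 20.0).data, 0.0)

    def test_invalid_band_rejected(self, toy_montage):
        raw = _raw(toy_montage, np.zeros((3, 2048)), fs=256.0)
        with pytest.raises(ValueError):
            bandpass(raw, 20.0, 0.5)
        with pytest.raises(ValueError):
            bandpass(raw, 0.5, 200.0)


class TestRereference:
    def test_hand_computed_toy_case(self, toy_montage):
        # Fz=5, M1=1, M2=3 -> Fz-out = 5 - 2 = 3
        raw = _raw(toy_montage, np.array([[5.0], [1.0], [3.0]]))
        out = rereference_mastoids(raw)
        assert out.data[0, 0] == pytest.approx(3.0)

    def test_mastoid_pair_mean_zero_everywhere(self, toy_montage):
        raw = _raw(toy_montage, np.random.default_rng(1).normal(size=(3, 500)))
        out = rereference_mastoids(raw)
        i1, i2 = toy_montage.mastoid_indices
        assert np.allclose(0.5 * (out.data[i1] + out.data[i2]), 0.0, atol=1e-12)

    def test_common_offset_invariance(self, toy_montage):
        x = np.random.default_rng(2).normal(size=(3, 500))
        a = rereference_mastoids(_raw(toy_montage, x))
        b = rereference_mastoids(_raw(toy_montage, x + 42.0))
        assert np.allclose(a.data, b.data)


class TestEpoching:
    def test_epoch_has_256_samples_at_256hz(self, toy_montage):
        ev = pd.DataFrame({"sample": [512], "condition": ["a"], "correct": [True]})
        raw = _raw(toy_montage, np.zeros((3, 2048)), fs=256.0, events=ev)
        ep = extract_epochs(raw, (-200.0, 800.0))
        assert ep.n_times == 256
        # 0 ms sits exactly on the event sample; the first sample is within
        # one sampling step of -200 ms (the grid cannot hold both exactly)
        assert 0.0 in ep.times
        assert abs(ep.times[0] + 200.0) <= 1000.0 / 256.0

    def test_boundary_event_skipped(self, toy_montage):
        ev = pd.DataFrame({"sample": [10, 512], "condition": ["early", "ok"], "correct": [True, True]})
        raw = _raw(toy_montage, np.zeros((3, 2048)), fs=256.0, events=ev)
        ep = extract_epochs(raw, (-200.0, 800.0))
        assert ep.n_epochs == 1 and ep.labels[0] == "ok"

    def test_labels_follow_events(self, toy_montage):
        ev = pd.DataFrame(
            {"sample": [300, 600, 900], "condition": ["a", "b", "a"], "correct": [True] * 3}
        )
        raw = _raw(toy_montage, np.zeros((3, 2048)), fs=256.0, events=ev)
        ep = extract_epochs(raw, (-200.0, 800.0))
        assert list(ep.labels) == ["a", "b", "a"]

    def test_incorrect_control_answers_excluded(self, toy_montage):
        ev = pd.DataFrame(
            {"sample": [300, 600, 900], "condition": ["a", "b", "a"],
             "correct": [True, False, True]}
        )
        raw = _raw(toy_montage, np.zeros((3, 2048)), fs=256.0, events=ev)
        assert extract_epochs(raw, (-200.0, 800.0)).n_epochs == 2
        assert extract_epochs(raw, (-200.0, 800.0), usable_only=False).n_epochs == 3

    def test_no_events_raises(self, toy_montage):
        raw = _raw(toy_montage, np.zeros((3, 2048)), fs=256.0)
        with pytest.raises(ValueError):
            extract_epochs(raw)


class TestBaseline:
    @staticmethod
    def _epochs(toy_montage, data):
        n_t = data.shape[2]
        times = (np.arange(n_t) - n_t // 5) / 256.0 * 1000.0  # -200..800-ish
        return EpochSet(
            data=data,
            times=times,
            labels=np.array(["x"] * data.shape[0], dtype=object),
            montage=toy_montage,
            fs=256.0,
        )

    def test_baseline_window_mean_zero_after_correction(self, toy_montage):
        rng = np.random.default_rng(0)
        ep = self._epochs(toy_montage, rng.normal(size=(4, 3, 255)))
        out = baseline_correct(ep, (-200.0, 0.0))
        mask = (out.times >= -200.0) & (out.times < 0.0)
        assert np.allclose(out.data[:, :, mask].mean(axis=2), 0.0, atol=1e-9)

    def test_constant_epoch_becomes_zero(self, toy_montage):
        ep = self._epochs(toy_montage, np.full((2, 3, 255), 7.0))
        assert np.allclose(baseline_correct(ep).data, 0.0)

    def test_linear_ramp_closed_form(self, toy_montage):
        """Ramp from -1 at -200 ms to +4 at 800 ms: baseline mean is the ramp
        value at the baseline midpoint, so the corrected value at 0 ms equals
        slope * 100 ms."""
        n_t = 256
        times = (np.arange(n_t) - 51) / 256.0 * 1000.0
        ramp = -1.0 + (times - times[0]) / 1000.0 * 5.0
        data = np.tile(ramp, (1, 3, 1))
        ep = EpochSet(
            data=data, times=times, labels=np.array(["x"], dtype=object),
            montage=toy_montage, fs=256.0,
        )
        out = baseline_correct(ep, (-200.0, 0.0))
        k0 = int(np.argmin(np.abs(out.times)))
        mask = (times >= -200.0) & (times < 0.0)
        expected = ramp[k0] - ramp[mask].mean()
        assert out.data[0, 0, k0] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(5.0 * 0.1, abs=0.02)  # slope x 100 ms

    def test_double_application_errors_but_recorrection_is_identity(self, toy_montage):
        rng = np.random.default_rng(3)
        ep = self._epochs(toy_montage, rng.normal(size=(3, 3, 255)))
        once = baseline_correct(ep)
        with pytest.raises(ValueError):
            baseline_correct(once)
        # idempotence: correcting the already-corrected data again (as a fresh
        # epoch set) changes nothing
        fresh = EpochSet(
            data=once.data.copy(), times=once.times, labels=once.labels,
            montage=toy_montage, fs=once.fs,
        )
        twice = baseline_correct(fresh)
        assert np.allclose(twice.data, once.data, atol=1e-12)


class TestRejection:
    @staticmethod
    def _epochs(toy_montage, data):
        times = (np.arange(data.shape[2]) - 51) / 256.0 * 1000.0
        return EpochSet(
            data=data, times=times,
            labels=np.array(["x"] * data.shape[0], dtype=object),
            montage=toy_montage, fs=256.0,
        )

    def test_large_blink_rejected_at_100uv(self, toy_montage):
        data = np.random.default_rng(0).normal(size=(2, 3, 255))
        data[1, 0, 100:130] += 500.0
        out = reject_artifacts(self._epochs(toy_montage, data), 100.0, 1000.0)
        assert list(out.rejected) == [False, True]
        assert out.rejection_reason[1] == "ptp"

    def test_steep_gradient_rejected(self, toy_montage):
        data = np.zeros((1, 3, 255))
        data[0, 1, 100] = 80.0  # single-sample spike: ptp 80 < 100 but gradient 80 > 50
        out = reject_artifacts(self._epochs(toy_montage, data), 100.0, 50.0)
        assert out.rejected[0] and out.rejection_reason[0] == "gradient"

    def test_infinite_thresholds_reject_nothing(self, toy_montage):
        data = np.random.default_rng(1).normal(size=(5, 3, 255)) * 300
        out = reject_artifacts(self._epochs(toy_montage, data), np.inf, np.inf)
        assert not out.rejected.any()

    def test_manual_override(self, toy_montage):
        data = np.zeros((3, 3, 255))
        out = reject_artifacts(self._epochs(toy_montage, data), 100.0, 50.0, manual_reject=[2])
        assert list(out.rejected) == [False, False, True]

    def test_clean_synthetic_epochs_mostly_retained(
        self, small_igt_config, montage, sphere, source_space
    ):
        """5 µV noise, no blinks: >= 95% of epochs survive default thresholds."""
        session = fp.simulate_igt_session(small_igt_config, seed=21)
        raw = fp.synthesize_eeg(
            session, fp.ERPTemplate.for_profile("control"), montage,
            fp.NoiseParams(rms_uv=5.0, blink_rate_hz=0.0), seed=21,
            sphere=sphere, source_space=source_space,
        )
        ep = preprocess(raw)
        assert ep.kept.mean() >= 0.95


class TestChainProperties:
    def test_filter_downsample_order_robustness(self, toy_montage):
        """On a band-limited signal the two orderings agree closely."""
        fs = 1024.0
        t = np.arange(int(fs * 24)) / fs
        sig = (
            np.sin(2 * np.pi * 3.0 * t)
            + 0.5 * np.sin(2 * np.pi * 9.0 * t + 1.0)
            + 0.2 * np.sin(2 * np.pi * 15.0 * t + 2.0)
        )
        raw = _raw(toy_montage, np.tile(sig, (3, 1)), fs=fs)
        a = bandpass(downsample(raw, 256.0), 0.5, 20.0)
        b = downsample(bandpass(raw, 0.5, 20.0), 256.0)
        # trim 6 s per side: the 0.5 Hz high-pass transient decays slowly
        mid = slice(6 * 256, -6 * 256)
        rms = a.data[0, mid].std()
        assert np.allclose(a.data[0, mid], b.data[0, mid], atol=0.03 * rms)

    def test_injected_template_survives_full_chain(
        self, noiseless_control_epochs, montage
    ):
        """Latency shift <= 1 output sample, amplitude change <= 10%."""
        from conftest import igt_condition_labels

        loss, _ = igt_condition_labels(noiseless_control_epochs, "hf")
        erp = fp.average_condition(noiseless_control_epochs, loss)
        fz = erp.channel("Fz")
        k = int(np.argmin(fz))
        assert abs(erp.times[k] - 330.0) <= 1000.0 / 256.0 + 1e-9
        assert fz[k] == pytest.approx(-6.0, rel=0.10)

    def test_epoching_is_label_conservative(self, noiseless_control_epochs):
        ep = noiseless_control_epochs
        per_condition = sum((ep.labels == c).sum() for c in set(ep.labels))
        assert per_condition == ep.n_epochs

    def test_invalid_preproc_config_rejected(self, toy_montage):
        raw = _raw(toy_montage, np.zeros((3, 2048)))
        with pytest.raises(ValueError):
            preprocess(raw, PreprocConfig(band=(20.0, 0.5)))
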