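"""Filtering, re-referencing, epoching, stage labeling, artifact screening."""

import numpy as np
import pandas as pd
import pytest

from screamsleep import preproc
from screamsleep.containers import CHANNELS_13, ContinuousEEG, Hypnogram
from screamsleep.preproc import FilterSpec


def make_eeg(data, rate=500.0, labels=None):
    data = np.atleast_2d(data)
    if labels is None:
        labels = [f"ch{i}" for i in range(data.shape[0])]
    return ContinuousEEG(data=data, rate=rate, channel_labels=labels)


def butter_bandpass_gain(f, low, high, order):
    """Analytic Butterworth band-pass magnitude (low-pass prototype via the
    standard band-pass transform); independent oracle for filter tests."""
    w, w1, w2 = 2 * np.pi * f, 2 * np.pi * low, 2 * np.pi * high
    w0sq, bw = w1 * w2, w2 - w1
    x = (w**2 - w0sq) / (w * bw)
    return 1.0 / np.sqrt(1.0 + x ** (2 * order))


class TestBandpass:
    def test_passband_center_nearly_unattenuated(self):
        t = np.arange(50000) / 500.0
        eeg = make_eeg(np.sin(2 * np.pi * 10 * t))
        out = preproc.bandpass(eeg, FilterSpec((0.1, 30.0), order=1))
        seg = slice(10000, 40000)
        atten = 1 - out.data[0, seg].std() / eeg.data[0, seg].std()
        assert atten < 0.05

    def test_stopband_attenuation_matches_analytic_response(self):
        t = np.arange(50000) / 500.0
        eeg = make_eeg(np.sin(2 * np.pi * 60 * t))
        out = preproc.bandpass(eeg, FilterSpec((4.0, 8.0), order=4, zero_phase=True))
        seg = slice(10000, 40000)
        measured = out.data[0, seg].std() / eeg.data[0, seg].std()
        expected = butter_bandpass_gain(60.0, 4.0, 8.0, 4) ** 2  # forward-backward
        assert measured < 0.01
        assert np.isclose(measured, expected, rtol=0.25, atol=1e-6)

    def test_zero_phase_has_no_group_delay(self, rng):
        x = rng.standard_normal(20000)
        out = preproc.bandpass(make_eeg(x), FilterSpec((4.0, 8.0), order=4, zero_phase=True))
        y = out.data[0]
        lags = np.arange(-50, 51)
        xc = [np.dot(x[200:-200], np.roll(y, lag)[200:-200]) for lag in lags]
        assert lags[np.argmax(xc)] == 0

    def test_invalid_band_rejected(self):
        eeg = make_eeg(np.zeros(1000))
        with pytest.raises(ValueError):
            preproc.bandpass(eeg, FilterSpec((30.0, 10.0), order=1))


class TestCommonAverage:
    def test_two_channel_example(self):
        eeg = make_eeg(np.array([[3.0], [1.0]]))
        out = preproc.rereference_common_average(eeg)
        assert np.allclose(out.data[:, 0], [1.0, -1.0])
        assert out.reference == "common-average"

    def test_idempotent(self, rng):
        eeg = make_eeg(rng.standard_normal((13, 500)), labels=CHANNELS_13)
        once = preproc.rereference_common_average(eeg)
        twice = preproc.rereference_common_average(once)
        assert np.allclose(once.data, twice.data, atol=1e-9)

    def test_channel_mean_zero_after(self, rng):
        eeg = make_eeg(rng.standard_normal((13, 1000)), labels=CHANNELS_13)
        out = preproc.rereference_common_average(eeg)
        assert np.abs(out.data.mean(axis=0)).max() < 1e-9

    def test_bad_channels_excluded_from_average(self):
        eeg = make_eeg(np.array([[1.0], [3.0], [100.0]]))
        eeg.bad_channels = ["ch2"]
        out = preproc.rereference_common_average(eeg)
        assert np.allclose(out.data[:2, 0], [-1.0, 1.0])

    def test_needs_two_good_channels(self):
        eeg = make_eeg(np.zeros((2, 10)))
        eeg.bad_channels = ["ch0"]
        with pytest.raises(ValueError):
            preproc.rereference_common_average(eeg)


class TestEpoch:
    def test_window_arithmetic(self, rng):
        eeg = make_eeg(rng.standard_normal((2, 10000)))
        events = pd.DataFrame({"onset_sample": [5000]})
        es = preproc.epoch(eeg, events, (-1.0, 2.0))
        assert es.data.shape == (1, 2, 1501)
        assert np.array_equal(es.data[0], eeg.data[:, 4500:6001])
        assert es.times[np.flatnonzero(es.times == 0)[0]] == 0

    def test_edge_event_flagged_not_dropped(self, rng):
        eeg = make_eeg(rng.standard_normal((1, 3000)))
        events = pd.DataFrame({"onset_sample": [100, 2000]})
        es = preproc.epoch(eeg, events, (-1.0, 2.0))
        assert es.n_trials == 2
        assert not es.kept[0] and es.reject_reason[0] == "edge"
        assert not es.kept[1] and es.reject_reason[1] == "edge"  # 2000+1001 > 3000

    def test_injected_erp_peak_latency(self, wake_session):
        es = preproc.epoch(wake_session.eeg, wake_session.events, (-1.0, 2.0))
        fz = wake_session.eeg.channel_labels.index("Fz")
        avg = es.data[es.kept][:, fz, :].mean(axis=0)
        post = (es.times > 0.05) & (es.times < 0.5)
        t_peak = es.times[post][np.argmax(np.abs(avg[post]))]
        assert abs(t_peak - 0.20) <= 0.01  # P2 component of the injected kernel


class TestLabelEpochs:
    def make_epochs(self, onsets, rate=500.0):
        eeg = make_eeg(np.zeros((1, int(400 * rate))), rate=rate)
        return preproc.epoch(eeg, pd.DataFrame({"onset_sample": onsets}), (-1.0, 2.0))

    def test_stage_mapping(self):
        hyp = Hypnogram(stages=["W"] * 15 + ["N3", "R", "N1"])
        es = self.make_epochs([int(305 * 500), int(100 * 500), int(325 * 500), int(345 * 500)])
        es = preproc.label_epochs(es, hyp)
        assert es.vigilance[0] == "NREM"  # 305 s -> epoch 15 = N3
        assert es.vigilance[1] == "wake"
        assert es.vigilance[2] == "REM"
        assert not es.kept[3] and es.reject_reason[3] == "N1"

    def test_half_open_boundary(self):
        hyp = Hypnogram(stages=["W"] * 15 + ["N2"] * 5)
        es = self.make_epochs([int(299.99 * 500), int(300.0 * 500)])
        es = preproc.label_epochs(es, hyp)
        assert es.vigilance[0] == "wake"  # epoch 14
        assert es.vigilance[1] == "NREM"  # epoch 15, [300, 320)

    def test_unscored_onset_rejected(self):
        hyp = Hypnogram(stages=["W"] * 2)
        es = self.make_epochs([int(300 * 500)])
        es = preproc.label_epochs(es, hyp)
        assert not es.kept[0] and es.reject_reason[0] == "unscored"

    def test_generator_labels_agree(self, nrem_session):
        es = preproc.epoch(nrem_session.eeg, nrem_session.events, (-1.0, 2.0))
        es = preproc.label_epochs(es, nrem_session.hypnogram)
        want = nrem_session.truth["stage"].map(
            {"W": "wake", "N2": "NREM", "N3": "NREM", "R": "REM"})
        assert list(es.vigilance) == list(want)


class TestRejectArtifacts:
    def test_amplitude_and_flat(self, rng):
        data = rng.standard_normal((3, 2, 100)) * 10
        data[1, 0, 50] = 500.0
        data[2] = 0.05
        from screamsleep.containers import EpochSet
        es = EpochSet(data=data, times=np.linspace(-0.1, 0.1, 100), rate=500.0,
                      channel_labels=["a", "b"], events=pd.DataFrame({"onset_sample": [0, 1, 2]}),
                      window=(-0.1, 0.1))
        es = preproc.reject_artifacts(es, abs_threshold=300.0, flat_threshold=1.0)
        assert es.kept[0]
        assert not es.kept[1] and es.reject_reason[1] == "amplitude"
        assert not es.kept[2] and es.reject_reason[2] == "flat"
        assert es.qc_fail  # fewer than 100 clean trials

    def test_generator_artifacts_exactly_flagged(self, stimulus_set):
        from screamsleep.synthdata import SessionConfig, generate_session

        cfg = SessionConfig(wake_blocks=0, nrem_blocks=2, artifact_fraction=0.1, seed=13)
        sess = generate_session(cfg, stimulus_set, 0)
        es = preproc.epoch(sess.eeg, sess.events, (-1.0, 2.0))
        es = preproc.reject_artifacts(es)
        assert np.array_equal(~es.kept, sess.truth["artifact"].to_numpy())

    def test_bookkeeping_conserved(self, nrem_session):
        es = preproc.epoch(nrem_session.eeg, nrem_session.events, (-1.0, 2.0))
        es = preproc.label_epochs(es, nrem_session.hypnogram)
        es = preproc.reject_artifacts(es)
        qc = es.qc_counts()
        assert qc["n_kept"] + sum(qc["rejected"].values()) == qc["n_events"]


class TestBaselineCorrect:
    def test_constant_trial_becomes_zero(self):
        from screamsleep.containers import EpochSet
        es = EpochSet(data=np.full((1, 1, 1501), 7.0), times=np.linspace(-1, 2, 1501),
                      rate=500.0, channel_labels=["a"],
                      events=pd.DataFrame({"onset_sample": [0]}), window=(-1.0, 2.0))
        es = preproc.baseline_correct(es, (-0.5, 0.0))
        assert np.allclose(es.data, 0.0)

    def test_ramp_subtracts_quarter(self):
        from screamsleep.containers import EpochSet
        times = np.linspace(-1, 2, 1501)
        es = EpochSet(data=times[None, None, :].copy(), times=times, rate=500.0,
                      channel_labels=["a"], events=pd.DataFrame({"onset_sample": [0]}),
                      window=(-1.0, 2.0))
        es = preproc.baseline_correct(es, (-0.5, 0.0))
        # baseline mean of t over [-0.5, 0] is -0.25, so t=0.5 maps to 0.75
        assert np.isclose(es.data[0, 0, 750], 0.75, atol=1e-3)

    def test_window_must_precede_onset(self):
        from screamsleep.containers import EpochSet
        es = EpochSet(data=np.zeros((1, 1, 11)), times=np.linspace(-1, 1, 11), rate=5.0,
                      channel_labels=["a"], events=pd.DataFrame({"onset_sample": [0]}),
                      window=(-1.0, 1.0))
        with pytest.raises(ValueError):
            preproc.baseline_correct(es, (0.0, 0.5))
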