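"""Morlet bank, wavelet transform, dB power, ITPC and band averaging."""

import numpy as np
import pandas as pd
import pytest

from screamsleep import timefreq
from screamsleep.containers import ContinuousEEG
from screamsleep.timefreq import (
    BANDS,
    ITPCMap,
    TFRComplex,
    TFRPower,
    band_average,
    baseline_power,
    build_wavelet_bank,
    fwhm_schedule,
    itpc,
    power_db,
    tfr_transform,
)

RATE = 500.0


def make_tfr(values, rate=50.0, freqs=None, t0=-2.0):
    values = np.asarray(values, dtype=complex)
    n_t = values.shape[-1]
    freqs = np.arange(1.0, 1.0 + values.shape[-2]) if freqs is None else np.asarray(freqs)
    return TFRComplex(values=values, times=t0 + np.arange(n_t) / rate, freqs=freqs,
                      rate=rate, valid=np.ones(values.shape[0], dtype=bool))


def continuous(x):
    return ContinuousEEG(data=np.atleast_2d(x), rate=RATE,
                         channel_labels=["Cz"][: np.atleast_2d(x).shape[0]])


def measured_fwhm(kernel, rate):
    env = np.abs(kernel)
    half = env.max() / 2
    above = np.flatnonzero(env >= half)
    return (above[-1] - above[0]) / rate


class TestWaveletBank:
    def test_fwhm_schedule_endpoints_and_midpoint(self):
        assert fwhm_schedule(1.0) == 1.0
        assert np.isclose(fwhm_schedule(30.0), 0.33)
        assert np.isclose(fwhm_schedule(15.5), 0.665)

    @pytest.mark.parametrize("f,expected", [(1.0, 1.0), (15.5, 0.665), (30.0, 0.33)])
    def test_measured_envelope_fwhm(self, f, expected):
        bank = build_wavelet_bank(RATE, freqs=[f])
        assert abs(measured_fwhm(bank.kernels[0], RATE) - expected) / expected < 0.02

    def test_30hz_kernel_spans_ten_cycles(self):
        # 0.33 s x 30 Hz = 9.9 cycles within the FWHM
        assert 9.5 < fwhm_schedule(30.0) * 30.0 < 10.0

    def test_unit_energy(self):
        bank = build_wavelet_bank(RATE)
        for k in bank.kernels:
            assert np.isclose(np.sum(np.abs(k) ** 2), 1.0)

    def test_rate_too_low_rejected(self):
        with pytest.raises(ValueError):
            build_wavelet_bank(40.0)


class TestTransform:
    def events(self, onsets):
        return pd.DataFrame({"onset_sample": onsets})

    def test_pure_tone_peaks_at_its_frequency_bin(self):
        t = np.arange(6000) / RATE
        eeg = continuous(np.sin(2 * np.pi * 10.0 * t))
        bank = build_wavelet_bank(RATE)
        tfr = tfr_transform(eeg, bank, self.events([3000]), window=(-2.0, 3.0))
        power = np.abs(tfr.values[0, 0]) ** 2
        interior = (tfr.times > -1.0) & (tfr.times < 1.0)
        peak_freqs = tfr.freqs[np.argmax(power[:, interior], axis=0)]
        assert np.all(np.abs(peak_freqs - 10.0) <= 0.5)

    def test_stationary_tone_power_is_time_constant(self):
        t = np.arange(20000) / RATE
        eeg = continuous(np.sin(2 * np.pi * 10.0 * t))
        bank = build_wavelet_bank(RATE, freqs=[10.0])
        tfr = tfr_transform(eeg, bank, self.events([10000]), window=(-2.0, 3.0))
        p = np.abs(tfr.values[0, 0, 0]) ** 2
        assert p.std() / p.mean() < 0.01

    def test_centered_kernel_phase_at_signal_peaks(self):
        t = np.arange(20000) / RATE
        eeg = continuous(np.cos(2 * np.pi * 5.0 * t))
        bank = build_wavelet_bank(RATE, freqs=[5.0])
        tfr = tfr_transform(eeg, bank, self.events([10000]), window=(-2.0, 3.0), decim=10)
        # with onset at a signal peak (10000/500*5 = 100 cycles), phase at t=0 is 0
        i0 = np.flatnonzero(np.isclose(tfr.times, 0.0))[0]
        assert abs(np.angle(tfr.values[0, 0, 0, i0])) < 0.05

    def test_amplitude_step_transition_width_matches_kernel_fwhm(self):
        # oracle: a Gaussian-smoothed amplitude step rises from 25% to 75%
        # of its jump over 1.349 envelope SDs = 0.573 FWHM
        f = 6.0
        t = np.arange(40000) / RATE
        amp = np.where(t < 40.0, 1.0, 2.0)
        eeg = continuous(amp * np.sin(2 * np.pi * f * t))
        bank = build_wavelet_bank(RATE, freqs=[f])
        tfr = tfr_transform(eeg, bank, self.events([20000]), window=(-2.0, 3.0), decim=1)
        env = np.abs(tfr.values[0, 0, 0])
        lo, hi = env[tfr.times < -1.0].mean(), env[tfr.times > 1.0].mean()
        t25 = tfr.times[np.argmax(env > lo + 0.25 * (hi - lo))]
        t75 = tfr.times[np.argmax(env > lo + 0.75 * (hi - lo))]
        expected = 0.573 * fwhm_schedule(f)
        assert abs((t75 - t25) - expected) / expected < 0.15

    def test_edge_trials_flagged_invalid(self, rng):
        eeg = continuous(rng.standard_normal(4000))
        bank = build_wavelet_bank(RATE, freqs=[6.0])
        tfr = tfr_transform(eeg, bank, self.events([500, 2500]), window=(-2.0, 3.0))
        assert not tfr.valid[0]
        assert np.all(tfr.values[0] == 0)

    def test_decimation_matches_full_rate_transform(self, rng):
        x = rng.standard_normal(8000)
        eeg = continuous(x)
        bank = build_wavelet_bank(RATE, freqs=[7.0])
        full = tfr_transform(eeg, bank, self.events([4000]), window=(-2.0, 3.0), decim=1)
        dec = tfr_transform(eeg, bank, self.events([4000]), window=(-2.0, 3.0), decim=10)
        # tiny differences stem from the slightly different FFT padding grid
        assert np.allclose(full.values[0, 0, 0, ::10], dec.values[0, 0, 0],
                           rtol=1e-5, atol=1e-8)


class TestPowerDb:
    def test_known_values(self):
        tfr = make_tfr(np.full((1, 1, 1, 3), 1.0))
        assert np.allclose(power_db(tfr).values, 0.0)
        tfr = make_tfr(np.full((1, 1, 1, 1), np.sqrt(np.e)))
        assert np.allclose(power_db(tfr).values, 10.0)
        tfr = make_tfr(np.full((1, 1, 1, 1), np.sqrt(2.0)))
        assert np.allclose(power_db(tfr).values, 6.9315, atol=1e-4)

    def test_log10_variant_rescales_by_ln10(self):
        tfr = make_tfr(np.full((1, 1, 1, 1), np.sqrt(2.0)))
        assert np.isclose(power_db(tfr, db_log10=True).values[0, 0, 0, 0] * np.log(10),
                          power_db(tfr).values[0, 0, 0, 0])


class TestBaselinePower:
    def test_constant_map_zeroed(self):
        p = TFRPower(values=np.full((2, 1, 1, 100), 3.0), times=np.linspace(-2, 3, 100),
                     freqs=np.array([5.0]), rate=20.0)
        assert np.allclose(baseline_power(p).values, 0.0)

    def test_step_map_arithmetic(self):
        times = np.linspace(-2, 3, 251)
        vals = np.where(times > 0, 5.0, 3.0)[None, None, None, :]
        p = TFRPower(values=vals, times=times, freqs=np.array([5.0]), rate=50.0)
        out = baseline_power(p, (-0.5, 0.0)).values[0, 0, 0]
        assert np.allclose(out[times > 0], 2.0)
        assert np.allclose(out[(times >= -0.5) & (times <= 0)], 0.0)


class TestITPC:
    def phasors(self, phases):
        z = np.exp(1j * np.asarray(phases, dtype=float))
        return make_tfr(z.reshape(-1, 1, 1, 1))

    def test_identical_phases_give_one(self):
        m = itpc(self.phasors([0.7, 0.7, 0.7]), baseline=None)
        assert np.isclose(m.raw[0, 0, 0], 1.0)

    def test_antipodal_pair_gives_zero(self):
        m = itpc(self.phasors([0.3, 0.3 + np.pi]), baseline=None)
        assert np.isclose(m.raw[0, 0, 0], 0.0, atol=1e-12)

    def test_quarter_turn_example(self):
        m = itpc(self.phasors([0.0, np.pi / 2, np.pi / 2, np.pi / 2]), baseline=None)
        assert np.isclose(m.raw[0, 0, 0], np.sqrt(10) / 4)

    def test_amplitude_invariance(self, rng):
        phases = rng.uniform(0, 2 * np.pi, size=(20, 1, 1, 5))
        amps = rng.uniform(0.1, 10, size=(20, 1, 1, 5))
        a = itpc(make_tfr(np.exp(1j * phases)), baseline=None)
        b = itpc(make_tfr(amps * np.exp(1j * phases)), baseline=None)
        assert np.allclose(a.raw, b.raw)

    def test_rayleigh_expectation_for_uniform_phases(self, rng):
        n = 20
        draws = np.abs(np.exp(1j * rng.uniform(0, 2 * np.pi, size=(1000, n))).mean(axis=1))
        assert abs(draws.mean() - np.sqrt(np.pi / (4 * n))) / np.sqrt(np.pi / (4 * n)) < 0.10

    def test_baseline_subtraction_bounds(self, rng):
        z = np.exp(1j * rng.uniform(0, 2 * np.pi, size=(10, 2, 3, 251)))
        tfr = make_tfr(z)
        m = itpc(tfr, baseline=(-1.0, 0.0))
        assert np.all(m.raw >= 0) and np.all(m.raw <= 1)
        assert np.all(m.values >= -1) and np.all(m.values <= 1)
        base = (tfr.times >= -1) & (tfr.times <= 0)
        assert np.allclose(m.values[..., base].mean(axis=-1), 0.0, atol=1e-12)

    def test_needs_two_trials(self):
        with pytest.raises(ValueError):
            itpc(self.phasors([0.0]), baseline=None)


class TestBandAverage:
    def test_theta_uses_five_bins(self):
        lo, hi = BANDS["theta"]
        assert np.sum((np.arange(1, 31) >= lo) & (np.arange(1, 31) <= hi)) == 5

    def test_arithmetic_mean_over_bins(self):
        vals = np.zeros((1, 1, 30, 4))
        vals[0, 0, 3:8, :] = np.array([0, 1, 2, 3, 4])[:, None]  # bins 4..8
        p = TFRPower(values=vals, times=np.arange(4) / 50, freqs=np.arange(1.0, 31.0), rate=50.0)
        assert np.allclose(band_average(p, "theta").values, 2.0)

    def test_itpc_map_axis(self, rng):
        m = ITPCMap(values=rng.random((3, 30, 5)), raw=rng.random((3, 30, 5)),
                    times=np.arange(5) / 50, freqs=np.arange(1.0, 31.0), n_trials=10)
        out = band_average(m, "sigma")
        assert out.values.shape == (3, 5)

    def test_unknown_band_rejected(self):
        p = TFRPower(values=np.zeros((1, 1, 30, 2)), times=np.arange(2) / 50,
                     freqs=np.arange(1.0, 31.0), rate=50.0)
        with pytest.raises(ValueError):
            band_average(p, "gamma")


class TestAgainstMNE:
    def test_itpc_matches_mne_morlet_implementation(self, rng):
        """Dual-route check: our continuous-convolution ITPC vs mne's
        epoch-wise Morlet ITC with matched FWHM, away from epoch edges."""
        mne = pytest.importorskip("mne")
        f = 6.0
        n_trials, n_samp = 30, 5000
        sig = np.sin(2 * np.pi * f * np.arange(n_samp) / RATE)
        trials = 0.5 * sig + rng.standard_normal((n_trials, n_samp))
        # ours: concatenate trials into a continuous record with gaps
        gap = np.zeros(2000)
        pieces, onsets, pos = [], [], 0
        for tr in trials:
            pieces += [tr, gap]
            onsets.append(pos + n_samp // 2)
            pos += n_samp + gap.size
        eeg = continuous(np.concatenate(pieces))
        bank = build_wavelet_bank(RATE, freqs=[f])
        tfr = tfr_transform(eeg, bank, pd.DataFrame({"onset_sample": onsets}),
                            window=(-2.0, 3.0), decim=10)
        ours = itpc(tfr, baseline=None).raw[0, 0]
        # mne: same FWHM via n_cycles = 2*pi*f*sigma_t
        sigma_t = fwhm_schedule(f) / (2 * np.sqrt(2 * np.log(2)))
        out = mne.time_frequency.tfr_array_morlet(
            trials[:, None, :], sfreq=RATE, freqs=[f], n_cycles=[2 * np.pi * f * sigma_t],
            output="itc", zero_mean=False, verbose="error")[0, 0]
        theirs = out[n_samp // 2 - 500 : n_samp // 2 + 500 : 10]  # -1..1 s at 50 Hz
        ours_win = ours[(tfr.times >= -1.0) & (tfr.times < 1.0)]
        center = slice(20, 80)  # avoid epoch-edge effects in the mne route
        assert ours_win.size == theirs.size == 100
        assert np.allclose(ours_win[center], theirs[center], atol=0.03)
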