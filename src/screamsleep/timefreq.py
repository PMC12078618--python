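"""Morlet time-frequency decomposition, dB power, ITPC and band averaging.

The decomposition follows the FWHM parameterization of Morlet wavelets:
30 frequency bins from 1 to 30 Hz (1 Hz steps) whose Gaussian-envelope full
width at half maximum decreases linearly from 1 s at 1 Hz to 0.33 s at
30 Hz (1 cycle at 1 Hz, ~10 cycles at 30 Hz).  Convolution runs on the
*continuous* signal; trials are cut afterwards from −2 to 3 s around each
onset and decimated by 10 (the analytic wavelet output is band-limited, so
plain subsampling is safe).

Power uses the 10·ln(|z|²) "decibel" convention by default (a
``db_log10`` switch gives the conventional 10·log10; the two differ only by
the constant factor ln 10).  ITPC is the resultant length of unit phasors
across trials:  ITPC(f, t) = |Σ_k exp(i·φ_k(f, t))| / N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import next_fast_len

__all__ = [
    "BANDS",
    "WaveletBank",
    "TFRComplex",
    "TFRPower",
    "ITPCMap",
    "BandTimecourse",
    "fwhm_schedule",
    "build_wavelet_bank",
    "tfr_transform",
    "power_db",
    "baseline_power",
    "itpc",
    "band_average",
]

#: Canonical frequency bands of sleep research, inclusive on the 1-Hz grid.
BANDS = {"delta": (1, 4), "theta": (4, 8), "sigma": (12, 15)}

FWHM_AT_1HZ = 1.0  # s
FWHM_AT_30HZ = 0.33  # s
_FWHM_SLOPE = (FWHM_AT_1HZ - FWHM_AT_30HZ) / 29.0


def fwhm_schedule(freq: np.ndarray | float) -> np.ndarray | float:
    """Envelope FWHM (s) at ``freq`` Hz: linear from 1 s (1 Hz) to 0.33 s (30 Hz)."""
    return FWHM_AT_1HZ - (np.asarray(freq, dtype=float) - 1.0) * _FWHM_SLOPE


def _sigma_t(freq: float) -> float:
    return float(fwhm_schedule(freq)) / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class WaveletBank:
    """Complex Morlet kernels, one per frequency bin, unit energy each."""

    freqs: np.ndarray
    fwhms: np.ndarray
    kernels: list[np.ndarray]
    rate: float

    def kernel_times(self, i: int) -> np.ndarray:
        n = self.kernels[i].size
        return (np.arange(n) - n // 2) / self.rate


@dataclass
class TFRComplex:
    """Complex wavelet coefficients, (n_trials, n_channels, n_freqs, n_times)."""

    values: np.ndarray
    times: np.ndarray
    freqs: np.ndarray
    rate: float  # effective (decimated) sampling rate
    valid: np.ndarray  # per-trial flag: window clear of recording edges


@dataclass
class TFRPower:
    """Power in dB (10·ln by default), same layout as :class:`TFRComplex`."""

    values: np.ndarray
    times: np.ndarray
    freqs: np.ndarray
    rate: float
    baseline_window: tuple[float, float] | None = None


@dataclass
class ITPCMap:
    """Inter-trial phase coherence, (n_channels, n_freqs, n_times).

    ``raw`` is the resultant length in [0, 1]; ``values`` is ``raw`` after
    subtraction of the pre-stimulus baseline mean (hence in [-1, 1]), or
    identical to ``raw`` when no baseline was applied.
    """

    values: np.ndarray
    raw: np.ndarray
    times: np.ndarray
    freqs: np.ndarray
    n_trials: int
    baseline_window: tuple[float, float] | None = None


@dataclass
class BandTimecourse:
    band: str
    values: np.ndarray  # source units, frequency axis averaged out
    times: np.ndarray


def build_wavelet_bank(rate: float, freqs=None) -> WaveletBank:
    """Construct the Morlet bank on the 1–30 Hz, 1-Hz grid.

    Kernels are Gaussian-envelope complex exponentials truncated at ±5
    envelope SDs and normalized to unit energy (Σ|k|² = 1), so relative dB
    changes are independent of the normalization choice.
    """
    if rate < 60:
        raise ValueError("sampling rate must be at least twice the top frequency (30 Hz)")
    freqs = np.arange(1.0, 31.0) if freqs is None else np.asarray(freqs, dtype=float)
    fwhms = np.asarray(fwhm_schedule(freqs))
    kernels = []
    for f, fw in zip(freqs, fwhms):
        st = fw / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        half = int(np.ceil(5.0 * st * rate))
        t = np.arange(-half, half + 1) / rate
        k = np.exp(2j * np.pi * f * t) * np.exp(-0.5 * (t / st) ** 2)
        k /= np.sqrt(np.sum(np.abs(k) ** 2))
        kernels.append(k)
    return WaveletBank(freqs=freqs, fwhms=fwhms, kernels=kernels, rate=rate)


def tfr_transform(eeg, bank: WaveletBank, events, window: tuple[float, float] = (-2.0, 3.0),
                  decim: int = 10, freqs=None) -> TFRComplex:
    """Wavelet-convolve the continuous signal, then epoch and decimate.

    The convolution is evaluated in the frequency domain: each kernel's
    transfer function is an analytic Gaussian centered on its frequency, so
    the filter has exactly zero phase (centered kernel).  ``freqs`` may
    restrict the decomposition to a subset of the bank's grid (e.g. one
    band) to save time.

    Trials whose window, padded by the widest kernel FWHM, leaves the
    recording are flagged invalid rather than dropped.
    """
    if eeg.rate != bank.rate:
        raise ValueError("bank was built for a different sampling rate")
    rate = eeg.rate
    if freqs is None:
        sel = np.arange(bank.freqs.size)
    else:
        sel = np.array([int(np.flatnonzero(bank.freqs == f)[0]) for f in np.asarray(freqs)])
    use_freqs = bank.freqs[sel]

    lo, hi = window
    n_full = int(round((hi - lo) * rate)) + 1
    start_off = int(round(lo * rate))
    offsets = start_off + np.arange(0, n_full, decim)
    times = offsets / rate

    onsets = np.asarray(
        events["onset_sample"] if hasattr(events, "columns") else events, dtype=int
    )
    n_trials = onsets.size
    data = eeg.data
    n_ch, n_samp = data.shape

    guard = int(np.ceil(bank.fwhms[sel].max() * rate))
    valid = (onsets + offsets[0] - guard >= 0) & (onsets + offsets[-1] + guard < n_samp)

    max_half = max(bank.kernels[i].size // 2 for i in sel)
    n_pad = decim * next_fast_len(int(np.ceil((n_samp + 2 * max_half) / decim)))
    m = n_pad // decim
    X = np.fft.fft(data, n_pad, axis=1)

    out = np.empty((n_trials, n_ch, sel.size, times.size), dtype=complex)
    n_t = times.size

    # The wavelet's transfer function is a narrow Gaussian band, so the
    # convolution output is synthesized only on the samples actually kept:
    # folding the band into an n_pad/decim spectrum and inverting gives
    # exactly every decim-th sample of the full convolution (subsampling
    # identity), per onset residue modulo decim.
    start_off = offsets[0]
    residues = np.unique((onsets + start_off) % decim)

    for j, f in enumerate(use_freqs):
        st = _sigma_t(f)
        sf = 1.0 / (2.0 * np.pi * st)
        half_bw = 6.0 * sf
        j_lo = int(np.ceil((f - half_bw) * n_pad / rate))
        j_hi = int(np.floor((f + half_bw) * n_pad / rate))
        bins = np.arange(j_lo, j_hi + 1)
        nu = bins * rate / n_pad
        g = np.exp(-2.0 * (np.pi * st) ** 2 * (nu - f) ** 2)
        # unit-energy normalization in the frequency domain (Parseval)
        g *= np.sqrt(n_pad / np.sum(g**2))
        V = X[:, bins % n_pad] * g[None, :]
        dest = bins % m
        for r in residues:
            shift = np.exp(2j * np.pi * bins * (r / n_pad))
            Q = np.zeros((n_ch, m), dtype=complex)
            # the band is narrower than m, so it lands in <= 2 contiguous runs
            cuts = np.flatnonzero(np.diff(dest) != 1)
            seg_starts = np.concatenate(([0], cuts + 1))
            seg_stops = np.concatenate((cuts + 1, [dest.size]))
            Vr = V * shift[None, :]
            for a, b in zip(seg_starts, seg_stops):
                Q[:, dest[a] : dest[a] + (b - a)] += Vr[:, a:b]
            y_r = np.fft.ifft(Q, axis=1) / decim  # == y[k*decim + r] for all k
            for i in np.flatnonzero((onsets + start_off) % decim == r):
                n0 = (onsets[i] + start_off - r) // decim
                if 0 <= n0 and n0 + n_t <= m:
                    out[i, :, j, :] = y_r[:, n0 : n0 + n_t]
                else:
                    out[i, :, j, :] = 0.0
                    valid[i] = False

    out[~valid] = 0.0
    return TFRComplex(values=out, times=times, freqs=use_freqs, rate=rate / decim, valid=valid)


def power_db(tfr: TFRComplex, db_log10: bool = False) -> TFRPower:
    """10·ln(|z|²) power (or 10·log10 with ``db_log10``), floored at tiny."""
    p = np.abs(tfr.values) ** 2
    p = np.maximum(p, np.finfo(float).tiny)
    vals = 10.0 * (np.log10(p) if db_log10 else np.log(p))
    return TFRPower(values=vals, times=tfr.times, freqs=tfr.freqs, rate=tfr.rate)


def _window_mask(times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    mask = (times >= window[0]) & (times <= window[1])
    if not mask.any():
        raise ValueError("window contains no time samples")
    return mask


def baseline_power(p: TFRPower, window: tuple[float, float] = (-0.5, 0.0)) -> TFRPower:
    """Subtract the mean power in ``window`` per trial, channel and frequency."""
    mask = _window_mask(p.times, window)
    vals = p.values - p.values[..., mask].mean(axis=-1, keepdims=True)
    return TFRPower(values=vals, times=p.times, freqs=p.freqs, rate=p.rate,
                    baseline_window=window)


def itpc(tfr: TFRComplex, baseline: tuple[float, float] | None = (-1.0, 0.0),
         trials=None) -> ITPCMap:
    """Inter-trial phase coherence across trials, optionally baseline-corrected.

    Amplitude information is discarded (unit phasors), so the measure is
    invariant to per-trial amplitude scaling.  ``trials`` may select a
    subset (e.g. one condition); ITPC is a first-order statistic computed
    across the trials of one participant and condition.
    """
    vals = tfr.values if trials is None else tfr.values[np.asarray(trials)]
    if vals.shape[0] < 2:
        raise ValueError("ITPC needs at least 2 trials")
    mod = np.abs(vals)
    phasors = vals / np.maximum(mod, np.finfo(float).tiny)
    raw = np.abs(phasors.mean(axis=0))
    if baseline is None:
        corrected = raw
    else:
        mask = _window_mask(tfr.times, baseline)
        corrected = raw - raw[..., mask].mean(axis=-1, keepdims=True)
    return ITPCMap(values=corrected, raw=raw, times=tfr.times, freqs=tfr.freqs,
                   n_trials=vals.shape[0], baseline_window=baseline)


def band_average(x, band: str) -> BandTimecourse:
    """Unweighted mean over the band's inclusive integer frequency bins.

    Works on :class:`TFRPower` (frequency axis 2) and :class:`ITPCMap`
    (frequency axis 1); e.g. theta = bins {4, 5, 6, 7, 8}.
    """
    if band not in BANDS:
        raise ValueError(f"unknown band {band!r}; expected one of {sorted(BANDS)}")
    lo, hi = BANDS[band]
    mask = (x.freqs >= lo) & (x.freqs <= hi)
    if not mask.any():
        raise ValueError(f"band {band} has no bins on this frequency grid")
    axis = 2 if isinstance(x, TFRPower) else 1
    vals = np.compress(mask, x.values, axis=axis).mean(axis=axis)
    return BandTimecourse(band=band, values=vals, times=x.times)
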