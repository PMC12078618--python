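"""Acoustic feature extraction for vocal stimuli.

Screamed vocalizations differ from neutral ones chiefly by *roughness*:
energy in fast amplitude modulations (30–150 Hz) of the waveform envelope.
This module quantifies roughness from the modulation power spectrum (MPS),
the 2-D Fourier transform of a short-window spectrogram, and estimates the
fundamental frequency (F0) with a YIN-style difference function.  It also
applies the standard stimulus normalizations: fixed duration, quarter-sine
onset/offset ramps, and RMS equalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.io import wavfile

__all__ = [
    "AudioClip",
    "Spectrogram",
    "ModulationPowerSpectrum",
    "AcousticFeatures",
    "spectrogram",
    "modulation_power_spectrum",
    "roughness",
    "estimate_f0",
    "normalize_clip",
    "extract_features",
    "NoVoicedFramesError",
]

ROUGHNESS_BAND = (30.0, 150.0)  # Hz, temporal-modulation band defining roughness


class NoVoicedFramesError(RuntimeError):
    """Raised when no frame of a clip shows detectable periodicity."""


@dataclass
class AudioClip:
    """Mono audio samples at a fixed sampling rate.

    Parameters
    ----------
    samples : ndarray
        Amplitude sequence (float).
    rate : float
        Sampling rate in Hz, > 0.
    """

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))

    @classmethod
    def from_wav(cls, path) -> "AudioClip":
        rate, data = wavfile.read(path)
        data = np.asarray(data)
        if data.ndim > 1:
            data = data.mean(axis=1)
        if np.issubdtype(data.dtype, np.integer):
            data = data / float(np.iinfo(data.dtype).max)
        return cls(samples=data.astype(float), rate=float(rate))

    def to_wav(self, path) -> None:
        """Write 16-bit PCM mono WAV (clipped at full scale)."""
        scaled = np.clip(self.samples, -1.0, 1.0)
        wavfile.write(path, int(round(self.rate)), (scaled * 32767).astype(np.int16))


@dataclass
class Spectrogram:
    """Magnitude spectrogram with its axes."""

    values: np.ndarray  # (n_freqs, n_frames), magnitude >= 0
    freqs: np.ndarray  # Hz
    times: np.ndarray  # s, frame centers
    frame_rate: float  # Hz = 1 / hop


@dataclass
class ModulationPowerSpectrum:
    """2-D modulation power over (spectral scale) x (temporal rate)."""

    power: np.ndarray  # (n_scales, n_rates), >= 0
    rates: np.ndarray  # temporal modulation, Hz (both signs)
    scales: np.ndarray  # spectral modulation, cycles/Hz


@dataclass
class AcousticFeatures:
    stimulus_id: str
    condition: str
    roughness: float
    f0: float


def spectrogram(clip: AudioClip, window_len: float = 0.010, hop: float | None = None) -> Spectrogram:
    """Short-window magnitude spectrogram.

    The defaults (10 ms Hann window, 640 Hz frame rate) are chosen so that
    temporal modulations up to 150 Hz remain resolvable in the subsequent
    modulation power spectrum; long windows would low-pass the envelope and
    erase the roughness band.
    """
    nperseg = int(round(window_len * clip.rate))
    if nperseg < 2:
        raise ValueError("window shorter than two samples")
    if clip.samples.size < nperseg:
        raise ValueError("clip shorter than one analysis window")
    if hop is None:
        hop_samples = max(1, int(round(clip.rate / 640.0)))
    else:
        if hop <= 0:
            raise ValueError("hop must be positive")
        hop_samples = max(1, int(round(hop * clip.rate)))
    freqs, times, mag = sps.spectrogram(
        clip.samples,
        fs=clip.rate,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg - hop_samples,
        mode="magnitude",
        detrend=False,
    )
    return Spectrogram(values=mag, freqs=freqs, times=times, frame_rate=clip.rate / hop_samples)


def modulation_power_spectrum(spec: Spectrogram, log_compress: bool = True) -> ModulationPowerSpectrum:
    """Modulation power spectrum: 2-D Fourier power of the spectrogram.

    The magnitude spectrogram is log-compressed (with a floor relative to
    its maximum, making the result gain-invariant), mean-subtracted, and
    transformed with an orthonormal 2-D FFT, so that total MPS power equals
    the total squared deviation of the compressed spectrogram (Parseval).

    Raises
    ------
    ValueError
        If the frame rate cannot represent 150 Hz temporal modulations.
    """
    S = spec.values
    if S.shape[0] < 2 or S.shape[1] < 2:
        raise ValueError("spectrogram must have at least 2 frequency rows and 2 frames")
    if spec.frame_rate < 2 * ROUGHNESS_BAND[1]:
        raise ValueError(
            f"frame rate {spec.frame_rate:.0f} Hz cannot resolve modulations up to "
            f"{ROUGHNESS_BAND[1]:.0f} Hz; use a smaller hop"
        )
    if log_compress:
        peak = S.max()
        if peak == 0:
            X = np.zeros_like(S)
        else:
            X = np.log(S + 1e-6 * peak) - np.log(1e-6 * peak)
    else:
        X = S
    X = X - X.mean()
    F = np.fft.fft2(X, norm="ortho")
    power = np.abs(F) ** 2
    rates = np.fft.fftfreq(S.shape[1], d=1.0 / spec.frame_rate)
    df = spec.freqs[1] - spec.freqs[0]
    scales = np.fft.fftfreq(S.shape[0], d=df)
    return ModulationPowerSpectrum(power=power, rates=rates, scales=scales)


def roughness(mps: ModulationPowerSpectrum, band: tuple[float, float] = ROUGHNESS_BAND) -> float:
    """Roughness in a.u.: log10 mean normalized modulation power in 30–150 Hz.

    Both signs of the temporal-modulation axis are pooled.  The power matrix
    is normalized by its total before averaging, so the measure is a relative
    (gain-invariant) log quantity.
    """
    lo, hi = band
    if mps.rates.max() < hi:
        raise ValueError("temporal-modulation axis does not cover the requested band")
    mask = (np.abs(mps.rates) >= lo) & (np.abs(mps.rates) <= hi)
    if not mask.any():
        raise ValueError("empty modulation band")
    total = mps.power.sum()
    if total == 0:
        return float("-inf")
    norm = mps.power / total
    return float(np.log10(norm[:, mask].mean()))


def clip_roughness(clip: AudioClip) -> float:
    """Convenience: roughness of a clip via spectrogram -> MPS -> band average."""
    return roughness(modulation_power_spectrum(spectrogram(clip)))


def _frame_f0(frame: np.ndarray, rate: float, tau_min: int, tau_max: int,
              threshold: float = 0.25) -> float | None:
    """YIN-style F0 of one frame, or None if unvoiced.

    Uses the cumulative-mean-normalized difference function (CMNDF) computed
    via FFT autocorrelation, absolute-threshold tau selection and parabolic
    interpolation of the minimum.
    """
    n = frame.size
    frame = frame - frame.mean()
    if not frame.any():
        return None
    # difference function d(tau) = sum_{t<W} (x[t] - x[t+tau])^2 with a fixed
    # integration window W = n - tau_max, cross term via FFT correlation
    w = n - tau_max
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    fw = np.fft.rfft(frame[:w], nfft)
    fx = np.fft.rfft(frame, nfft)
    cross = np.fft.irfft(np.conj(fw) * fx, nfft)[: tau_max + 1]
    cumsq = np.concatenate(([0.0], np.cumsum(frame**2)))
    e0 = cumsq[w] - cumsq[0]
    e_tau = cumsq[np.arange(tau_max + 1) + w] - cumsq[np.arange(tau_max + 1)]
    d = e0 + e_tau - 2 * cross
    d = np.maximum(d, 0.0)
    taus = np.arange(1, tau_max + 1)
    cmndf = np.ones(tau_max + 1)
    running = np.cumsum(d[1:])
    cmndf[1:] = d[1:] * taus / np.where(running > 0, running, 1.0)
    lo = max(tau_min, 2)
    if lo >= tau_max:
        return None
    seg = cmndf[lo:tau_max]
    below = np.flatnonzero(seg < threshold)
    if below.size:
        i = below[0]
        # descend to the local minimum following the first threshold crossing
        while i + 1 < seg.size and seg[i + 1] < seg[i]:
            i += 1
        tau = lo + i
    else:
        tau = lo + int(np.argmin(seg))
        if seg.min() > 0.35:  # aperiodicity too high: unvoiced
            return None
    # subharmonic disambiguation: deep amplitude modulation carves a
    # spurious dip at the envelope period; prefer the shortest integer
    # divisor of the chosen period whose own dip is credible
    for k in range(6, 1, -1):
        cand = int(round(tau / k))
        if cand < max(tau_min, 2):
            continue
        lo_c = max(cand - 2, 1)
        seg_c = cmndf[lo_c : cand + 3]
        if seg_c.size and seg_c.min() < 0.35:
            tau = lo_c + int(np.argmin(seg_c))
            break
    # parabolic interpolation around tau
    if 1 <= tau < tau_max:
        a, b, c = cmndf[tau - 1], cmndf[tau], cmndf[tau + 1]
        denom = a - 2 * b + c
        shift = 0.5 * (a - c) / denom if denom != 0 else 0.0
        tau_refined = tau + np.clip(shift, -1, 1)
    else:
        tau_refined = float(tau)
    return rate / tau_refined


def estimate_f0(clip: AudioClip, fmin: float = 40.0, fmax: float = 1500.0,
                frame_len: float = 0.08, hop: float = 0.01) -> float:
    """Median fundamental frequency over voiced frames, in Hz.

    Difference-function (YIN-style) estimator.  The default 40–1500 Hz search
    range covers high-pitched screams (F0 well above typical speech).

    Raises
    ------
    NoVoicedFramesError
        If no frame is judged voiced (e.g. white noise or silence).
    """
    nyq = clip.rate / 2
    if not (0 < fmin < fmax < nyq):
        raise ValueError("need 0 < fmin < fmax < Nyquist")
    n = int(round(frame_len * clip.rate))
    step = max(1, int(round(hop * clip.rate)))
    tau_min = int(np.floor(clip.rate / fmax))
    tau_max = int(np.ceil(clip.rate / fmin))
    if tau_max >= n // 2:
        raise ValueError("frame too short for the requested fmin")
    if clip.samples.size < n:
        raise ValueError("clip shorter than one analysis frame")
    f0s = []
    for start in range(0, clip.samples.size - n + 1, step):
        f0 = _frame_f0(clip.samples[start : start + n], clip.rate, tau_min, tau_max)
        if f0 is not None and fmin <= f0 <= fmax:
            f0s.append(f0)
    if not f0s:
        raise NoVoicedFramesError("no voiced frame detected")
    return float(np.median(f0s))


def normalize_clip(clip: AudioClip, target_duration: float = 0.75, ramp: float = 0.1,
                   target_rms: float = 0.05) -> AudioClip:
    """Edit a clip to a fixed duration with sine ramps and exact RMS.

    The clip is cropped to ``target_duration``, the first and last ``ramp``
    seconds are shaped by quarter-sine onset/offset envelopes, and the result
    is rescaled to ``target_rms``.
    """
    if target_duration <= 2 * ramp:
        raise ValueError("target_duration must exceed twice the ramp length")
    n = int(round(target_duration * clip.rate))
    if clip.samples.size < n:
        raise ValueError("clip shorter than target duration")
    x = clip.samples[:n].copy()
    nr = int(round(ramp * clip.rate))
    if nr > 0:
        t = np.arange(nr) / nr  # sample k sits at phase k/nr of the quarter period
        env = np.sin(0.5 * np.pi * t)
        x[:nr] *= env
        x[-nr:] *= env[::-1]
    rms = np.sqrt(np.mean(x**2))
    if rms == 0:
        raise ValueError("cannot RMS-normalize a silent clip")
    return AudioClip(samples=x * (target_rms / rms), rate=clip.rate)


def extract_features(clip: AudioClip, stimulus_id: str = "", condition: str = "") -> AcousticFeatures:
    """Roughness and F0 of a single (already normalized) clip."""
    return AcousticFeatures(
        stimulus_id=stimulus_id,
        condition=condition,
        roughness=clip_roughness(clip),
        f0=estimate_f0(clip),
    )
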