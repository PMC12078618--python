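"""Synthetic stimuli and polysomnographic sessions with known ground truth.

The generator builds everything the downstream analysis consumes — a
pitch-matched scream/neutral stimulus set, continuous multichannel EEG with
a 1/f background and spontaneous sleep oscillations, an event table and a
20-s-epoch hypnogram — while recording the exact injected responses so every
stage of the pipeline can be validated against ground truth.

Stimuli are sine-ramped amplitude-modulated harmonic complexes rather than
recorded voices: the analysis consumes only roughness and pitch scalars, and
synthetic clips give full control of both.  "Screams" carry amplitude
modulation in the 30–150 Hz roughness band; "neutral" clips modulate slowly
(prosody-like) or not at all.  Scream/neutral pairs share a carrier F0,
mirroring pitch matching of natural stimulus sets.

Injected neural responses per stimulus, by vigilance state at onset:

* wake — an N1-P2-N2 evoked-potential kernel plus a phase-locked theta burst;
* N2/N3 — the theta burst, an evoked delta (slow-wave-like) deflection, and
  a non-phase-locked sigma (spindle-band) burst at 0.6–1.4 s latency.

The theta burst's across-trial phase concentration is von Mises with
kappa linear in z-scored roughness; sigma and delta amplitudes are linear
in z-scored roughness *in the (10·ln) dB domain*, matching the regression
model the statistics module fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .acoustics import AudioClip, clip_roughness, estimate_f0, normalize_clip
from .containers import CHANNELS_13, ContinuousEEG, Hypnogram

__all__ = [
    "StimulusSpec",
    "StimulusSet",
    "SessionConfig",
    "Session",
    "generate_stimulus_set",
    "generate_session",
    "render_stimulus",
    "pink_noise",
    "SessionTooShortError",
]


class SessionTooShortError(RuntimeError):
    """The configured maximum duration cannot accommodate all events."""


# ---------------------------------------------------------------------------
# stimuli
# ---------------------------------------------------------------------------

@dataclass
class StimulusSpec:
    """Parameters of one synthetic vocalization."""

    stimulus_id: str
    condition: str  # {"scream", "neutral"}
    carrier_f0: float  # Hz
    am_rate: float  # Hz; in the 30–150 Hz roughness band for screams
    am_depth: float  # [0, 1]
    duration: float = 0.75  # s

    def __post_init__(self) -> None:
        if self.condition not in ("scream", "neutral"):
            raise ValueError("condition must be 'scream' or 'neutral'")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not 0 <= self.am_depth <= 1:
            raise ValueError("am_depth must lie in [0, 1]")
        if self.condition == "scream" and not (30 <= self.am_rate <= 150):
            raise ValueError("scream AM rate must lie in the 30–150 Hz roughness band")
        if self.condition == "neutral" and self.am_rate >= 30 and self.am_depth > 0:
            raise ValueError("neutral clips must not carry roughness-band AM")


@dataclass
class StimulusSet:
    """Rendered clips plus per-stimulus acoustic features.

    ``features`` columns: stimulus_id, condition, roughness (a.u., from the
    acoustics module's own MPS estimator applied to the rendered clip),
    f0 (Hz, YIN estimate), plus the generating parameters.
    """

    specs: list[StimulusSpec]
    clips: dict[str, AudioClip]
    features: pd.DataFrame
    rate: float

    @property
    def duration(self) -> float:
        return self.specs[0].duration

    def feature_row(self, stimulus_id: str) -> pd.Series:
        return self.features.set_index("stimulus_id").loc[stimulus_id]


def render_stimulus(spec: StimulusSpec, rate: float = 16000.0, target_rms: float = 0.05,
                    n_harmonics: int = 6) -> AudioClip:
    """Render an AM harmonic complex and apply the standard normalizations
    (750 ms default duration via ``spec.duration``, 100 ms sine ramps, RMS)."""
    n = int(round(spec.duration * rate)) + 16  # headroom before cropping
    t = np.arange(n) / rate
    x = np.zeros(n)
    for h in range(1, n_harmonics + 1):
        fh = h * spec.carrier_f0
        if fh >= 0.45 * rate:
            break
        x += np.cos(2 * np.pi * fh * t) / h
    if spec.am_depth > 0:
        m = spec.am_depth
        x *= (1 + m * np.cos(2 * np.pi * spec.am_rate * t)) / (1 + m)
    return normalize_clip(AudioClip(x, rate), target_duration=spec.duration,
                          ramp=0.1, target_rms=target_rms)


def generate_stimulus_set(n_per_condition: int = 8, seed: int = 0, rate: float = 16000.0,
                          duration: float = 0.75, target_rms: float = 0.05) -> StimulusSet:
    """Pitch-matched scream/neutral pairs spanning a roughness × pitch plane.

    Carrier F0 is drawn log-normally (median ≈ 620 Hz, heavy right tail,
    emulating the high and variable pitch of screamed vocalizations); each
    neutral clip reuses its paired scream's carrier so the conditions differ
    in roughness, not pitch.  Roughness ground truth is taken from the
    acoustics estimator run on the rendered clip, not from ``am_depth``.
    """
    if n_per_condition < 1:
        raise ValueError("n_per_condition must be >= 1")
    rng = np.random.default_rng(seed)
    specs: list[StimulusSpec] = []
    for i in range(n_per_condition):
        f0 = float(np.clip(rng.lognormal(mean=6.43, sigma=0.57), 300.0, 1400.0))
        # keep the AM rate well below the carrier (< 0.18 f0): rough
        # vocalizations modulate slower than their pitch, and faster AM
        # would make the clip's period — hence its pitch — ambiguous
        am_hi = min(110.0, 0.18 * f0)
        specs.append(
            StimulusSpec(
                stimulus_id=f"scr{i:02d}", condition="scream", carrier_f0=f0,
                am_rate=float(rng.uniform(40, am_hi)), am_depth=float(rng.uniform(0.6, 0.95)),
                duration=duration,
            )
        )
        specs.append(
            StimulusSpec(
                stimulus_id=f"neu{i:02d}", condition="neutral", carrier_f0=f0,
                am_rate=float(rng.uniform(3, 10)), am_depth=float(rng.uniform(0.1, 0.3)),
                duration=duration,
            )
        )
    clips = {s.stimulus_id: render_stimulus(s, rate=rate, target_rms=target_rms) for s in specs}
    rows = []
    for s in specs:
        clip = clips[s.stimulus_id]
        rows.append(
            {
                "stimulus_id": s.stimulus_id,
                "condition": s.condition,
                "roughness": clip_roughness(clip),
                "f0": estimate_f0(clip),
                "carrier_f0": s.carrier_f0,
                "am_rate": s.am_rate,
                "am_depth": s.am_depth,
            }
        )
    return StimulusSet(specs=specs, clips=clips, features=pd.DataFrame(rows), rate=rate)


# ---------------------------------------------------------------------------
# sessions
# ---------------------------------------------------------------------------

@dataclass
class SessionConfig:
    """All knobs of the session generator; defaults are the study conditions.

    Effect sizes: ``theta_kappa_per_roughness`` is the von Mises
    concentration gain per SD of roughness for the phase-locked theta burst;
    ``sigma_gain_db_per_sd`` / ``delta_gain_db_per_sd`` are induced-amplitude
    slopes in (10·ln) dB per SD of roughness.  Background sleep EEG is not
    constrained by the analysis, so spindle/slow-wave densities default to
    literature-plausible values.
    """

    n_participants: int = 15
    sampling_rate: float = 500.0
    channels: list[str] = field(default_factory=lambda: list(CHANNELS_13))
    jitter_range: tuple[float, float] = (5.0, 11.0)
    block_size: int = 22
    wake_blocks: int = 2
    nrem_blocks: int = 3
    noise_exponent: float = 1.0
    background_sd: float = 15.0  # µV broadband
    # evoked / induced responses
    erp_amplitude: float = 8.0  # µV
    theta_burst_amplitude: float = 12.0  # µV
    theta_kappa_base: float = 1.0
    theta_kappa_per_roughness: float = 0.8
    nrem_theta_kappa_factor: float = 0.6  # phase locking weakens in NREM
    nrem_theta_amp_factor: float = 1.3  # theta power grows in NREM
    sigma_burst_amplitude: float = 28.0  # µV; dominates background sigma in its window
    sigma_gain_db_per_sd: float = 1.0
    delta_wave_amplitude: float = 40.0  # µV
    delta_gain_db_per_sd: float = 1.0
    # spontaneous sleep oscillations (rates per minute)
    spindle_rate_n2: float = 3.0
    spindle_rate_n3: float = 1.5
    slow_wave_rate_n2: float = 3.0
    slow_wave_rate_n3: float = 8.0
    slow_wave_amplitude_n2: float = 40.0  # µV
    slow_wave_amplitude_n3: float = 75.0  # µV
    artifact_fraction: float = 0.0
    inter_block_gap: float = 30.0  # s
    lead_in: float = 20.0  # s
    max_duration: float | None = None  # s; explicit failure if exceeded
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.jitter_range
        if not (0 < lo < hi):
            raise ValueError("jitter_range must be positive and ordered")
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")
        for name in ("theta_kappa_per_roughness", "sigma_gain_db_per_sd",
                     "delta_gain_db_per_sd", "erp_amplitude"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def zero_effects(self) -> "SessionConfig":
        """Copy with all stimulus-feature effect gains and evoked responses off."""
        return replace(
            self,
            erp_amplitude=0.0,
            theta_burst_amplitude=0.0,
            theta_kappa_per_roughness=0.0,
            sigma_burst_amplitude=0.0,
            sigma_gain_db_per_sd=0.0,
            delta_wave_amplitude=0.0,
            delta_gain_db_per_sd=0.0,
        )


@dataclass
class Session:
    """One participant's synthetic recording plus ground truth."""

    eeg: ContinuousEEG
    events: pd.DataFrame  # onset_sample, stimulus_id, condition, roughness, pitch
    hypnogram: Hypnogram
    truth: pd.DataFrame  # per-trial injected parameters (stage, phases, amplitudes...)
    participant: int


def pink_noise(n: int, rate: float, exponent: float, rng: np.random.Generator,
               f_floor: float = 0.5) -> np.ndarray:
    """Gaussian 1/f^exponent noise, unit variance.

    Spectral shaping of white noise; the PSD is flattened below ``f_floor``
    to keep the variance finite.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / rate)
    shape = np.maximum(f, f_floor) ** (-exponent / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n)
    return x / x.std()


def _topography(channels: list[str], kind: str) -> np.ndarray:
    """Dipolar anterior–posterior gain profiles for injected components.

    Weights are re-centered to zero mean across the montage (scalp fields
    referenced to the common average sum to zero), so re-referencing leaves
    the injected responses unchanged; magnitudes stay >= ~0.5 everywhere.
    """
    frontal = {"Fpz": 0.7, "F3": 0.8, "Fz": 0.8, "F4": 0.8, "T3": -0.5, "C3": 0.55,
               "Cz": 0.5, "C4": 0.55, "T4": -0.5, "P3": -0.85, "Pz": -1.0, "P4": -0.85,
               "Oz": -1.0}
    central = {"Fpz": -1.0, "F3": -0.7, "Fz": -0.8, "F4": -0.7, "T3": -0.5, "C3": 0.8,
               "Cz": 1.0, "C4": 0.8, "T4": -0.5, "P3": 0.85, "Pz": 0.9, "P4": 0.85,
               "Oz": -1.0}
    table = frontal if kind == "frontal" else central
    w = np.array([table.get(ch, 0.8) for ch in channels])
    w = w - w.mean()
    return w / np.abs(w).max()


def _erp_kernel(t: np.ndarray, amplitude: float) -> np.ndarray:
    """Wake auditory evoked potential: N1 (100 ms) – P2 (200 ms) – N2 (350 ms)."""
    def g(mu, sd):
        return np.exp(-0.5 * ((t - mu) / sd) ** 2)
    return amplitude * (-0.6 * g(0.10, 0.03) + 1.0 * g(0.20, 0.05) - 0.4 * g(0.35, 0.07))


def _plateau_envelope(t: np.ndarray, start: float, stop: float, ramp: float) -> np.ndarray:
    """Unit envelope: cosine ramps start→start+ramp and stop−ramp→stop."""
    env = np.zeros_like(t)
    core = (t >= start + ramp) & (t <= stop - ramp)
    env[core] = 1.0
    up = (t >= start) & (t < start + ramp)
    env[up] = 0.5 * (1 - np.cos(np.pi * (t[up] - start) / ramp))
    dn = (t > stop - ramp) & (t <= stop)
    env[dn] = 0.5 * (1 - np.cos(np.pi * (stop - t[dn]) / ramp))
    return env


def _build_hypnogram_and_onsets(config: SessionConfig, stim_duration: float,
                                rng: np.random.Generator) -> tuple[Hypnogram, np.ndarray, int]:
    """Plan the session timeline: stage sequence and event onset times.

    Wake blocks come first, then a single N1 transition epoch, then NREM
    blocks over a repeating N2/N2/N2/N3/N3 cycle.  Onsets are jittered
    uniformly in ``jitter_range`` after each stimulus offset.
    """
    jit_lo, jit_hi = config.jitter_range
    onsets: list[float] = []
    t = config.lead_in

    def place_block():
        nonlocal t
        for _ in range(config.block_size):
            onsets.append(t)
            t += stim_duration + rng.uniform(jit_lo, jit_hi)

    n_wake_events = config.wake_blocks * config.block_size
    for _ in range(config.wake_blocks):
        place_block()
        t += config.inter_block_gap
    wake_end = t
    if config.nrem_blocks > 0:
        # one N1 scoring epoch between wake and NREM, events kept clear of it
        n1_epoch = int(np.ceil(wake_end / 20.0))
        t = (n1_epoch + 1) * 20.0 + 2.0
        for _ in range(config.nrem_blocks):
            place_block()
            t += config.inter_block_gap
    total = t + 15.0  # tail for epoch windows and wavelet support
    if config.max_duration is not None and total > config.max_duration:
        raise SessionTooShortError(
            f"session needs {total:.0f} s but max_duration is {config.max_duration:.0f} s"
        )
    n_epochs = int(np.ceil(total / 20.0))
    stages = []
    nrem_cycle = ["N2", "N2", "N2", "N3", "N3"]
    for k in range(n_epochs):
        if config.nrem_blocks == 0 or k * 20.0 < wake_end:
            stages.append("W")
        elif k == n1_epoch:
            stages.append("N1")
        elif k < n1_epoch:
            stages.append("W")
        else:
            stages.append(nrem_cycle[(k - n1_epoch - 1) % len(nrem_cycle)])
    return Hypnogram(stages=stages), np.asarray(onsets), n_wake_events


def generate_session(config: SessionConfig, stimuli: StimulusSet, participant: int) -> Session:
    """Generate one participant's continuous EEG, event table and hypnogram.

    Deterministic given ``config.seed`` and ``participant``.  The returned
    ``truth`` table records, per trial: the vigilance stage at onset, the
    z-scored roughness used for effect injection, the injected theta phase
    and its von Mises kappa, and the injected sigma/delta linear amplitudes.
    """
    if participant >= config.n_participants:
        raise ValueError("participant index out of range")
    rng = np.random.default_rng([int(config.seed) % (2**31), 1000 + participant])
    rate = config.sampling_rate
    stim_dur = stimuli.duration

    hyp, onset_times, _ = _build_hypnogram_and_onsets(config, stim_dur, rng)
    n_events = onset_times.size
    n_samples = int(round(hyp.duration * rate))

    # stimulus sequence: tiled shuffled copies keep conditions near-balanced
    ids = list(stimuli.features["stimulus_id"])
    seq: list[str] = []
    while len(seq) < n_events:
        block = list(ids)
        rng.shuffle(block)
        seq.extend(block)
    seq = seq[:n_events]

    feats = stimuli.features.set_index("stimulus_id")
    rough = feats["roughness"]
    z_all = (rough - rough.mean()) / rough.std(ddof=1)

    channels = list(config.channels)
    n_ch = len(channels)
    data = np.empty((n_ch, n_samples))
    for c in range(n_ch):
        data[c] = config.background_sd * pink_noise(n_samples, rate, config.noise_exponent, rng)

    topo_frontal = _topography(channels, "frontal")
    topo_central = _topography(channels, "central")

    def add(component: np.ndarray, start: int, topo: np.ndarray) -> None:
        stop = min(start + component.size, n_samples)
        if start >= n_samples or stop <= max(start, 0):
            return
        lo = max(start, 0)
        seg = component[lo - start : stop - start]
        data[:, lo:stop] += topo[:, None] * seg[None, :]

    # --- spontaneous sleep oscillations per N2/N3 scoring epoch -------------
    spindle_t = np.arange(int(round(1.0 * rate))) / rate  # 1 s events
    for k, stage in enumerate(hyp.stages):
        if stage not in ("N2", "N3"):
            continue
        t0 = k * 20.0
        sp_rate = config.spindle_rate_n2 if stage == "N2" else config.spindle_rate_n3
        for _ in range(rng.poisson(sp_rate * 20.0 / 60.0)):
            f = rng.uniform(12, 15)
            amp = max(5.0, rng.normal(15.0, 3.0))
            wave = amp * np.hanning(spindle_t.size) * np.sin(
                2 * np.pi * f * spindle_t + rng.uniform(0, 2 * np.pi)
            )
            add(wave, int((t0 + rng.uniform(0, 19)) * rate), topo_central)
        sw_rate = config.slow_wave_rate_n2 if stage == "N2" else config.slow_wave_rate_n3
        sw_amp = config.slow_wave_amplitude_n2 if stage == "N2" else config.slow_wave_amplitude_n3
        for _ in range(rng.poisson(sw_rate * 20.0 / 60.0)):
            f = rng.uniform(0.6, 1.1)
            dur = 1.0 / f
            tw = np.arange(int(round(dur * rate))) / rate
            wave = -sw_amp * rng.uniform(0.7, 1.3) * np.sin(2 * np.pi * f * tw)
            add(wave, int((t0 + rng.uniform(0, 19)) * rate), topo_frontal)

    # --- per-event injected responses --------------------------------------
    resp_t = np.arange(int(round(2.0 * rate))) / rate  # 0..2 s post onset
    n_artifact = int(round(config.artifact_fraction * n_events))
    artifact_idx = set(rng.choice(n_events, size=n_artifact, replace=False)) if n_artifact else set()

    rows = []
    for i, (t_on, sid) in enumerate(zip(onset_times, seq)):
        o = int(round(t_on * rate))
        stage = hyp.stage_at(t_on)
        z = float(z_all[sid])
        is_nrem = stage in ("N2", "N3")

        kappa = config.theta_kappa_base + config.theta_kappa_per_roughness * z
        if is_nrem:
            kappa *= config.nrem_theta_kappa_factor
        kappa = max(kappa, 0.05)
        phi = float(rng.vonmises(0.0, kappa))
        theta_amp = config.theta_burst_amplitude * (
            config.nrem_theta_amp_factor if is_nrem else 1.0
        )
        if theta_amp > 0:
            env = np.exp(-0.5 * ((resp_t - 0.30) / 0.15) ** 2)
            add(theta_amp * env * np.cos(2 * np.pi * 6.0 * (resp_t - 0.30) + phi), o, topo_frontal)

        sigma_amp = delta_amp = 0.0
        if is_nrem:
            sigma_amp = config.sigma_burst_amplitude * np.exp(config.sigma_gain_db_per_sd * z / 20.0)
            if sigma_amp > 0:
                env = _plateau_envelope(resp_t, 0.6, 1.4, 0.2)
                add(sigma_amp * env * np.sin(2 * np.pi * 13.5 * resp_t + rng.uniform(0, 2 * np.pi)),
                    o, topo_central)
            delta_amp = config.delta_wave_amplitude * np.exp(config.delta_gain_db_per_sd * z / 20.0)
            if delta_amp > 0:
                mask = (resp_t >= 0.2) & (resp_t <= 1.2)
                wave = np.zeros_like(resp_t)
                wave[mask] = -np.sin(2 * np.pi * 1.0 * (resp_t[mask] - 0.2))
                add(delta_amp * wave, o, topo_frontal)
        elif stage == "W" and config.erp_amplitude > 0:
            add(_erp_kernel(resp_t, config.erp_amplitude), o, topo_frontal)

        if i in artifact_idx:
            # movement-like spike on a few channels (survives re-referencing)
            spike = 500.0 * np.hanning(int(round(0.1 * rate)))
            topo = np.zeros(n_ch)
            topo[rng.choice(n_ch, size=min(3, n_ch), replace=False)] = 1.0
            add(spike, o + int(round(0.5 * rate)), topo)

        rows.append(
            {
                "trial": i, "onset_sample": o, "stimulus_id": sid,
                "condition": feats.loc[sid, "condition"], "stage": stage,
                "z_roughness": z, "theta_phase": phi, "theta_kappa": kappa,
                "sigma_amp": sigma_amp, "delta_amp": delta_amp,
                "artifact": i in artifact_idx,
            }
        )

    truth = pd.DataFrame(rows)
    events = pd.DataFrame(
        {
            "onset_sample": truth["onset_sample"],
            "stimulus_id": truth["stimulus_id"],
            "condition": truth["condition"],
            "roughness": [feats.loc[s, "roughness"] for s in truth["stimulus_id"]],
            "pitch": [feats.loc[s, "f0"] for s in truth["stimulus_id"]],
        }
    )
    eeg = ContinuousEEG(data=data, rate=rate, channel_labels=channels, reference="Fpz-online")
    return Session(eeg=eeg, events=events, hypnogram=hyp, truth=truth, participant=participant)
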