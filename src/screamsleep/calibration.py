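"""Calibration studies run on synthetic data: type-I error of the cluster
test, recovery of injected regression slopes, and detection rates of the
roughness effects at generator defaults.

These are the package's own validation experiments; the test suite and the
acceptance script both run them (at sizes chosen to keep a single-CPU run
in minutes — see the methods note for the exact problem sizes).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import preproc, stats, timefreq
from .synthdata import SessionConfig, generate_session, generate_stimulus_set

__all__ = [
    "ar1_series",
    "null_cluster_type1_rate",
    "recover_sigma_beta",
    "detection_rates",
]

SIGMA_EVAL_WINDOW = (0.7, 1.3)  # s; plateau of the injected sigma burst


def ar1_series(n_participants: int, n_times: int, phi: float, rng: np.random.Generator) -> np.ndarray:
    """Temporally autocorrelated Gaussian noise, one AR(1) row per participant."""
    x = np.empty((n_participants, n_times))
    x[:, 0] = rng.standard_normal(n_participants)
    innov_sd = np.sqrt(1 - phi**2)
    for t in range(1, n_times):
        x[:, t] = phi * x[:, t - 1] + innov_sd * rng.standard_normal(n_participants)
    return x


def null_cluster_type1_rate(n_sims: int = 500, n_participants: int = 15, n_times: int = 50,
                            rate: float = 50.0, phi: float = 0.8, n_perm: int = 1000,
                            alpha: float = 0.05, seed: int = 0) -> float:
    """Family-wise false-positive rate of the cluster test under the null.

    Each simulation draws two independent AR(1) participants × time series
    (0–1 s at the decimated rate) with no effect and counts whether any
    cluster reaches p < ``alpha``.  Should sit near ``alpha``.
    """
    rng = np.random.default_rng(seed)
    times = np.arange(n_times) / rate
    hits = 0
    for _ in range(n_sims):
        a = ar1_series(n_participants, n_times, phi, rng)
        b = ar1_series(n_participants, n_times, phi, rng)
        res = stats.paired_cluster_permutation(a, b, times, n_perm=n_perm, rng=rng)
        if res.significant(alpha):
            hits += 1
    return hits / n_sims


def _nrem_session_config(base: SessionConfig | None, n_trials: int, seed: int,
                         **overrides) -> SessionConfig:
    cfg = base if base is not None else SessionConfig()
    n_blocks = int(np.ceil(n_trials / cfg.block_size))
    return replace(cfg, wake_blocks=0, nrem_blocks=n_blocks, seed=seed, **overrides)


def recover_sigma_beta(slope: float, n_seeds: int = 20, n_trials: int = 200,
                       seed: int = 0) -> np.ndarray:
    """Estimate the injected sigma-power slope (dB per SD roughness).

    One single-participant NREM session per seed (about ``n_trials``
    stimuli); the estimate is the channel-averaged regression slope of
    baseline-corrected sigma-band dB power on z-scored roughness, averaged
    over the burst plateau (0.7–1.3 s).  Returns one estimate per seed.
    """
    stimuli = generate_stimulus_set(seed=seed)
    z_map = dict(zip(stimuli.features["stimulus_id"],
                     stats.zscore_features(stimuli.features["roughness"])))
    bank = timefreq.build_wavelet_bank(500.0, freqs=np.arange(12.0, 16.0))
    betas = np.empty(n_seeds)
    for s in range(n_seeds):
        cfg = _nrem_session_config(None, n_trials, seed=seed + 1 + s,
                                   sigma_gain_db_per_sd=slope)
        session = generate_session(cfg, stimuli, participant=0)
        eeg = preproc.rereference_common_average(session.eeg)
        tfr = timefreq.tfr_transform(eeg, bank, session.events, freqs=None)
        # regression slopes are invariant to per-trial offsets, so the noisy
        # single-trial baseline subtraction is omitted for beta estimation
        power = timefreq.power_db(tfr)
        nrem = session.truth["stage"].isin(["N2", "N3"]).to_numpy() & tfr.valid
        bp = timefreq.band_average(power, "sigma")
        z = np.array([z_map[sid] for sid in session.events["stimulus_id"][nrem]])
        beta_ct = stats.single_trial_regression(bp.values[nrem], z)  # (C, T)
        tmask = (bp.times >= SIGMA_EVAL_WINDOW[0]) & (bp.times <= SIGMA_EVAL_WINDOW[1])
        betas[s] = stats.channel_average(beta_ct).mean(where=tmask)
    return betas


def _dataset_effect_detection(config: SessionConfig, stimuli, n_perm: int,
                              test_seed: int) -> dict:
    """One dataset: per-participant first-order stats, then the two
    screams-vs-neutral contrasts (theta ITPC 0–1 s, sigma power 0–2 s)."""
    bank = timefreq.build_wavelet_bank(config.sampling_rate,
                                       freqs=np.concatenate([np.arange(4.0, 9.0),
                                                             np.arange(12.0, 16.0)]))
    itpc_s, itpc_n, pow_s, pow_n = [], [], [], []
    times = None
    for p in range(config.n_participants):
        session = generate_session(config, stimuli, p)
        eeg = preproc.rereference_common_average(session.eeg)
        tfr = timefreq.tfr_transform(eeg, bank, session.events)
        scream = (session.events["condition"] == "scream").to_numpy() & tfr.valid
        neutral = (session.events["condition"] == "neutral").to_numpy() & tfr.valid
        power = timefreq.baseline_power(timefreq.power_db(tfr))
        bp = timefreq.band_average(power, "sigma")
        pow_s.append(stats.channel_average(stats.trial_average(bp.values, scream)))
        pow_n.append(stats.channel_average(stats.trial_average(bp.values, neutral)))
        for dest, mask in ((itpc_s, scream), (itpc_n, neutral)):
            imap = timefreq.itpc(tfr, trials=np.flatnonzero(mask))
            dest.append(stats.channel_average(timefreq.band_average(imap, "theta").values))
        times = tfr.times
    res_itpc = stats.paired_cluster_permutation(
        np.stack(itpc_s), np.stack(itpc_n), times, window=(0.0, 1.0),
        n_perm=n_perm, seed=test_seed)
    res_pow = stats.paired_cluster_permutation(
        np.stack(pow_s), np.stack(pow_n), times, window=(0.0, 2.0),
        n_perm=n_perm, seed=test_seed + 1)
    return {
        "theta_itpc": bool(res_itpc.significant()),
        "sigma_power": bool(res_pow.significant()),
    }


def detection_rates(n_datasets: int = 20, n_perm: int = 1000, seed: int = 0,
                    effects: bool = True, n_participants: int = 15,
                    n_trials: int = 44) -> dict:
    """Detection rates of the screams-vs-neutral effects over seeded datasets.

    Each dataset is an NREM stimulation session per participant (about
    ``n_trials`` stimuli each) at generator defaults; with ``effects=False``
    all stimulus-feature gains and evoked responses are switched off, so
    detections are false positives.
    """
    stimuli = generate_stimulus_set(seed=seed)
    hits = {"theta_itpc": 0, "sigma_power": 0}
    for ds in range(n_datasets):
        cfg = _nrem_session_config(None, n_trials, seed=seed + 7919 * (ds + 1),
                                   n_participants=n_participants)
        if not effects:
            cfg = cfg.zero_effects()
        out = _dataset_effect_detection(cfg, stimuli, n_perm, test_seed=seed + ds)
        for k in hits:
            hits[k] += out[k]
    return {k: v / n_datasets for k, v in hits.items()}
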