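"""End-to-end orchestration: synthetic sessions → preprocessing →
time-frequency → cluster statistics, with QC and a serializable report.

The contrast structure mirrors the study design: screams vs neutral
vocalizations, each condition against its pre-stimulus baseline, wake vs
NREM sleep, and single-trial regression slopes (roughness, pitch) against
zero — per canonical band, with power tested in 0–2 s and ERP/ITPC in
0–1 s post-onset windows.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from . import preproc, stats, timefreq
from .synthdata import SessionConfig, StimulusSet, generate_session, generate_stimulus_set

__all__ = ["AnalysisConfig", "ReportBundle", "run_analysis", "contrast_names"]

__version__ = "0.1.0"


@dataclass
class AnalysisConfig:
    """Configuration of a full synthetic-data analysis run."""

    session: SessionConfig = field(default_factory=SessionConfig)
    n_per_condition: int = 8
    stimulus_seed: int = 0
    seed: int = 0
    n_perm: int = 5000
    alpha_point: float = 0.05
    db_log10: bool = False
    bands: tuple[str, ...] = ("delta", "theta", "sigma")
    freqs: tuple[float, ...] | None = None  # restrict the wavelet grid (None = 1..30)
    states: tuple[str, ...] = ("wake", "NREM")
    power_window: tuple[float, float] = (0.0, 2.0)
    itpc_window: tuple[float, float] = (0.0, 1.0)
    tfr_epoch_window: tuple[float, float] = (-2.0, 3.0)
    screen_epoch_window: tuple[float, float] = (-1.0, 2.0)
    power_baseline: tuple[float, float] = (-0.5, 0.0)
    itpc_baseline: tuple[float, float] = (-1.0, 0.0)
    erp_filter: preproc.FilterSpec = field(
        default_factory=lambda: preproc.FilterSpec((0.1, 30.0), order=1))
    erp_baseline: tuple[float, float] = (-0.5, 0.0)
    erp_window: tuple[float, float] = (0.0, 1.0)
    erp_roi: tuple[str, ...] = ("Fpz", "F3", "Fz", "F4")
    abs_threshold: float = 300.0
    flat_threshold: float = 1.0
    min_kept_trials: int = preproc.MIN_KEPT_TRIALS
    min_trials_per_cell: int = 5

    def content_hash(self) -> str:
        from .io import _to_plain

        blob = json.dumps(_to_plain(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    """All contrast results plus QC and provenance of one run."""

    contrasts: dict
    qc: list[dict]
    provenance: dict

    def to_json(self, path=None) -> str:
        payload = {
            "provenance": self.provenance,
            "qc": self.qc,
            "contrasts": {k: v.to_dict() for k, v in self.contrasts.items()},
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_text(self) -> str:
        lines = []
        for name, res in sorted(self.contrasts.items()):
            lines.append(f"{name} (window {res.window[0]:g}–{res.window[1]:g} s, "
                         f"n={res.n_participants}, {res.n_perm} permutations)")
            if not res.clusters:
                lines.append("  no clusters")
            for c in res.clusters:
                lines.append(
                    f"  cluster {c.start_s:.2f}–{c.stop_s:.2f} s: "
                    f"t_cluster={c.stat:.2f}, p_cluster={c.p:.3f}, "
                    f"mean={c.mean:.3g} ± {c.sd:.3g}, d={c.d:.2f}"
                )
        return "\n".join(lines)


def contrast_names(config: AnalysisConfig) -> list[str]:
    """Manifest of every statistical comparison a run reports."""
    names = []
    for state in config.states:
        for band in config.bands:
            names += [
                f"{state}_power_{band}_scream_vs_neutral",
                f"{state}_power_{band}_scream_vs_baseline",
                f"{state}_power_{band}_neutral_vs_baseline",
                f"{state}_beta_roughness_{band}_vs_zero",
                f"{state}_beta_pitch_{band}_vs_zero",
            ]
        names += [
            f"{state}_itpc_theta_scream_vs_neutral",
            f"{state}_itpc_theta_scream_vs_baseline",
            f"{state}_itpc_theta_neutral_vs_baseline",
            f"{state}_erp_scream_vs_neutral",
            f"{state}_erp_scream_vs_baseline",
            f"{state}_erp_neutral_vs_baseline",
        ]
    if {"wake", "NREM"} <= set(config.states):
        names += ["wake_vs_NREM_power_theta", "wake_vs_NREM_itpc_theta"]
    return names


def _participant_first_order(config: AnalysisConfig, stimuli: StimulusSet, participant: int,
                             bank: timefreq.WaveletBank):
    """One participant: generate, preprocess, decompose, first-order stats.

    Returns (series dict, qc dict).  Series are per-contrast-input
    channel-averaged time courses on the decimated grid.
    """
    session = generate_session(config.session, stimuli, participant)
    eeg = preproc.rereference_common_average(session.eeg)

    screen = preproc.epoch(eeg, session.events, config.screen_epoch_window)
    screen = preproc.label_epochs(screen, session.hypnogram)
    screen = preproc.reject_artifacts(screen, config.abs_threshold, config.flat_threshold)
    kept = screen.kept.copy()
    vigilance = screen.vigilance

    tfr = timefreq.tfr_transform(eeg, bank, session.events, window=config.tfr_epoch_window,
                                 freqs=config.freqs)
    usable = kept & tfr.valid
    power = timefreq.baseline_power(timefreq.power_db(tfr, db_log10=config.db_log10),
                                    config.power_baseline)

    feats = stimuli.features
    z_rough_all = dict(zip(feats["stimulus_id"],
                           stats.zscore_features(feats["roughness"])))
    z_pitch_all = dict(zip(feats["stimulus_id"], stats.zscore_features(feats["f0"])))
    stim_ids = session.events["stimulus_id"].to_numpy()
    is_scream = (session.events["condition"] == "scream").to_numpy()

    series: dict[str, np.ndarray] = {}
    ok = True
    for state in config.states:
        in_state = usable & (vigilance == state)
        for band in config.bands:
            bp = timefreq.band_average(power, band)  # (trials, C, T)
            for cond, mask in (("scream", in_state & is_scream),
                               ("neutral", in_state & ~is_scream)):
                if mask.sum() < config.min_trials_per_cell:
                    ok = False
                    continue
                series[f"{state}_power_{band}_{cond}"] = stats.channel_average(
                    stats.trial_average(bp.values, mask))
            if in_state.sum() >= config.min_trials_per_cell * 2:
                z_r = np.array([z_rough_all[s] for s in stim_ids[in_state]])
                z_p = np.array([z_pitch_all[s] for s in stim_ids[in_state]])
                series[f"{state}_beta_roughness_{band}"] = stats.channel_average(
                    stats.single_trial_regression(bp.values[in_state], z_r))
                series[f"{state}_beta_pitch_{band}"] = stats.channel_average(
                    stats.single_trial_regression(bp.values[in_state], z_p))
            else:
                ok = False
        for cond, mask in (("scream", in_state & is_scream),
                           ("neutral", in_state & ~is_scream)):
            if mask.sum() < max(2, config.min_trials_per_cell):
                ok = False
                continue
            imap = timefreq.itpc(tfr, baseline=config.itpc_baseline,
                                 trials=np.flatnonzero(mask))
            series[f"{state}_itpc_theta_{cond}"] = stats.channel_average(
                timefreq.band_average(imap, "theta").values)

    # evoked potentials: 0.1-30 Hz order-1 causal filter on the continuous
    # signal, -1..2 s epochs, 500 ms baseline; averaged over a frontal ROI
    # (signed voltages cancel under whole-scalp averaging of dipolar fields)
    filtered = preproc.bandpass(eeg, config.erp_filter)
    erp = preproc.epoch(filtered, session.events, config.screen_epoch_window)
    erp = preproc.baseline_correct(erp, config.erp_baseline)
    roi = [i for i, ch in enumerate(eeg.channel_labels) if ch in config.erp_roi]
    for state in config.states:
        in_state = usable & (vigilance == state)
        for cond, mask in (("scream", in_state & is_scream),
                           ("neutral", in_state & ~is_scream)):
            if mask.sum() < config.min_trials_per_cell:
                ok = False
                continue
            series[f"{state}_erp_{cond}"] = stats.trial_average(
                erp.data[:, roi, :], mask).mean(axis=0)

    qc = screen.qc_counts()
    qc["participant"] = participant
    qc["qc_fail"] = bool(kept.sum() < config.min_kept_trials) or not ok
    return series, qc, tfr.times, erp.times


def run_analysis(config: AnalysisConfig) -> ReportBundle:
    """Run the full pipeline over all participants and test every contrast.

    Deterministic given the config (stimulus seed, session seed, test seed).
    Participants failing QC (too few clean trials, or an empty design cell)
    are excluded from second-order statistics and logged.
    """
    stimuli = generate_stimulus_set(config.n_per_condition, seed=config.stimulus_seed)
    bank = timefreq.build_wavelet_bank(config.session.sampling_rate)

    all_series, qcs = [], []
    times = erp_times = None
    for p in range(config.session.n_participants):
        series, qc, times, erp_times = _participant_first_order(config, stimuli, p, bank)
        all_series.append(series)
        qcs.append(qc)

    included = [i for i, qc in enumerate(qcs) if not qc["qc_fail"]]
    if len(included) < 5:
        raise RuntimeError("fewer than 5 participants pass QC; cannot run second-order stats")

    def stack(key):
        return np.stack([all_series[i][key] for i in included])

    rng = np.random.default_rng(config.seed)
    contrasts = {}

    def test(name, a, b, window, axis=None):
        seed = int(rng.integers(2**31))
        contrasts[name] = stats.paired_cluster_permutation(
            a, b, erp_times if axis == "erp" else times, window=window,
            alpha_point=config.alpha_point, n_perm=config.n_perm, seed=seed,
        )

    for state in config.states:
        for band in config.bands:
            scream = stack(f"{state}_power_{band}_scream")
            neutral = stack(f"{state}_power_{band}_neutral")
            test(f"{state}_power_{band}_scream_vs_neutral", scream, neutral, config.power_window)
            test(f"{state}_power_{band}_scream_vs_baseline", scream, 0.0, config.power_window)
            test(f"{state}_power_{band}_neutral_vs_baseline", neutral, 0.0, config.power_window)
            test(f"{state}_beta_roughness_{band}_vs_zero",
                 stack(f"{state}_beta_roughness_{band}"), 0.0, config.power_window)
            test(f"{state}_beta_pitch_{band}_vs_zero",
                 stack(f"{state}_beta_pitch_{band}"), 0.0, config.power_window)
        iscr = stack(f"{state}_itpc_theta_scream")
        ineu = stack(f"{state}_itpc_theta_neutral")
        test(f"{state}_itpc_theta_scream_vs_neutral", iscr, ineu, config.itpc_window)
        test(f"{state}_itpc_theta_scream_vs_baseline", iscr, 0.0, config.itpc_window)
        test(f"{state}_itpc_theta_neutral_vs_baseline", ineu, 0.0, config.itpc_window)
        escr = stack(f"{state}_erp_scream")
        eneu = stack(f"{state}_erp_neutral")
        test(f"{state}_erp_scream_vs_neutral", escr, eneu, config.erp_window, axis="erp")
        test(f"{state}_erp_scream_vs_baseline", escr, 0.0, config.erp_window, axis="erp")
        test(f"{state}_erp_neutral_vs_baseline", eneu, 0.0, config.erp_window, axis="erp")

    if {"wake", "NREM"} <= set(config.states):
        wake_p = 0.5 * (stack("wake_power_theta_scream") + stack("wake_power_theta_neutral"))
        nrem_p = 0.5 * (stack("NREM_power_theta_scream") + stack("NREM_power_theta_neutral"))
        test("wake_vs_NREM_power_theta", wake_p, nrem_p, config.power_window)
        wake_i = 0.5 * (stack("wake_itpc_theta_scream") + stack("wake_itpc_theta_neutral"))
        nrem_i = 0.5 * (stack("NREM_itpc_theta_scream") + stack("NREM_itpc_theta_neutral"))
        test("wake_vs_NREM_itpc_theta", wake_i, nrem_i, config.itpc_window)

    provenance = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "stimulus_seed": config.stimulus_seed,
        "session_seed": config.session.seed,
        "n_perm": config.n_perm,
        "n_participants_included": len(included),
        "version": __version__,
    }
    return ReportBundle(contrasts=contrasts, qc=qcs, provenance=provenance)
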