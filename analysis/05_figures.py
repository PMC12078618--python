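#!/usr/bin/env python
"""Line plots with SEM shading for the main band time courses: NREM theta
ITPC and sigma power for screams vs neutral vocalizations, from a small
synthetic cohort.  PNGs go to scratch/figures/.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from screamsleep import preproc, stats, timefreq
from screamsleep.synthdata import SessionConfig, generate_session, generate_stimulus_set

FIGDIR = Path(__file__).resolve().parents[1] / "scratch" / "figures"


def main() -> None:
    FIGDIR.mkdir(parents=True, exist_ok=True)
    stimuli = generate_stimulus_set(seed=0)
    cfg = SessionConfig(n_participants=6, wake_blocks=0, nrem_blocks=2, seed=23)
    bank = timefreq.build_wavelet_bank(
        cfg.sampling_rate, freqs=np.concatenate([np.arange(4.0, 9.0), np.arange(12.0, 16.0)]))

    series = {"itpc_scr": [], "itpc_neu": [], "pow_scr": [], "pow_neu": []}
    times = None
    for p in range(cfg.n_participants):
        sess = generate_session(cfg, stimuli, p)
        eeg = preproc.rereference_common_average(sess.eeg)
        tfr = timefreq.tfr_transform(eeg, bank, sess.events)
        times = tfr.times
        scr = (sess.events["condition"] == "scream").to_numpy() & tfr.valid
        neu = ~(sess.events["condition"] == "scream").to_numpy() & tfr.valid
        power = timefreq.baseline_power(timefreq.power_db(tfr))
        bp = timefreq.band_average(power, "sigma")
        series["pow_scr"].append(stats.channel_average(stats.trial_average(bp.values, scr)))
        series["pow_neu"].append(stats.channel_average(stats.trial_average(bp.values, neu)))
        for key, mask in (("itpc_scr", scr), ("itpc_neu", neu)):
            imap = timefreq.itpc(tfr, trials=np.flatnonzero(mask))
            series[key].append(stats.channel_average(timefreq.band_average(imap, "theta").values))

    def shaded(ax, data, label, color):
        arr = np.stack(data)
        m, sem = arr.mean(0), arr.std(0, ddof=1) / np.sqrt(arr.shape[0])
        ax.plot(times, m, label=label, color=color)
        ax.fill_between(times, m - sem, m + sem, alpha=0.3, color=color)

    for key_s, key_n, title, ylab, fname in [
        ("itpc_scr", "itpc_neu", "NREM theta ITPC", "ITPC (baseline-corrected)", "itpc_theta.png"),
        ("pow_scr", "pow_neu", "NREM sigma power", "power (dB, 10·ln)", "power_sigma.png"),
    ]:
        fig, ax = plt.subplots(figsize=(6, 3.5))
        shaded(ax, series[key_s], "screams", "crimson")
        shaded(ax, series[key_n], "neutral", "steelblue")
        ax.axvline(0, color="k", lw=0.5)
        ax.set(xlabel="time from onset (s)", ylabel=ylab, title=title, xlim=(-1, 2.5))
        ax.legend(frameon=False)
        fig.tight_layout()
        fig.savefig(FIGDIR / fname, dpi=120)
        print(f"wrote {FIGDIR / fname}")


if __name__ == "__main__":
    main()
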