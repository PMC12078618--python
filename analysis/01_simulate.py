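#!/usr/bin/env python
"""Generate the synthetic study materials: a pitch-matched 8+8 stimulus set
(WAV) and two example polysomnographic sessions (EDF + event/hypnogram TSV),
with the generator configuration archived as YAML.

Small tables go to results/; bulky media (WAV, EDF) go to scratch/.
"""

from pathlib import Path

from screamsleep import io
from screamsleep.synthdata import SessionConfig, generate_session, generate_stimulus_set

RESULTS = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch" / "sim"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)

    stimuli = generate_stimulus_set(n_per_condition=8, seed=0)
    for sid, clip in stimuli.clips.items():
        clip.to_wav(SCRATCH / f"{sid}.wav")
    stimuli.features.to_csv(RESULTS / "stimulus_features.tsv", sep="\t", index=False)
    print(f"stimuli: {len(stimuli.clips)} clips -> {SCRATCH}")
    print(stimuli.features.groupby("condition")[["roughness", "f0"]].mean().round(2))

    config = SessionConfig(n_participants=2, wake_blocks=1, nrem_blocks=2, seed=7)
    io.save_config_yaml(RESULTS / "generator_config.yaml", config)
    for p in range(config.n_participants):
        sess = generate_session(config, stimuli, p)
        io.write_edf(SCRATCH / f"sub{p:02d}.edf", sess.eeg)
        io.write_events_tsv(SCRATCH / f"sub{p:02d}_events.tsv", sess.events)
        io.write_hypnogram_tsv(SCRATCH / f"sub{p:02d}_hypnogram.tsv", sess.hypnogram)
        counts = sess.truth["stage"].value_counts().to_dict()
        print(f"sub{p:02d}: {sess.eeg.duration:.0f} s, {len(sess.events)} events, "
              f"stages at onset {counts}")


if __name__ == "__main__":
    main()
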