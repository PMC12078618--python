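#!/usr/bin/env python
"""Calibration studies: cluster-test type-I error under an AR(1) null,
recovery of the injected sigma-power slope, and detection rates of the
roughness effects at generator defaults (with a zero-gain control).

This is the long-running validation; sizes here are trimmed relative to
scripts/acceptance.py so the script finishes in ~2 minutes.
"""

import json
import time
from pathlib import Path

from screamsleep import calibration

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    out = {}
    t0 = time.time()

    rate = calibration.null_cluster_type1_rate(n_sims=200, n_perm=1000, seed=3)
    out["cluster_type1_familywise_rate"] = rate
    print(f"type-I family-wise rate (200 null sims): {rate:.3f}")

    betas = calibration.recover_sigma_beta(slope=0.2, n_seeds=5, n_trials=200, seed=3)
    out["sigma_beta_mean"] = betas.mean()
    print(f"sigma slope 0.2 recovered as {betas.mean():.3f} (5 seeds)")

    rates = calibration.detection_rates(n_datasets=3, n_perm=1000, seed=3)
    out["detection_rates"] = rates
    print(f"detection at defaults (3 datasets): {rates}")

    (RESULTS / "calibration.json").write_text(json.dumps(out, indent=1))
    print(f"done in {time.time() - t0:.0f} s -> results/calibration.json")


if __name__ == "__main__":
    main()
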