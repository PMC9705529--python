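#!/usr/bin/env python
"""Run repeated multilayer community detection on every trial.

Each trial's 12-layer WPLI graph (resolution gamma = 1, ordinal interlayer
coupling omega = 0.1 at this 12-node scale) is optimized 50 times with the
generalized Louvain heuristic; all downstream metrics average over the
repetitions.  Writes per-condition summaries of the detected structure to
results/03_community_summary.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from dynmodnet.pipeline import demo_config, run_pipeline

ROOT = Path(__file__).resolve().parents[1]
RUN_DIR = ROOT / "scratch" / "run"
RESULTS = ROOT / "results"


def main() -> None:
    config = demo_config(seed=7)
    run_pipeline(config, RUN_DIR)

    rows = []
    for i, cond in enumerate(config.conditions, start=1):
        labels = np.load(RUN_DIR / "parts" / f"cond{i}.npy")  # (trials, R, N, W)
        n_modules = [
            len(np.unique(labels[t, r]))
            for t in range(labels.shape[0])
            for r in range(0, labels.shape[1], 10)
        ]
        per_layer_changes = (labels[:, :, :, 1:] != labels[:, :, :, :-1]).mean()
        rows.append(
            dict(condition=cond,
                 mean_detected_modules=np.mean(n_modules),
                 node_window_switch_rate=per_layer_changes)
        )
    table = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "03_community_summary.csv", index=False)
    print(f"Community detection: {config.n_reps} repetitions per trial, "
          f"gamma={config.gamma}, omega={config.omega}")
    print(table.round(4).to_string(index=False))
    print("\nThe switch rate should drop in the second condition, where DMN"
          "\nnodes change planted modules half as often.")


if __name__ == "__main__":
    sys.exit(main())
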