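#!/usr/bin/env python
"""Render the synthetic study: 12 subjects x 10 heel-strike trials.

Writes raw force-plate and marker CSVs plus the ground-truth manifest
to scratch/fixtures/ (regenerated deterministically from the seed; the
files are inputs for 02_process_trials.py).  Prints the spread of the
drawn contact parameters so the simulated population is on record.
"""

import json
from pathlib import Path

import numpy as np

from heelstrike.synthetic import make_fixture_study

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "scratch" / "fixtures"


def main() -> None:
    trials = make_fixture_study(n_subjects=12, n_trials=10, seed=SEED,
                                out_dir=OUT, noisy=True)
    print(f"rendered {len(trials)} trials to {OUT}")

    masses = sorted({t['config'].mass for t in trials})
    zetas = sorted({round(t['config'].damping_ratio, 3) for t in trials})
    v0s = [t["config"].v0 for t in trials]
    print(f"effective mass range: {masses[0]:.2f} - {masses[-1]:.2f} kg")
    print(f"damping ratio range:  {zetas[0]:.2f} - {zetas[-1]:.2f}")
    print(f"touchdown velocity:   {np.mean(v0s):.3f} +/- {np.std(v0s):.3f} m/s")

    manifest = json.loads((OUT / "truth.json").read_text())
    te = [m["truth"]["t_e_true"] - m["truth"]["touchdown_time"]
          for m in manifest.values()]
    print(f"true heel-strike duration: {1e3 * np.mean(te):.1f} "
          f"+/- {1e3 * np.std(te):.1f} ms")


if __name__ == "__main__":
    main()
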