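#!/usr/bin/env python
"""Diagnostic figures: forces, deformation, COP cloud, method comparison.

Renders for one representative trial the vertical GRF with the detected
events, the shared force/deformation time axis, and the local-frame COP
cloud with the heel point H and displaced point Q; plus the bar chart
of the five energy measures over the study.  Writes PNGs to
results/figures/.
"""

import json
from pathlib import Path

import pandas as pd

from heelstrike import PipelineConfig, process_records
from heelstrike import plots
from heelstrike.io import read_force_csv, read_marker_csv

ROOT = Path(__file__).resolve().parent.parent
FIXTURES = ROOT / "scratch" / "fixtures"
RESULTS = ROOT / "results"
FIGURES = RESULTS / "figures"


def main() -> None:
    FIGURES.mkdir(parents=True, exist_ok=True)
    manifest = json.loads((FIXTURES / "truth.json").read_text())
    meta = manifest["S01_T01"]
    rec = read_force_csv(FIXTURES / meta["force_file"])
    markers = read_marker_csv(FIXTURES / meta["marker_file"])
    result, inter = process_records(
        rec, markers, PipelineConfig(body_mass=meta["body_mass"]),
        return_intermediates=True,
    )
    plots.plot_grf(inter["grf"], result, FIGURES / "grf.png")
    plots.plot_deformation(inter["grf"], inter["track"], result,
                           FIGURES / "deformation.png")
    plots.plot_local_cop(inter["local_cop"], inter["r_H"], result,
                         FIGURES / "local_cop.png")

    table = pd.read_csv(RESULTS / "summary_table.csv", index_col=0)
    plots.plot_energy_methods(table, FIGURES / "energy_methods.png")
    print(f"figures written to {FIGURES}")


if __name__ == "__main__":
    main()
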