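"""Full file-based pipeline on a small synthetic cohort.

Writes every stage output (time series TSVs, NIfTI volumes, connectivity
matrices, cohort CSV, statistics bundle, provenance record) under
``scratch/example_cohort`` and prints the headline statistics.  Equivalent
shell command::

    connectodyn run-all --seed 42 --out scratch/example_cohort
"""

import json
from pathlib import Path

from connectodyn import PipelineConfig, SimulationConfig, run_pipeline

cfg = PipelineConfig(
    simulation=SimulationConfig(
        n_patients=10, n_controls=10, n_regions=30, n_blocks=5, seed=42
    )
)
out = run_pipeline(cfg, Path("scratch/example_cohort"))

summary = json.loads((out / "results" / "summary.json").read_text())
provenance = json.loads((out / "provenance.json").read_text())
densities = json.loads((out / "densities.json").read_text())

print(f"pipeline wrote {len(provenance['outputs'])} files under {out}")
print(f"common densities: functional {densities['functional']:.3f}, structural {densities['structural']:.3f}")
if "sc_fc_fisher" in summary:
    f = summary["sc_fc_fisher"]
    print(
        f"SC-FC coupling: r_patient = {f['r_patient']:.2f}, r_control = {f['r_control']:.2f}, "
        f"z = {f['z']:.2f}, p = {f['p']:.4f}"
    )
print("rerunning with the same seed reproduces every file byte-for-byte")
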