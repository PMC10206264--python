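"""End-to-end pipeline on synthetic inputs.

Chains all six stages — input generation, trajectory analysis, MM/GBSA,
binding-model report, R-group design and ensemble scoring — into one
deterministic run directory with a manifest.
"""

import json

import bindsight as bs
from bindsight.pipeline import PipelineConfig, run_pipeline

config = PipelineConfig(
    seed=3,
    synthetic=bs.SyntheticSpec(n_receptor_residues=8, n_ligand_atoms=8,
                               n_frames=60),
    energy_frames=8, entropy_frames=8, cluster_max_frames=30,
    surrogate_sasa_points=96)

out = run_pipeline(config, "pipeline-demo")
meta = json.loads((out / "manifest.json").read_text())
print("stages and outputs:")
for stage, files in meta["stages"].items():
    print(f"  {stage}: {', '.join(files)}")
print("\nsummary:", json.dumps(meta["summary"], indent=2))
print("\nRe-running with the same config and seed reproduces every file "
      "byte for byte (config hash", meta["config_hash"] + ").")
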