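"""Run the whole analysis end to end on a generated campaign.

Generates a three-zone campaign at the published targets, writes the input
files, and runs the pipeline: summaries, metal and PAH risk, pollution
indices, Monte Carlo and CPF, with a manifest recording every choice.
"""

import tempfile
from pathlib import Path

from riskpm import (GeneratorSpec, gen_concentrations, gen_trajectories, io,
                    presets, run_pipeline)

targets = {}
for kind in ("metals", "pahs"):
    for r in presets.campaign_zone_table(kind).itertuples():
        targets[(r.zone, r.species)] = (r.mean, r.stdev)
spec = GeneratorSpec(targets=targets, n_days=30, seed=8)

work = Path(tempfile.mkdtemp(prefix="riskpm_"))
io.write_measurements(gen_concentrations(spec), work / "concentrations.csv")
io.write_trajectories(gen_trajectories(spec, directions=("backward",)),
                      work / "trajectories.csv")

outputs = run_pipeline({
    "concentrations": str(work / "concentrations.csv"),
    "trajectories": str(work / "trajectories.csv"),
    "censor_policy": "zero",
    "seed": 8,
    "mc": {"enabled": True, "n_iterations": 2000},
    "cpf": {"metric": "HI", "zone": "North",
            "grid": {"cell_km": 4.0, "n_rows": 32, "n_cols": 32}},
}, work / "out")

print("stages completed:", ", ".join(sorted(outputs)))
print("\nzone hazard indices:")
print(outputs["hazard_index"].to_string(index=False))
print("\nzone ILCR:")
print(outputs["ilcr"].to_string(index=False))
print(f"\nall tables written under {work / 'out'} with manifest.json "
      "recording config hash, seed and input digests.")
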