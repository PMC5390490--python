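"""Simulate a complete factorial experiment and run every stage.

Generates the three input CSVs (leaf records, A-Ci curves, biochemistry)
for the rice/wheat/maize x control/WD/HT/HT-WD design, runs the full
pipeline, and prints the limitation table and the temperature effect.

Equivalent shell commands:
    photolim simulate --seed 1 --out sim/
    photolim run-all --input-dir sim/ --out results/ --seed 1
"""

import tempfile
from pathlib import Path

import pandas as pd

from photolim.pipeline import run_pipeline, simulate_to_dir

with tempfile.TemporaryDirectory() as tmp:
    sim = Path(tmp) / "sim"
    out = Path(tmp) / "out"
    simulate_to_dir(sim, seed=1)
    manifest = run_pipeline({"n_boot": 500}, sim, out, seed=1)

    lim = pd.read_csv(out / "limitations.csv")
    cols = ["species", "treatment", "SL", "MCL", "BL", "DL", "BL_se"]
    print(lim[cols].round(3).to_string(index=False))

    anova = pd.read_csv(out / "anova.csv")
    row = anova[(anova.response == "activation_state")
                & (anova.effect == "temperature")]
    print(f"\ntemperature effect on activation state: "
          f"F = {float(row['F'].iloc[0]):.1f}, "
          f"p = {float(row['p'].iloc[0]):.2g}")
    print(f"infeasible records: {manifest['n_infeasible_records']}")

# Diffusive limitation (DL) leads in the C3 species under water deficit;
# biochemical limitation (BL) dominates under high growth temperature in
# all three species, driven by the halved Rubisco activation state.
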