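"""Track donor-strain engraftment through the full pipeline.

Simulates a study with known per-phylum engraftment probabilities,
runs species coverage -> EM strain deconvolution -> origin
classification, and prints the per-phylum transferability index (the
fraction of donor-specific strains found in patients at first
follow-up).
"""

import tempfile
from pathlib import Path

import pandas as pd

from straintrack import PipelineConfig, SimulationConfig, run

probs = {"Bacteroidota": 0.34, "Firmicutes_A": 0.26}
sim = SimulationConfig(
    n_donors=2, n_patients=10, n_species=40, strains_per_species=(2, 3),
    phylum_weights={ph: 0.5 for ph in probs},
    engraftment_prob={(arm, ph): p for ph, p in probs.items()
                      for arm in ("ABX+", "ABX-")},
    displacement_prob={"ABX+": 0.0, "ABX-": 0.0},
    mean_coverage=8000.0,
    timepoints={"B": -7.0, "F1": 56.0},
    donor_sample_counts=(2, 2),
)

with tempfile.TemporaryDirectory() as tmp:
    cfg = PipelineConfig(
        output_dir=tmp, seed=4, simulation=sim,
        stages=("simulate", "coverage", "strains", "track"),
    )
    run(cfg)
    tt = pd.read_csv(Path(tmp) / "transferability.tsv", sep="\t")
    traj = pd.read_csv(Path(tmp) / "origin_trajectories.tsv", sep="\t")

print("Per-phylum transferability (estimated from inferred strains)")
print(tt.to_string(index=False))
print("\nConfigured engraftment probabilities:", probs)
print("\nMean community fraction by origin class at F1")
f1 = traj[traj["timepoint"] == "F1"]
print(f1[["baseline-specific", "donor-specific", "shared", "neither"]]
      .mean().round(3).to_string())
print("\nEstimated rates should sit close to the configured"
      "\nprobabilities; origin fractions per sample sum to 1.")
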