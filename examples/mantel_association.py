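"""Associate taxonomic turnover with bile-acid turnover by partial Mantel.

Within-patient dissimilarity matrices are combined block-diagonally
(inter-patient comparisons carry no information about turnover and are
masked); the partial Mantel correlation controls for the square root
of the time between collections, and the permutation null shuffles
sample identities within each patient block.
"""

import pandas as pd

from straintrack import SimulationConfig, partial_mantel, simulate_study
from straintrack.ecology import build_block_matrix, time_control_matrix

config = SimulationConfig(
    n_donors=2, n_patients=8, n_species=12, donor_sample_counts=(2, 2),
    ba_taxa_coupling=0.5, ba_patient_sd=0.3, ba_noise_sd=0.2, rng_seed=2,
)
study = simulate_study(config)
md = study.metadata.set_index("sample_id")
patients = md[md["role"] == "patient"]

phylum_comp = study.truth.true_community[patients.index].groupby(
    pd.Series(dict(study.pool.strain_phylum))
).sum()

d_taxa = build_block_matrix(phylum_comp, patients["subject_id"], "braycurtis")
d_ba = build_block_matrix(study.bile_acids[d_taxa.ids],
                          patients["subject_id"], "cosine")
d_time = time_control_matrix(patients.loc[d_taxa.ids, "days_since_fmt"],
                             patients["subject_id"])

res = partial_mantel(d_taxa, d_ba, d_time, n_perm=999, seed=0)
print(f"partial Mantel r = {res.r:.3f}  (taxa vs bile acids | sqrt time)")
print(f"permutation p    = {res.p:.4f}  over {res.n_pairs} within-patient pairs")
print("\nWith taxa-coupled bile acids (coupling 0.5) the correlation is"
      "\npositive and significant; with coupling 0 it is null-calibrated.")
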