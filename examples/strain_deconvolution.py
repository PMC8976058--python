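"""Recover strain haplotypes and frequencies from allele counts by EM.

A 3-strain species is simulated at 200x coverage; the fitted model is
aligned to the truth by Hungarian matching on genotype distance, and
the recovery error is printed.
"""

import numpy as np

from straintrack import fit_strains, match_strains
from straintrack.metagenotype import Metagenotype

rng = np.random.default_rng(0)
K, L, S = 3, 100, 10
genotypes = rng.integers(0, 2, size=(K, L)).astype(float)
frequencies = rng.dirichlet(np.ones(K), size=S).T  # per-sample simplex

eps = 0.01
total = rng.poisson(200, size=(L, S))
q = eps + (1 - 2 * eps) * (genotypes.T @ frequencies)
minor = rng.binomial(total, q)
mgt = Metagenotype(
    "species_x",
    [f"pos{i}" for i in range(L)],
    [f"sample{j}" for j in range(S)],
    np.stack([total - minor, minor], axis=2),
)

model = fit_strains(mgt, K=K, epsilon=eps, seed=0, n_restarts=3)
perm = match_strains(genotypes, model.genotypes)

acc = (model.genotypes[perm] == genotypes).mean()
err = np.abs(model.frequencies[perm] - frequencies).mean()
print(f"log-likelihood       : {model.log_likelihood:.1f} "
      f"({model.n_iter} iterations, converged={model.converged})")
print(f"genotype accuracy    : {acc:.3f}   (fraction of alleles correct)")
print(f"mean |freq error|    : {err:.4f}  (absolute per-strain-per-sample)")
print("\nAt 200x coverage and 100 sites the mixture is essentially fully"
      "\nidentifiable: expect accuracy ~1.0 and frequency error < 0.01.")
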