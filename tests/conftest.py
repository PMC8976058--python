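import numpy as np
import pytest

from straintrack.metagenotype import Metagenotype
from straintrack.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def toy_config():
    """A small but complete study: 2 donors, 8 patients, 12 species."""
    return SimulationConfig(
        n_donors=2,
        n_patients=8,
        n_species=12,
        donor_sample_counts=(3, 2),
        rng_seed=42,
    )


@pytest.fixture(scope="session")
def toy_study(toy_config):
    return simulate_study(toy_config)


def make_mixture_metagenotype(
    g, f, coverage=200.0, eps=0.01, seed=0, species_id="sp"
):
    """Binomial counts from a known strain mixture (test oracle input)."""
    g = np.asarray(g, dtype=float)
    f = np.asarray(f, dtype=float)
    K, L = g.shape
    S = f.shape[1]
    rng = np.random.default_rng(seed)
    total = rng.poisson(coverage, size=(L, S))
    q = eps + (1 - 2 * eps) * (g.T @ f)
    minor = rng.binomial(total, np.clip(q, 0, 1))
    return Metagenotype(
        species_id,
        [f"p{i:03d}" for i in range(L)],
        [f"s{j:02d}" for j in range(S)],
        np.stack([total - minor, minor], axis=2),
    )
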