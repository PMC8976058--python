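"""SNP-haplotype deconvolution: infer strain genotypes and frequencies by EM.

Model
-----
Each species is a mixture of at most K binary haplotypes ("strains")
over its biallelic SNP sites.  With per-sample strain frequencies
``f[k, s]`` (a simplex over k), genotypes ``g[k, l]`` (1 = minor
allele) and a symmetric sequencing error rate ``eps``, the minor-allele
count at site l in sample s is

    minor[l, s] ~ Binomial(total[l, s], q[l, s]),
    q[l, s] = eps + (1 - 2 eps) * sum_k f[k, s] * g[k, l].

Fitting alternates (i) an EM update of every sample's frequency vector
given the genotypes — each read is a latent draw from one strain — and
(ii) a per-(strain, site) exact maximisation of the binary allele given
the frequencies.  Both steps never decrease the log-likelihood.  The
number of strains K is fixed (capped at 20), not selected; restarts
guard against poor local optima.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import gammaln

from .metagenotype import Metagenotype

MAX_STRAINS = 20
_Q_FLOOR = 1e-12


@dataclass
class StrainModel:
    """Fitted strain mixture for one species.

    ``frequencies`` columns for samples with zero coverage are NaN —
    they carry no information and are excluded rather than set to an
    arbitrary point of the simplex.
    """

    species_id: str
    genotypes: np.ndarray = field(repr=False)   # (K, L) in {0, 1}
    frequencies: np.ndarray = field(repr=False)  # (K, S), per-sample simplex
    samples: list[str]
    positions: list[str]
    error_rate: float
    log_likelihood: float
    n_iter: int
    converged: bool
    degenerate: bool = False

    @property
    def n_strains(self) -> int:
        return self.genotypes.shape[0]


def _log_likelihood(minor, total, q, coeff):
    q = np.clip(q, _Q_FLOOR, 1 - _Q_FLOOR)
    return float(np.sum(minor * np.log(q) + (total - minor) * np.log1p(-q)) + coeff)


def _update_frequencies(minor, total, g, f, eps, covered, max_iter=60, tol=1e-10):
    """EM on per-sample strain frequencies with genotypes held fixed."""
    e1 = eps + (1 - 2 * eps) * g          # (K, L): P(minor read | strain k, site l)
    e0 = 1.0 - e1
    n_tot = total.sum(axis=0)             # (S,)
    prev = -np.inf
    for _ in range(max_iter):
        q = np.clip(e1.T @ f, _Q_FLOOR, 1 - _Q_FLOOR)   # (L, S)
        A = minor / q
        B = (total - minor) / (1.0 - q)
        f_new = f * (e1 @ A + e0 @ B)
        with np.errstate(invalid="ignore", divide="ignore"):
            f_new = f_new / n_tot
        f = np.where(covered, f_new, f)
        ll = np.sum(minor * np.log(q) + (total - minor) * np.log1p(-q))
        if ll - prev < tol * max(1.0, abs(ll)):
            break
        prev = ll
    # renormalise against accumulated round-off
    col = f.sum(axis=0)
    f = f / np.where(col > 0, col, 1.0)
    return f


def _all_genotype_combos(K: int) -> np.ndarray:
    """All 2^K binary allele assignments for one site, shape (2^K, K)."""
    idx = np.arange(2**K)
    return ((idx[:, None] >> np.arange(K)[None, :]) & 1).astype(float)


def _update_genotypes(minor, total, g, f, eps):
    """Likelihood-maximising allele assignment per site given frequencies.

    Sites are independent given f, so each site's K-vector of alleles
    can be maximised exactly.  For K up to 10 all 2^K assignments are
    scored (two matrix products); beyond that a per-(strain, site)
    coordinate sweep is used.  Either way the step never decreases the
    log-likelihood.
    """
    K = g.shape[0]
    if K <= 10:
        combos = _all_genotype_combos(K)                   # (C, K)
        q = np.clip(eps + (1 - 2 * eps) * (combos @ f), _Q_FLOOR, 1 - _Q_FLOOR)  # (C, S)
        # site log-likelihood of every combo: (L, C)
        ll = minor @ np.log(q).T + (total - minor) @ np.log1p(-q).T
        best = np.argmax(ll, axis=1)
        return combos[best].T.copy()                       # (K, L)
    s_mix = g.T @ f                                        # (L, S) mixture sum
    scale = 1 - 2 * eps
    for k in range(K):
        contrib = np.outer(g[k], f[k])
        s_minus = s_mix - contrib
        q0 = np.clip(eps + scale * s_minus, _Q_FLOOR, 1 - _Q_FLOOR)
        q1 = np.clip(eps + scale * (s_minus + f[k][None, :]), _Q_FLOOR, 1 - _Q_FLOOR)
        ll0 = np.sum(minor * np.log(q0) + (total - minor) * np.log1p(-q0), axis=1)
        ll1 = np.sum(minor * np.log(q1) + (total - minor) * np.log1p(-q1), axis=1)
        g[k] = np.where(np.isclose(ll0, ll1), g[k], (ll1 > ll0).astype(float))
        s_mix = s_minus + np.outer(g[k], f[k])
    return g


def fit_strains(
    m: Metagenotype,
    K: int,
    epsilon: float = 0.01,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
    n_restarts: int = 3,
) -> StrainModel:
    """Fit a K-strain mixture to one species' metagenotype.

    Returns the best of ``n_restarts`` seeded initialisations
    (frequencies from a symmetric Dirichlet, genotypes from
    per-position minor-fraction-weighted coin flips).  Convergence is a
    relative log-likelihood change below ``tol`` or ``max_iter`` outer
    iterations.
    """
    if not 1 <= K <= MAX_STRAINS:
        raise ValueError(f"K must be in 1..{MAX_STRAINS}")
    if not 0 <= epsilon < 0.5:
        raise ValueError("epsilon must be in [0, 0.5)")
    minor = m.counts[:, :, 1].astype(float)
    total = m.counts.sum(axis=2).astype(float)
    L, S = total.shape
    covered = total.sum(axis=0) > 0       # (S,)
    coeff = float(np.sum(gammaln(total + 1) - gammaln(minor + 1) - gammaln(total - minor + 1)))

    if not covered.any():
        g = np.zeros((K, L))
        f = np.full((K, S), np.nan)
        f[0] = np.where(covered, 1.0, np.nan)
        return StrainModel(
            m.species_id, g, f, list(m.samples), list(m.positions),
            epsilon, 0.0, 0, True, degenerate=True,
        )

    with np.errstate(invalid="ignore", divide="ignore"):
        pooled = minor.sum(axis=1) / np.maximum(total.sum(axis=1), 1.0)  # (L,)

    ss = np.random.SeedSequence([int(seed) % (2**31), 0])
    best = None
    for child in ss.spawn(n_restarts):
        rng = np.random.default_rng(child)
        f = rng.dirichlet(np.ones(K), size=S).T          # (K, S)
        g = (rng.random((K, L)) < pooled[None, :]).astype(float)
        prev_ll = -np.inf
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            f = _update_frequencies(minor, total, g, f, epsilon, covered)
            g = _update_genotypes(minor, total, g, f, epsilon)
            q = np.clip((epsilon + (1 - 2 * epsilon) * g).T @ f, _Q_FLOOR, 1 - _Q_FLOOR)
            ll = _log_likelihood(minor, total, q, coeff)
            if abs(ll - prev_ll) < tol * max(1.0, abs(ll)):
                converged = True
                prev_ll = ll
                break
            prev_ll = ll
        f = np.where(covered[None, :], f, np.nan)
        model = StrainModel(
            m.species_id, g.astype(int).astype(float), f,
            list(m.samples), list(m.positions),
            epsilon, prev_ll, it, converged,
        )
        if best is None or model.log_likelihood > best.log_likelihood:
            best = model
    return best


def model_log_likelihood(m: Metagenotype, g, f, epsilon: float) -> float:
    """Log-likelihood of arbitrary (g, f) on a metagenotype (for sanity bounds)."""
    minor = m.counts[:, :, 1].astype(float)
    total = m.counts.sum(axis=2).astype(float)
    coeff = float(np.sum(gammaln(total + 1) - gammaln(minor + 1) - gammaln(total - minor + 1)))
    g = np.asarray(g, dtype=float)
    f = np.nan_to_num(np.asarray(f, dtype=float))
    q = (epsilon + (1 - 2 * epsilon) * g).T @ f
    return _log_likelihood(minor, total, q, coeff)


def match_strains(g_true: np.ndarray, g_est: np.ndarray) -> np.ndarray:
    """Optimal strain relabelling: Hungarian assignment on genotype distance.

    Returns ``perm`` such that estimated strain ``perm[k]`` corresponds
    to true strain ``k``.  Inferred strains are defined only up to
    permutation, so any accuracy measure must first align labels.
    """
    g_true = np.asarray(g_true)
    g_est = np.asarray(g_est)
    cost = (g_true[:, None, :] != g_est[None, :, :]).sum(axis=2)
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(len(rows), dtype=int)
    perm[rows] = cols
    return perm


# ---------------------------------------------------------------------------
# Study-wide strain abundance table


def scale_to_coverage(model: StrainModel, species_coverage: pd.Series) -> pd.DataFrame:
    """Strain coverages: within-species frequencies x species coverage.

    ``species_coverage`` is indexed by sample id.  Samples with zero
    species coverage (or excluded from the fit) get strain coverage 0,
    so the conservation invariant sum_k coverage[k, s] ==
    species_coverage[s] holds for every sample.
    """
    rows = []
    for k in range(model.n_strains):
        for j, smp in enumerate(model.samples):
            cov_s = float(species_coverage.get(smp, 0.0))
            fks = model.frequencies[k, j]
            cov = 0.0 if (cov_s == 0 or np.isnan(fks)) else fks * cov_s
            rows.append((f"{model.species_id}_s{k:02d}", model.species_id, smp, cov))
    return pd.DataFrame(rows, columns=["strain_id", "species_id", "sample_id", "coverage"])


def build_strain_table(
    models: dict[str, StrainModel],
    coverage: pd.DataFrame,
    taxonomy: pd.Series,
) -> pd.DataFrame:
    """Tidy strain x sample table with lineage and relative abundance.

    ``coverage`` is the species x sample matrix; ``taxonomy`` maps
    species id to its GTDB-style lineage, inherited by every strain of
    the species.  Relative abundance is normalised per sample over all
    strains of all species.
    """
    parts = []
    for sp in sorted(models):
        cov_row = coverage.loc[sp] if sp in coverage.index else pd.Series(dtype=float)
        part = scale_to_coverage(models[sp], cov_row)
        part["lineage"] = taxonomy.get(sp, "")
        parts.append(part)
    table = pd.concat(parts, ignore_index=True)
    totals = table.groupby("sample_id")["coverage"].transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        table["relative_abundance"] = np.where(
            totals > 0, table["coverage"] / totals, 0.0
        )
    return table[
        ["strain_id", "species_id", "lineage", "sample_id", "coverage", "relative_abundance"]
    ]


def filter_detected(table: pd.DataFrame, detect_threshold: float = 1e-3) -> pd.DataFrame:
    """Keep strains detected (relative abundance strictly above threshold) in >= 2 samples.

    The default threshold sits above the EM frequency-noise floor at
    realistic (~200x) species coverage, so that "detected" reflects a
    genuinely supported strain rather than mixture-model leakage.
    """
    if detect_threshold < 0:
        raise ValueError("detect_threshold must be >= 0")
    detected = table["relative_abundance"] > detect_threshold
    n_det = detected.groupby(table["strain_id"]).sum()
    keep = set(n_det[n_det >= 2].index)
    return table[table["strain_id"].isin(keep)].reset_index(drop=True)


def strain_table_pivot(table: pd.DataFrame, value: str = "relative_abundance") -> pd.DataFrame:
    """Pivot the tidy table to a strain x sample matrix (missing -> 0)."""
    return table.pivot_table(
        index="strain_id", columns="sample_id", values=value, fill_value=0.0, aggfunc="sum"
    )


def strain_lineages(table: pd.DataFrame) -> pd.Series:
    return table.drop_duplicates("strain_id").set_index("strain_id")["lineage"]


def write_strain_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_strain_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_model(model: StrainModel, directory) -> None:
    """Serialise a model: genotypes TSV + frequencies TSV + JSON header."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    strains = [f"{model.species_id}_s{k:02d}" for k in range(model.n_strains)]
    pd.DataFrame(model.genotypes, index=strains, columns=model.positions).to_csv(
        directory / f"{model.species_id}.genotypes.tsv", sep="\t", float_format="%.0f"
    )
    pd.DataFrame(model.frequencies, index=strains, columns=model.samples).to_csv(
        directory / f"{model.species_id}.frequencies.tsv", sep="\t", float_format="%.10g"
    )
    header = {
        "species_id": model.species_id,
        "n_strains": model.n_strains,
        "error_rate": model.error_rate,
        "log_likelihood": model.log_likelihood,
        "n_iter": model.n_iter,
        "converged": model.converged,
        "degenerate": model.degenerate,
    }
    (directory / f"{model.species_id}.json").write_text(json.dumps(header, indent=2))
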