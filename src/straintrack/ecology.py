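"""Community ecology statistics: dissimilarities, ordination, ANOSIM, Mantel.

The longitudinal design of an FMT study means most pairwise sample
comparisons mix within-patient turnover with between-patient
differences.  The Mantel machinery here therefore supports masked
("block-diagonal") dissimilarity matrices in which only within-patient
pairs are defined, and permutes sample identities within patient blocks
so the permutation null respects the repeated-measures structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.manifold import MDS

from ._utils import lineage_taxon


# ---------------------------------------------------------------------------
# Pairwise dissimilarities


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity: 1 - 2 * sum(min(x, y)) / (sum x + sum y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have the same length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundance vectors must be nonnegative")
    total = x.sum() + y.sum()
    if total == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / total)


def cosine_dissimilarity(x, y) -> float:
    """Cosine dissimilarity: 1 - x.y / (|x||y|); for non-compositional profiles."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have the same length")
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("cosine dissimilarity undefined for a zero vector")
    return float(1.0 - float(x @ y) / (nx * ny))


# ---------------------------------------------------------------------------
# Dissimilarity matrices


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise sample dissimilarities with an optional mask.

    ``defined[i, j]`` is False for pairs that carry no information (e.g.
    inter-patient comparisons in a block-diagonal design); masked
    entries of ``data`` are NaN.
    """

    ids: list[str]
    data: np.ndarray = field(repr=False)
    defined: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise ValueError("matrix shape does not match number of ids")
        if self.defined is None:
            self.defined = ~np.isnan(self.data)
            np.fill_diagonal(self.defined, True)
        self.defined = np.asarray(self.defined, dtype=bool)
        if not np.array_equal(self.defined, self.defined.T):
            raise ValueError("mask must be symmetric")
        finite = self.data[self.defined]
        if np.isnan(finite).any():
            raise ValueError("defined entries must be finite")
        d = np.where(self.defined, self.data, 0.0)
        if not np.allclose(d, d.T, equal_nan=False):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.ids)

    def is_complete(self) -> bool:
        return bool(self.defined.all())

    def pair_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the defined upper-triangle pairs (i < j)."""
        iu, ju = np.triu_indices(self.n, k=1)
        keep = self.defined[iu, ju]
        return iu[keep], ju[keep]

    def condensed(self) -> np.ndarray:
        """Defined upper-triangle entries, in (i < j) order."""
        iu, ju = self.pair_indices()
        return self.data[iu, ju]

    def submatrix(self, ids: list[str]) -> "DissimilarityMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DissimilarityMatrix(
            list(ids), self.data[np.ix_(idx, idx)], self.defined[np.ix_(idx, idx)]
        )

    def to_frame(self) -> pd.DataFrame:
        out = np.where(self.defined, self.data, np.nan)
        return pd.DataFrame(out, index=self.ids, columns=self.ids)


def pairwise_dissimilarity(
    profiles: pd.DataFrame, metric: str = "braycurtis"
) -> DissimilarityMatrix:
    """All-pairs dissimilarity over the columns (samples) of a feature table."""
    fn = {"braycurtis": bray_curtis, "cosine": cosine_dissimilarity}[metric]
    ids = list(profiles.columns)
    X = profiles.to_numpy(dtype=float).T
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = fn(X[i], X[j])
    return DissimilarityMatrix(ids, d)


# ---------------------------------------------------------------------------
# Taxonomic aggregation


def aggregate_taxa(
    abundance: pd.DataFrame, lineages: pd.Series, level: str
) -> pd.DataFrame:
    """Sum abundances within taxa at ``level`` ('species', 'family', 'phylum').

    ``abundance`` is feature x sample (strains or species on the rows);
    ``lineages`` maps each row id to its GTDB-style lineage string.
    Per-sample sums are preserved exactly, so simplex columns stay on
    the simplex.
    """
    taxa = {}
    for rid in abundance.index:
        if rid not in lineages.index:
            raise ValueError(f"no lineage for feature {rid!r}")
        try:
            taxa[rid] = lineage_taxon(str(lineages.loc[rid]), level)
        except ValueError as exc:
            raise ValueError(f"malformed lineage for feature {rid!r}: {exc}") from exc
    groups = pd.Series(taxa, name=level)
    out = abundance.groupby(groups).sum()
    out.index.name = level
    return out.sort_index()


def subset_phylum(
    abundance: pd.DataFrame, lineages: pd.Series, phylum: str
) -> pd.DataFrame:
    """Restrict to one phylum and renormalise each sample to sum to one.

    Samples with zero abundance in the phylum are masked (all-NaN
    columns).
    """
    phyla = pd.Series(
        {rid: lineage_taxon(str(lineages.loc[rid]), "phylum") for rid in abundance.index}
    )
    keep = phyla[phyla == phylum].index
    if len(keep) == 0:
        raise ValueError(f"phylum {phylum!r} not present")
    sub = abundance.loc[keep].astype(float)
    totals = sub.sum(axis=0)
    return sub.div(totals.where(totals > 0), axis=1)


# ---------------------------------------------------------------------------
# Ordination


def nmds(
    d: DissimilarityMatrix, k: int = 2, seed: int = 0, n_init: int = 4, max_iter: int = 300
) -> tuple[pd.DataFrame, float]:
    """Non-metric multidimensional scaling of a complete dissimilarity matrix.

    Thin wrapper over scikit-learn's SMACOF-based non-metric MDS;
    coordinates are defined only up to rotation/reflection.  Returns
    (sample x k coordinates, normalised stress).
    """
    if not d.is_complete():
        raise ValueError("NMDS requires a complete (unmasked) dissimilarity matrix")
    import inspect

    params = inspect.signature(MDS.__init__).parameters
    kwargs = dict(
        n_components=k,
        random_state=int(seed),
        n_init=n_init,
        max_iter=max_iter,
        normalized_stress=True,
    )
    if "metric_mds" in params:  # scikit-learn >= 1.9 naming
        kwargs.update(metric_mds=False, metric="precomputed", init="random")
    else:
        kwargs.update(metric=False, dissimilarity="precomputed")
    model = MDS(**kwargs)
    coords = model.fit_transform(d.data)
    cols = [f"NMDS{i + 1}" for i in range(k)]
    return pd.DataFrame(coords, index=d.ids, columns=cols), float(model.stress_)


# ---------------------------------------------------------------------------
# ANOSIM


@dataclass
class AnosimResult:
    R: float
    p: float
    n_permutations: int
    n_samples: int


def _anosim_R(ranks: np.ndarray, within: np.ndarray) -> float:
    M = ranks.size
    rw = ranks[within].mean()
    rb = ranks[~within].mean()
    return float((rb - rw) / (M / 2.0))


def anosim(
    d: DissimilarityMatrix, groups, n_perm: int = 9999, seed: int = 0
) -> AnosimResult:
    """Analysis of similarities: are between-group ranks larger than within?

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2 pairwise dissimilarities ranked with average ties.  The
    permutation p-value is one-sided (greater), with the add-one
    estimator p = (1 + #{R_perm >= R_obs}) / (n_perm + 1).
    """
    if not d.is_complete():
        raise ValueError("ANOSIM requires a complete dissimilarity matrix")
    groups = np.asarray(groups)
    if groups.size != d.n:
        raise ValueError("one group label per sample required")
    if len(np.unique(groups)) < 2:
        raise ValueError("ANOSIM requires at least two groups")
    iu, ju = np.triu_indices(d.n, k=1)
    ranks = rankdata(d.data[iu, ju])
    within = groups[iu] == groups[ju]
    if within.all() or (~within).all():
        raise ValueError("need both within- and between-group pairs")
    r_obs = _anosim_R(ranks, within)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(groups)
        w = perm[iu] == perm[ju]
        if _anosim_R(ranks, w) >= r_obs:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return AnosimResult(R=r_obs, p=p, n_permutations=n_perm, n_samples=d.n)


# ---------------------------------------------------------------------------
# Block-diagonal (within-patient) Mantel machinery


def build_block_matrix(
    profiles: pd.DataFrame,
    sample_patient: pd.Series,
    metric: str = "braycurtis",
    exclude: list[str] | None = None,
) -> DissimilarityMatrix:
    """Within-patient pairwise dissimilarities, inter-patient pairs masked.

    ``sample_patient`` maps each sample (column of ``profiles``) to its
    patient; samples listed in ``exclude`` (e.g. post-antibiotic
    collections) are dropped before computing anything.  Patients with a
    single retained sample contribute no pairs (warning).
    """
    exclude = set(exclude or [])
    ids = [s for s in profiles.columns if s not in exclude]
    fn = {"braycurtis": bray_curtis, "cosine": cosine_dissimilarity}[metric]
    patients = np.asarray([sample_patient.loc[s] for s in ids])
    counts = pd.Series(patients).value_counts()
    singles = counts[counts < 2]
    if len(singles) > 0:
        warnings.warn(
            f"{len(singles)} patient(s) contribute no within-patient pairs"
        )
    n = len(ids)
    X = profiles[ids].to_numpy(dtype=float).T
    data = np.zeros((n, n))
    defined = np.zeros((n, n), dtype=bool)
    np.fill_diagonal(defined, True)
    for i in range(n):
        for j in range(i + 1, n):
            if patients[i] == patients[j]:
                data[i, j] = data[j, i] = fn(X[i], X[j])
                defined[i, j] = defined[j, i] = True
    return DissimilarityMatrix(ids, data, defined)


def time_control_matrix(
    days: pd.Series, sample_patient: pd.Series, transform: str = "sqrt_interval"
) -> DissimilarityMatrix:
    """Control matrix for partial Mantel: sqrt of the between-sample interval.

    Entry (i, j) = sqrt(|days_i - days_j|) for within-patient pairs.
    The square root damps the influence of very long intervals; the
    alternative reading |sqrt(days_i) - sqrt(days_j)| is not used.
    """
    ids = list(days.index)
    patients = np.asarray([sample_patient.loc[s] for s in ids])
    t = days.to_numpy(dtype=float)
    n = len(ids)
    data = np.zeros((n, n))
    defined = np.zeros((n, n), dtype=bool)
    np.fill_diagonal(defined, True)
    for i in range(n):
        for j in range(i + 1, n):
            if patients[i] == patients[j]:
                dt = abs(t[i] - t[j])
                data[i, j] = data[j, i] = np.sqrt(dt) if transform == "sqrt_interval" else dt
                defined[i, j] = defined[j, i] = True
    return DissimilarityMatrix(ids, data, defined)


@dataclass
class MantelResult:
    r: float
    p: float
    n_pairs: int
    n_permutations: int


def _mask_blocks(d: DissimilarityMatrix) -> list[np.ndarray]:
    """Connected components of the defined-pair graph = permutation blocks."""
    n = d.n
    seen = np.zeros(n, dtype=bool)
    blocks = []
    adj = d.defined.copy()
    np.fill_diagonal(adj, False)
    for start in range(n):
        if seen[start]:
            continue
        stack = [start]
        comp = []
        seen[start] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for w in np.flatnonzero(adj[v]):
                if not seen[w]:
                    seen[w] = True
                    stack.append(int(w))
        blocks.append(np.sort(np.asarray(comp)))
    return blocks


def _check_compatible(da: DissimilarityMatrix, db: DissimilarityMatrix) -> None:
    if da.ids != db.ids:
        raise ValueError("matrices must share the same sample set and order")
    if not np.array_equal(da.defined, db.defined):
        raise ValueError("matrices must share the same mask")


def _permuted_vector(
    d: DissimilarityMatrix, blocks: list[np.ndarray], rng: np.random.Generator,
    iu: np.ndarray, ju: np.ndarray,
) -> np.ndarray:
    perm = np.arange(d.n)
    for block in blocks:
        perm[block] = block[rng.permutation(block.size)]
    return d.data[perm[iu], perm[ju]]


def mantel(
    da: DissimilarityMatrix,
    db: DissimilarityMatrix,
    n_perm: int = 9999,
    seed: int = 0,
) -> MantelResult:
    """Mantel test: Pearson correlation of two (masked) distance matrices.

    The null is generated by permuting sample identities of ``db``
    independently within each block of the mask (for a complete matrix
    this is the ordinary Mantel permutation); p is two-sided on |r| with
    the add-one estimator.
    """
    _check_compatible(da, db)
    iu, ju = da.pair_indices()
    if iu.size < 3:
        raise ValueError("need at least 3 defined pairs")
    va = da.data[iu, ju]
    vb = db.data[iu, ju]
    if va.std() == 0 or vb.std() == 0:
        raise ValueError("degenerate (constant) dissimilarities")
    r_obs = float(np.corrcoef(va, vb)[0, 1])
    blocks = _mask_blocks(da)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        vp = _permuted_vector(db, blocks, rng, iu, ju)
        if vp.std() == 0:
            continue
        if abs(float(np.corrcoef(va, vp)[0, 1])) >= abs(r_obs) - 1e-12:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return MantelResult(r=r_obs, p=p, n_pairs=int(iu.size), n_permutations=n_perm)


def _residuals(v: np.ndarray, on: np.ndarray) -> np.ndarray:
    """Residuals of a simple linear regression of v on `on`."""
    X = np.column_stack([np.ones_like(on), on])
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ beta


def partial_mantel(
    da: DissimilarityMatrix,
    db: DissimilarityMatrix,
    dc: DissimilarityMatrix,
    n_perm: int = 9999,
    seed: int = 0,
) -> MantelResult:
    """Partial Mantel: correlation of da and db residualised on dc.

    Used to control for elapsed time between collections: both matrices
    are regressed on the control, and the correlation of residuals is
    tested by permuting ``db`` within blocks (recomputing its residuals
    each time).
    """
    _check_compatible(da, db)
    _check_compatible(da, dc)
    iu, ju = da.pair_indices()
    if iu.size < 3:
        raise ValueError("need at least 3 defined pairs")
    va = da.data[iu, ju]
    vb = db.data[iu, ju]
    vc = dc.data[iu, ju]
    if va.std() == 0 or vb.std() == 0:
        raise ValueError("degenerate (constant) dissimilarities")
    ra = _residuals(va, vc)
    rb = _residuals(vb, vc)
    # a residual spread at round-off scale means the control explains
    # that matrix completely; the partial correlation is then zero
    tol_a = 1e-10 * max(1.0, float(va.std()))
    tol_b = 1e-10 * max(1.0, float(vb.std()))
    if ra.std() <= tol_a or rb.std() <= tol_b:
        r_obs = 0.0
    else:
        r_obs = float(np.corrcoef(ra, rb)[0, 1])
    blocks = _mask_blocks(da)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        vp = _permuted_vector(db, blocks, rng, iu, ju)
        rp = _residuals(vp, vc)
        if rp.std() == 0:
            continue
        if abs(float(np.corrcoef(ra, rp)[0, 1])) >= abs(r_obs) - 1e-12:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return MantelResult(r=r_obs, p=p, n_pairs=int(iu.size), n_permutations=n_perm)
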