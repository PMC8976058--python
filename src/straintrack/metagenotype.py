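"""Metagenotype tables: per-species biallelic allele counts across samples.

A metagenotype is the output format of k-mer based SNP counters
(GT-PRO-style): for each species and each known biallelic position, the
number of reads supporting the major and the minor allele in every
sample.  Site coverage (major + minor) drives species abundance
estimation; the allele split drives strain deconvolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TSV_COLUMNS = ["species_id", "position_id", "sample_id", "major_count", "minor_count"]


@dataclass
class Metagenotype:
    """Allele counts for one species: position x sample x {major, minor}.

    ``counts`` has shape ``(n_positions, n_samples, 2)`` with the major
    allele in channel 0 and the minor allele in channel 1.
    """

    species_id: str
    positions: list[str]
    samples: list[str]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.positions), len(self.samples), 2):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.positions)} positions x {len(self.samples)} samples x 2"
            )
        if (self.counts < 0).any():
            raise ValueError("negative allele counts")
        if len(set(self.positions)) != len(self.positions):
            raise ValueError("duplicate position identifiers")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample identifiers")

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def site_coverage(self) -> np.ndarray:
        """Total reads (major + minor) per position x sample."""
        return self.counts.sum(axis=2)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with one row per (position, sample)."""
        pos = np.repeat(self.positions, self.n_samples)
        smp = np.tile(self.samples, self.n_positions)
        flat = self.counts.reshape(-1, 2)
        return pd.DataFrame(
            {
                "species_id": self.species_id,
                "position_id": pos,
                "sample_id": smp,
                "major_count": flat[:, 0],
                "minor_count": flat[:, 1],
            }
        )


def read_metagenotype(path) -> dict[str, Metagenotype]:
    """Read a metagenotype TSV into a ``{species_id: Metagenotype}`` dict.

    The expected header is ``species_id position_id sample_id
    major_count minor_count``; unknown columns are ignored with a
    warning, malformed or negative rows raise ``ValueError`` naming the
    offending line (1-based, header = line 1).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    extra = [c for c in df.columns if c not in TSV_COLUMNS]
    if extra:
        warnings.warn(f"ignoring unknown metagenotype columns: {extra}")
        df = df.drop(columns=extra)
    missing = [c for c in TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metagenotype file missing columns: {missing}")
    for col in ("major_count", "minor_count"):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() | (values % 1 != 0)
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise ValueError(f"malformed {col} at line {line}")
        if (values < 0).any():
            line = int(np.flatnonzero((values < 0).to_numpy())[0]) + 2
            raise ValueError(f"negative {col} at line {line}")
        df[col] = values.astype(np.int64)

    out: dict[str, Metagenotype] = {}
    for species_id, grp in df.groupby("species_id", sort=True):
        positions = list(pd.unique(grp["position_id"]))
        samples = list(pd.unique(grp["sample_id"]))
        pidx = {p: i for i, p in enumerate(positions)}
        sidx = {s: i for i, s in enumerate(samples)}
        counts = np.zeros((len(positions), len(samples), 2), dtype=np.int64)
        pi = grp["position_id"].map(pidx).to_numpy()
        si = grp["sample_id"].map(sidx).to_numpy()
        counts[pi, si, 0] = grp["major_count"].to_numpy()
        counts[pi, si, 1] = grp["minor_count"].to_numpy()
        out[str(species_id)] = Metagenotype(str(species_id), positions, samples, counts)
    return out


def write_metagenotype(collection: dict[str, Metagenotype], path) -> None:
    """Write a metagenotype collection as TSV; inverse of ``read_metagenotype``."""
    frames = [collection[k].to_frame() for k in sorted(collection)]
    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.DataFrame(columns=TSV_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def trimmed_mean_coverage(site_coverage: np.ndarray, trim: float = 0.05) -> float:
    """Mean site coverage after dropping the extreme tails.

    The ``floor(trim * L)`` largest and the same number of smallest
    coverage values are discarded before averaging (ties broken by
    position order), which makes the estimate robust to anomalously
    high- or low-coverage sites.  Returns 0.0 for an empty input.
    """
    c = np.asarray(site_coverage, dtype=float)
    L = c.size
    if L == 0:
        return 0.0
    k = int(np.floor(trim * L))
    order = np.argsort(c, kind="stable")
    kept = order[k: L - k] if k > 0 else order
    return float(c[kept].mean())


def species_coverage(m: Metagenotype, sample: str, trim: float = 0.05) -> float:
    """Trimmed-mean depth of one species in one sample."""
    j = m.samples.index(sample)
    return trimmed_mean_coverage(m.counts[:, j, :].sum(axis=1), trim=trim)


def coverage_table(collection: dict[str, Metagenotype], trim: float = 0.05) -> pd.DataFrame:
    """Species x sample trimmed-mean coverage matrix.

    Samples absent from a species' table get coverage 0.
    """
    all_samples: list[str] = []
    for m in collection.values():
        for s in m.samples:
            if s not in all_samples:
                all_samples.append(s)
    all_samples = sorted(all_samples)
    species = sorted(collection)
    mat = np.zeros((len(species), len(all_samples)))
    for i, sp in enumerate(species):
        m = collection[sp]
        cov = m.site_coverage()
        for j_local, smp in enumerate(m.samples):
            mat[i, all_samples.index(smp)] = trimmed_mean_coverage(cov[:, j_local], trim=trim)
    return pd.DataFrame(mat, index=pd.Index(species, name="species_id"), columns=all_samples)


def relative_abundance(coverage: pd.DataFrame) -> pd.DataFrame:
    """Per-sample relative abundances from a species x sample coverage matrix.

    Each column is normalised to sum to one.  A sample with zero total
    coverage carries no information and is flagged missing (all-NaN
    column) rather than given arbitrary zeros.
    """
    cov = coverage.astype(float)
    if (cov.to_numpy() < 0).any():
        raise ValueError("coverages must be nonnegative")
    totals = cov.sum(axis=0)
    rel = cov.div(totals.where(totals > 0), axis=1)
    return rel


def subsample_positions(m: Metagenotype, n: int = 100, seed: int = 0) -> Metagenotype:
    """Uniformly subsample ``n`` positions without replacement.

    Strain deconvolution does not need every site; a fixed random subset
    keeps the fit cheap.  If the species has at most ``n`` positions the
    input is returned unchanged (same object contents, new container).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if m.n_positions <= n:
        idx = np.arange(m.n_positions)
    else:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(m.n_positions, size=n, replace=False))
    return Metagenotype(
        m.species_id,
        [m.positions[i] for i in idx],
        list(m.samples),
        m.counts[idx],
    )


def write_species_profile(frame: pd.DataFrame, path) -> None:
    """Write a species x sample matrix TSV with header row and column."""
    frame.to_csv(path, sep="\t", float_format="%.10g")


def read_species_profile(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
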