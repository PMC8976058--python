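"""Synthetic FMT study generator: truth plus observed tables.

Emulates the statistical structure of a randomized 2x2 FMT trial for
ulcerative colitis: a few stool donors and ~22 patients sampled at
baseline (B), during six weekly maintenance doses (D1-D6), and at three
follow-ups (F1-F3).  Gut communities are heavy-tailed mixtures of
multi-strain species; the transplant replaces part of each patient's
baseline strain population with donor strains, with arm- and
phylum-dependent engraftment; sequencing yields binomial allele counts
with error; bile-acid and functional-gene profiles are patient-stable
and weakly coupled to composition; remission is Bernoulli with
arm-dependent log-odds.

Every stochastic step draws from its own child stream of a single root
seed, so the full study is bit-reproducible and adding one stage never
perturbs another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import make_lineage, parse_lineage
from .metagenotype import Metagenotype

# Six most abundant phyla and their baseline relative-abundance weights.
DEFAULT_PHYLUM_WEIGHTS = {
    "Firmicutes_A": 0.540,
    "Bacteroidota": 0.183,
    "Actinobacteriota": 0.104,
    "Firmicutes": 0.081,
    "Proteobacteria": 0.036,
    "Firmicutes_C": 0.028,
}

#: Study calendar: label -> days since the initial FMT (maintenance doses
#: weekly, follow-ups ~2, 6 and 14 weeks after the last dose).
DEFAULT_TIMEPOINTS = {
    "B": -7.0,
    "D1": 7.0, "D2": 14.0, "D3": 21.0, "D4": 28.0,
    "D5": 35.0, "D6": 42.0,
    "F1": 56.0, "F2": 84.0, "F3": 140.0,
}

ORIGIN_LABELS = ("baseline", "donor", "both", "neither")


def default_engraftment_prob() -> dict[tuple[str, str], float]:
    """Per-(arm, phylum) transfer probability of a donor strain.

    Base rates follow the observed per-phylum transferability ordering
    (Bacteroidota high, Verrucomicrobiota-like low); antibiotic
    pretreatment raises them, no pretreatment lowers them.
    """
    base = {
        "Firmicutes_A": 0.26,
        "Bacteroidota": 0.34,
        "Actinobacteriota": 0.29,
        "Firmicutes": 0.22,
        "Proteobacteria": 0.25,
        "Firmicutes_C": 0.20,
    }
    out = {}
    for ph, p in base.items():
        out[("ABX+", ph)] = min(1.0, p * 1.25)
        out[("ABX-", ph)] = p * 0.75
    return out


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; defaults mirror the trial design."""

    n_donors: int = 3
    n_patients: int = 22
    n_species: int = 50
    strains_per_species: tuple[int, int] = (2, 4)
    positions_per_species: int = 200
    phylum_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PHYLUM_WEIGHTS)
    )
    engraftment_prob: dict[tuple[str, str], float] = field(
        default_factory=default_engraftment_prob
    )
    displacement_prob: dict[str, float] = field(
        default_factory=lambda: {"ABX+": 0.7, "ABX-": 0.3}
    )
    mean_coverage: float = 1000.0
    seq_error: float = 0.01
    depth_sd: float = 0.3
    timepoints: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TIMEPOINTS))
    donor_sample_counts: tuple[int, ...] | None = None
    subset_prob: float = 0.5
    community_sigma: float = 1.0
    jitter_sigma: float = 0.2
    ba_n_features: int = 51
    fg_n_features: int = 120
    ba_patient_sd: float = 1.0
    ba_noise_sd: float = 0.3
    ba_taxa_coupling: float = 0.5
    remission_logodds: dict[str, float] = field(
        default_factory=lambda: {
            "ABX+": math.log(6 / 5),   # 6 of 11 remitted
            "ABX-": math.log(2 / 9),   # 2 of 11
        }
    )
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.strains_per_species
        if not 1 <= lo <= hi <= 20:
            raise ValueError("strains_per_species must be within 1..20")
        if self.positions_per_species < 2:
            raise ValueError("need at least 2 positions per species")
        for p in list(self.engraftment_prob.values()) + list(self.displacement_prob.values()):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if not 0 <= self.seq_error < 0.5:
            raise ValueError("seq_error must be in [0, 0.5)")
        if not 0 <= self.subset_prob <= 1:
            raise ValueError("subset_prob must be in [0, 1]")
        total = sum(self.phylum_weights.values())
        if total <= 0:
            raise ValueError("phylum weights must have positive sum")
        self.phylum_weights = {k: v / total for k, v in self.phylum_weights.items()}
        days = list(self.timepoints.values())
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("timepoints must be strictly increasing in days")
        if self.donor_sample_counts is None:
            # uneven replication, echoing real donor sampling depth (10/31/1)
            pattern = (10, 31, 1)
            self.donor_sample_counts = tuple(
                pattern[i % len(pattern)] for i in range(self.n_donors)
            )
        if len(self.donor_sample_counts) != self.n_donors:
            raise ValueError("donor_sample_counts length must equal n_donors")
        if any(c < 1 for c in self.donor_sample_counts):
            raise ValueError("every donor needs at least one sample")

    def rngs(self, n: int = 8) -> list[np.random.Generator]:
        ss = np.random.SeedSequence(self.rng_seed)
        return [np.random.default_rng(s) for s in ss.spawn(n)]


@dataclass
class StrainPool:
    """Reference pool: binary haplotypes per species plus taxonomy."""

    haplotypes: dict[str, np.ndarray]       # species -> (K, L) in {0, 1}
    taxonomy: pd.Series                     # species -> lineage
    strain_ids: list[str]
    strain_species: pd.Series               # strain -> species
    strain_phylum: pd.Series                # strain -> phylum


@dataclass
class TrueStudy:
    """Ground truth: community compositions, origins, transfer events."""

    metadata: pd.DataFrame
    true_community: pd.DataFrame            # strain x sample, columns on simplex
    origin_truth: pd.DataFrame              # patient, strain_id, label
    transfer_truth: pd.DataFrame            # patient, strain_id, phylum, transferred
    baseline_support: dict[str, set]
    donor_support: dict[str, set]


# ---------------------------------------------------------------------------
# Strain pool


def simulate_strain_pool(config: SimulationConfig, rng=None) -> StrainPool:
    """Draw binary haplotypes and a GTDB-style lineage for each species.

    Haplotypes are fair-coin allele vectors, redrawn (bounded retries)
    until pairwise distinct.  Phyla are drawn from the configured
    baseline weights; species are grouped two-per-family within a
    phylum to give the family level some structure.
    """
    rng = rng if rng is not None else config.rngs()[0]
    L = config.positions_per_species
    lo, hi = config.strains_per_species
    phyla = list(config.phylum_weights)
    weights = np.array([config.phylum_weights[p] for p in phyla])
    haplotypes: dict[str, np.ndarray] = {}
    lineages: dict[str, str] = {}
    strain_ids: list[str] = []
    strain_species: dict[str, str] = {}
    strain_phylum: dict[str, str] = {}
    per_phylum_count: dict[str, int] = {p: 0 for p in phyla}
    for i in range(config.n_species):
        sp = f"sp{i:04d}"
        K = int(rng.integers(lo, hi + 1))
        g = rng.integers(0, 2, size=(K, L)).astype(np.int8)
        for _ in range(100):
            if len({tuple(row) for row in g}) == K:
                break
            g = rng.integers(0, 2, size=(K, L)).astype(np.int8)
        else:
            raise RuntimeError(
                f"could not draw {K} distinct haplotypes of length {L} for {sp}"
            )
        phylum = phyla[int(rng.choice(len(phyla), p=weights))]
        j = per_phylum_count[phylum]
        per_phylum_count[phylum] += 1
        lineages[sp] = make_lineage(
            domain="Bacteria",
            phylum=phylum,
            **{"class": f"{phylum}_c"},
            order=f"{phylum}_o",
            family=f"{phylum}_fam{j // 2:03d}",
            genus=f"g_{sp}",
            species=f"s_{sp}",
        )
        haplotypes[sp] = g
        for k in range(K):
            sid = f"{sp}_s{k:02d}"
            strain_ids.append(sid)
            strain_species[sid] = sp
            strain_phylum[sid] = phylum
    return StrainPool(
        haplotypes=haplotypes,
        taxonomy=pd.Series(lineages, name="lineage"),
        strain_ids=strain_ids,
        strain_species=pd.Series(strain_species),
        strain_phylum=pd.Series(strain_phylum),
    )


# ---------------------------------------------------------------------------
# Study metadata


def make_metadata(config: SimulationConfig) -> pd.DataFrame:
    """Sample sheet: donors with replicate samples, patients with the full calendar.

    Arms cycle through the 2x2 design; each patient is assigned one
    donor round-robin.
    """
    rows = []
    donors = [f"D{i + 1:02d}" for i in range(config.n_donors)]
    for d, n_samples in zip(donors, config.donor_sample_counts):
        for i in range(n_samples):
            rows.append(
                (f"{d}_smp{i:02d}", d, "donor", "", "", "", "DNR", np.nan)
            )
    arms = [("ABX+", "CAPS"), ("ABX+", "ENMA"), ("ABX-", "CAPS"), ("ABX-", "ENMA")]
    for i in range(config.n_patients):
        subj = f"P{i + 1:02d}"
        abx, maint = arms[i % 4]
        donor = donors[i % len(donors)]
        for tp, day in config.timepoints.items():
            rows.append((f"{subj}_{tp}", subj, "patient", donor, abx, maint, tp, day))
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id", "subject_id", "role", "donor_assigned",
            "arm_abx", "arm_maint", "timepoint", "days_since_fmt",
        ],
    )


# ---------------------------------------------------------------------------
# Communities


def _draw_community(strain_ids, rng, subset_prob, sigma) -> pd.Series:
    """Log-normal weights over a random subset of the pool, normalised."""
    keep = rng.random(len(strain_ids)) < subset_prob
    if not keep.any():
        keep[rng.integers(len(strain_ids))] = True
    w = np.zeros(len(strain_ids))
    w[keep] = rng.lognormal(mean=0.0, sigma=sigma, size=int(keep.sum()))
    return pd.Series(w / w.sum(), index=strain_ids)


def _jittered(base: pd.Series, rng, sigma: float) -> pd.Series:
    if sigma == 0:
        return base.copy()
    w = base.to_numpy() * rng.lognormal(0.0, sigma, size=len(base))
    total = w.sum()
    return pd.Series(w / total if total > 0 else base.to_numpy(), index=base.index)


def simulate_communities(
    config: SimulationConfig, pool: StrainPool, metadata: pd.DataFrame, rng=None
) -> TrueStudy:
    """Donor and patient strain compositions, before and after FMT.

    Each subject's pre-FMT community is a log-normal-weighted random
    subset of the strain pool.  After FMT, every baseline strain is
    retained with probability 1 - displacement_prob[arm] and every
    donor strain transfers with probability engraftment_prob[(arm,
    phylum)]; retained and transferred weights are combined and
    renormalised, then held across D1-F3 with multiplicative log-normal
    jitter.  If nothing survives, the single largest baseline strain is
    kept.
    """
    rng = rng if rng is not None else config.rngs()[1]
    ids = pool.strain_ids
    donors = metadata.loc[metadata["role"] == "donor", "subject_id"].unique()
    patients = metadata.loc[metadata["role"] == "patient", "subject_id"].unique()

    donor_base = {d: _draw_community(ids, rng, config.subset_prob, config.community_sigma)
                  for d in donors}
    patient_base = {p: _draw_community(ids, rng, config.subset_prob, config.community_sigma)
                    for p in patients}

    columns: dict[str, pd.Series] = {}
    origin_rows = []
    transfer_rows = []
    baseline_support: dict[str, set] = {}
    donor_support: dict[str, set] = {d: set(np.array(ids)[donor_base[d] > 0]) for d in donors}

    for _, row in metadata[metadata["role"] == "donor"].iterrows():
        columns[row["sample_id"]] = _jittered(
            donor_base[row["subject_id"]], rng, config.jitter_sigma
        )

    for p in patients:
        meta_p = metadata[(metadata["subject_id"] == p)]
        arm = meta_p["arm_abx"].iloc[0]
        donor = meta_p["donor_assigned"].iloc[0]
        base = patient_base[p]
        dbase = donor_base[donor]
        b_sup = set(np.array(ids)[base.to_numpy() > 0])
        d_sup = donor_support[donor]
        baseline_support[p] = b_sup

        for sid in ids:
            in_b, in_d = sid in b_sup, sid in d_sup
            label = ("both" if in_b and in_d else
                     "baseline" if in_b else
                     "donor" if in_d else "neither")
            origin_rows.append((p, sid, label))

        p_disp = config.displacement_prob[arm]
        retained = {s for s in b_sup if rng.random() < 1.0 - p_disp}
        transferred = set()
        for sid in sorted(d_sup):
            ph = pool.strain_phylum[sid]
            p_eng = config.engraftment_prob[(arm, ph)]
            took = rng.random() < p_eng
            if took:
                transferred.add(sid)
            if sid not in b_sup:  # a donor-specific opportunity
                transfer_rows.append((p, sid, ph, took))

        post = pd.Series(0.0, index=ids)
        for sid in retained:
            post[sid] += base[sid]
        for sid in transferred:
            post[sid] += dbase[sid]
        if post.sum() == 0:
            post[base.idxmax()] = 1.0
        else:
            post = post / post.sum()

        for _, srow in meta_p.iterrows():
            tp = srow["timepoint"]
            source = base if tp == "B" else post
            columns[srow["sample_id"]] = _jittered(source, rng, config.jitter_sigma)

    community = pd.DataFrame(columns).reindex(
        columns=metadata["sample_id"].tolist()
    )
    community.index.name = "strain_id"
    return TrueStudy(
        metadata=metadata,
        true_community=community,
        origin_truth=pd.DataFrame(origin_rows, columns=["patient", "strain_id", "label"]),
        transfer_truth=pd.DataFrame(
            transfer_rows, columns=["patient", "strain_id", "phylum", "transferred"]
        ),
        baseline_support=baseline_support,
        donor_support=donor_support,
    )


# ---------------------------------------------------------------------------
# Sequencing counts


def simulate_metagenotype(
    true_community: pd.DataFrame,
    pool: StrainPool,
    config: SimulationConfig,
    rng=None,
) -> dict[str, Metagenotype]:
    """Binomial allele counts at every SNP site of every species.

    Site totals are Poisson with mean (mean_coverage x species relative
    abundance x per-sample depth factor); the minor-allele fraction is
    eps + (1 - 2 eps) * sum_k f_k g_kl over the within-species strain
    frequencies f.
    """
    rng = rng if rng is not None else config.rngs()[2]
    eps = config.seq_error
    samples = list(true_community.columns)
    depth = rng.lognormal(0.0, config.depth_sd, size=len(samples))
    out: dict[str, Metagenotype] = {}
    for sp, g in pool.haplotypes.items():
        K, L = g.shape
        strain_rows = [f"{sp}_s{k:02d}" for k in range(K)]
        abund = true_community.reindex(strain_rows).fillna(0.0).to_numpy()  # (K, S)
        sp_rel = abund.sum(axis=0)                                          # (S,)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(sp_rel > 0, abund / sp_rel, 0.0)
        lam = config.mean_coverage * sp_rel * depth
        totals = rng.poisson(np.broadcast_to(lam, (L, len(samples))))
        q = eps + (1 - 2 * eps) * (g.T.astype(float) @ f)                   # (L, S)
        minor = rng.binomial(totals, np.clip(q, 0.0, 1.0))
        counts = np.stack([totals - minor, minor], axis=2)
        positions = [f"pos{j:05d}" for j in range(L)]
        out[sp] = Metagenotype(sp, positions, samples, counts)
    return out


# ---------------------------------------------------------------------------
# Auxiliary profiles


def _loading_profiles(
    composition: pd.DataFrame,
    subjects: pd.Series,
    n_features: int,
    patient_sd: float,
    noise_sd: float,
    coupling: float,
    rng,
    prefix: str,
) -> pd.DataFrame:
    n_taxa = composition.shape[0]
    samples = list(composition.columns)
    subj_list = sorted(subjects.unique())
    intercepts = {
        s: rng.normal(0.0, patient_sd, size=n_features) for s in subj_list
    }
    loadings = rng.normal(0.0, 1.0, size=(n_features, n_taxa))
    comp = composition.to_numpy()
    values = np.empty((n_features, len(samples)))
    for j, smp in enumerate(samples):
        mean = intercepts[subjects[smp]] + coupling * (loadings @ comp[:, j])
        values[:, j] = np.exp(mean + rng.normal(0.0, noise_sd, size=n_features))
    return pd.DataFrame(
        values, index=[f"{prefix}{i:03d}" for i in range(n_features)], columns=samples
    )


def simulate_auxiliary_profiles(
    true_community: pd.DataFrame,
    pool: StrainPool,
    metadata: pd.DataFrame,
    config: SimulationConfig,
    rng=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bile-acid and functional-gene tables (feature x sample, nonnegative).

    Each feature is exp(subject intercept + coupling * loading .
    composition + noise): subject intercepts make profiles
    patient-stable, the loading term couples them (weakly, by default)
    to taxonomic composition.  Bile acids respond to phylum-level
    composition, gene families to species-level composition.
    """
    rng = rng if rng is not None else config.rngs()[3]
    subjects = metadata.set_index("sample_id")["subject_id"]
    phylum_of = pool.strain_phylum
    phyl_comp = true_community.groupby(
        pd.Series({s: phylum_of[s] for s in true_community.index})
    ).sum()
    species_of = pool.strain_species
    sp_comp = true_community.groupby(
        pd.Series({s: species_of[s] for s in true_community.index})
    ).sum()
    ba = _loading_profiles(
        phyl_comp, subjects, config.ba_n_features,
        config.ba_patient_sd, config.ba_noise_sd, config.ba_taxa_coupling,
        rng, "ba",
    )
    genes = _loading_profiles(
        sp_comp, subjects, config.fg_n_features,
        config.ba_patient_sd, config.ba_noise_sd, config.ba_taxa_coupling,
        rng, "ko",
    )
    return ba, genes


# ---------------------------------------------------------------------------
# Clinical outcomes


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def simulate_outcomes(
    config: SimulationConfig, metadata: pd.DataFrame, rng=None
) -> pd.DataFrame:
    """Mayo score tables at D0 and F1 consistent with drawn remission flags.

    Remission is Bernoulli(logistic(remission_logodds[arm])).  D0
    scores satisfy trial eligibility (total 4-9, endoscopy 1-2); for a
    remitting patient the F1 total is <= 2 with the endoscopic subscore
    decreased by >= 1, otherwise the F1 total stays >= 3.
    """
    rng = rng if rng is not None else config.rngs()[4]
    patients = metadata.loc[metadata["role"] == "patient"]
    per_patient = patients.drop_duplicates("subject_id")[["subject_id", "arm_abx"]]
    rows = []
    for _, prow in per_patient.iterrows():
        subj, arm = prow["subject_id"], prow["arm_abx"]
        remit = bool(rng.random() < _sigmoid(config.remission_logodds[arm]))
        endo0 = int(rng.integers(1, 3))
        while True:
            sf0 = int(rng.integers(1, 4))
            rb0 = int(rng.integers(0, 4))
            pg0 = int(rng.integers(1, 3))
            if 4 <= sf0 + rb0 + endo0 + pg0 <= 9:
                break
        rows.append((subj, "D0", sf0, rb0, endo0, pg0, sf0 + rb0 + endo0 + pg0))
        if remit:
            endo1 = endo0 - 1
            budget = 2 - endo1
            sf1 = int(rng.integers(0, min(1, budget) + 1))
            pg1 = int(rng.integers(0, max(0, budget - sf1) + 1))
            rb1 = 0
        else:
            total0 = sf0 + rb0 + endo0 + pg0
            target = max(3, total0 - int(rng.integers(0, 4)))
            endo1 = endo0
            sf1, rb1, pg1 = sf0, rb0, pg0
            # walk non-endoscopy subscores down to the target total
            while sf1 + rb1 + endo1 + pg1 > target:
                choices = [c for c in ("sf", "rb", "pg")
                           if {"sf": sf1, "rb": rb1, "pg": pg1}[c] > 0]
                if not choices:
                    break
                pick = choices[int(rng.integers(len(choices)))]
                if pick == "sf":
                    sf1 -= 1
                elif pick == "rb":
                    rb1 -= 1
                else:
                    pg1 -= 1
        rows.append((subj, "F1", sf1, rb1, endo1, pg1, sf1 + rb1 + endo1 + pg1))
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id", "visit", "stool_frequency", "rectal_bleeding",
            "endoscopy", "physician_global", "total",
        ],
    )


# ---------------------------------------------------------------------------
# Full study


@dataclass
class SyntheticStudy:
    config: SimulationConfig
    pool: StrainPool
    metadata: pd.DataFrame
    truth: TrueStudy
    metagenotypes: dict[str, Metagenotype]
    bile_acids: pd.DataFrame
    gene_families: pd.DataFrame
    clinical: pd.DataFrame


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate a complete study (truth and observed tables) from one seed."""
    rngs = config.rngs()
    pool = simulate_strain_pool(config, rngs[0])
    metadata = make_metadata(config)
    truth = simulate_communities(config, pool, metadata, rngs[1])
    mgt = simulate_metagenotype(truth.true_community, pool, config, rngs[2])
    ba, genes = simulate_auxiliary_profiles(
        truth.true_community, pool, metadata, config, rngs[3]
    )
    clinical = simulate_outcomes(config, metadata, rngs[4])
    return SyntheticStudy(
        config=config, pool=pool, metadata=metadata, truth=truth,
        metagenotypes=mgt, bile_acids=ba, gene_families=genes, clinical=clinical,
    )


def write_study(study: SyntheticStudy, directory) -> None:
    """Write all observed tables plus ``truth_``-prefixed tables for tests."""
    from pathlib import Path

    from .metagenotype import write_metagenotype

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_metagenotype(study.metagenotypes, d / "metagenotype.tsv")
    study.pool.taxonomy.rename_axis("species_id").reset_index().to_csv(
        d / "taxonomy.tsv", sep="\t", index=False
    )
    study.metadata.to_csv(d / "metadata.tsv", sep="\t", index=False)
    study.bile_acids.rename_axis("feature_id").to_csv(
        d / "bile_acids.tsv", sep="\t", float_format="%.10g"
    )
    study.gene_families.rename_axis("feature_id").to_csv(
        d / "gene_families.tsv", sep="\t", float_format="%.10g"
    )
    study.clinical.to_csv(d / "clinical.tsv", sep="\t", index=False)
    study.truth.true_community.to_csv(
        d / "truth_community.tsv", sep="\t", float_format="%.10g"
    )
    study.truth.origin_truth.to_csv(d / "truth_origin.tsv", sep="\t", index=False)
    study.truth.transfer_truth.to_csv(d / "truth_transfer.tsv", sep="\t", index=False)
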