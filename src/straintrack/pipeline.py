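"""End-to-end orchestration: simulate -> genotype -> deconvolve -> track -> test.

Each stage reads and writes plain TSV tables in an output directory and
records row counts, parameters and seeds in a JSON manifest, so every
number in the outputs is traceable to a seed and a config.  Stages
never mutate another stage's outputs; a rerun with ``resume=True``
skips stages whose outputs already exist.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._utils import child_seed, lineage_taxon
from .clinical import (
    fisher_exact,
    mayo_from_row,
    read_clinical,
    remission,
    remission_table,
    responder,
    wilcoxon_signed_rank,
)
from .deconvolution import (
    build_strain_table,
    filter_detected,
    fit_strains,
    read_strain_table,
    strain_lineages,
    strain_table_pivot,
    write_strain_table,
)
from .ecology import (
    aggregate_taxa,
    anosim,
    build_block_matrix,
    mantel,
    nmds,
    pairwise_dissimilarity,
    partial_mantel,
    time_control_matrix,
)
from .engraftment import (
    classify_origin,
    origin_fraction_trajectories,
    phylum_transfer_test,
    read_metadata,
    similarity_to,
    transferability,
)
from .metagenotype import (
    coverage_table,
    read_metagenotype,
    relative_abundance,
    subsample_positions,
    write_species_profile,
)
from .simulate import SimulationConfig, simulate_study, write_study

log = logging.getLogger("straintrack")

STAGES = ("simulate", "coverage", "strains", "track", "cluster", "mantel", "clinical")


@dataclass
class PipelineConfig:
    """Analysis parameters and paths for one pipeline run."""

    output_dir: str = "straintrack_out"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    n_positions: int = 100          # SNP sites used per species for deconvolution
    k_strains: int = 4              # fixed number of haplotypes fitted per species
    epsilon: float = 0.01
    n_restarts: int = 2
    detect_threshold: float = 1e-3
    n_perm: int = 9999
    transfer_timepoint: str = "F1"
    transfer_margin: float = 2.0    # detectability guard band for opportunities
    exclude_samples: tuple[str, ...] = ()
    mantel_phylum_subsets: bool = False
    stages: tuple[str, ...] = STAGES
    resume: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("simulation", {})
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown pipeline config keys: {sorted(bad)}")
        cfg = cls(**raw)
        if sim_raw:
            sim_known = {f.name for f in dataclasses.fields(SimulationConfig)}
            bad = set(sim_raw) - sim_known
            if bad:
                raise ValueError(f"unknown simulation config keys: {sorted(bad)}")
            if "engraftment_prob" in sim_raw:
                sim_raw["engraftment_prob"] = {
                    tuple(k.split("|")): v for k, v in sim_raw["engraftment_prob"].items()
                }
            cfg.simulation = SimulationConfig(**sim_raw)
        return cfg


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run(config: PipelineConfig) -> dict:
    """Run the configured stages; returns the manifest dictionary."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "n_positions": config.n_positions,
            "k_strains": config.k_strains,
            "epsilon": config.epsilon,
            "n_restarts": config.n_restarts,
            "detect_threshold": config.detect_threshold,
            "n_perm": config.n_perm,
            "transfer_timepoint": config.transfer_timepoint,
        },
        "stages": {},
    }
    log.info("straintrack %s | seed=%d | out=%s", __version__, config.seed, out)
    for stage in config.stages:
        if stage not in STAGES:
            raise StageError(stage, "unknown stage")
        fn = globals()[f"_stage_{stage}"]
        t0 = time.time()
        try:
            info = fn(config, out)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - reported with stage context
            raise StageError(stage, str(exc)) from exc
        info["seconds"] = round(time.time() - t0, 3)
        manifest["stages"][stage] = info
        log.info("stage %-9s done in %.1fs", stage, info["seconds"])
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _outputs_exist(out: Path, names: list[str]) -> bool:
    return all((out / n).exists() for n in names)


def _stage_simulate(config: PipelineConfig, out: Path) -> dict:
    names = ["metagenotype.tsv", "metadata.tsv", "taxonomy.tsv", "clinical.tsv"]
    if config.resume and _outputs_exist(out, names):
        return {"skipped": True}
    sim = dataclasses.replace(
        config.simulation, rng_seed=child_seed(config.seed, 0)
    )
    study = simulate_study(sim)
    write_study(study, out)
    return {
        "n_species": sim.n_species,
        "n_samples": int(len(study.metadata)),
        "n_strains_true": int(len(study.pool.strain_ids)),
    }


def _stage_coverage(config: PipelineConfig, out: Path) -> dict:
    names = ["species_coverage.tsv", "species_relabund.tsv"]
    if config.resume and _outputs_exist(out, names):
        return {"skipped": True}
    mgt = read_metagenotype(out / "metagenotype.tsv")
    cov = coverage_table(mgt)
    rel = relative_abundance(cov)
    write_species_profile(cov, out / "species_coverage.tsv")
    write_species_profile(rel, out / "species_relabund.tsv")
    return {"n_species": int(cov.shape[0]), "n_samples": int(cov.shape[1])}


def _stage_strains(config: PipelineConfig, out: Path) -> dict:
    names = ["strain_abundance.tsv"]
    if config.resume and _outputs_exist(out, names):
        return {"skipped": True}
    mgt = read_metagenotype(out / "metagenotype.tsv")
    taxonomy = pd.read_csv(out / "taxonomy.tsv", sep="\t").set_index("species_id")["lineage"]
    cov = pd.read_csv(out / "species_coverage.tsv", sep="\t", index_col=0)
    models = {}
    skipped = []
    for i, sp in enumerate(sorted(mgt)):
        m = mgt[sp]
        if m.site_coverage().sum() == 0:
            skipped.append(sp)
            log.warning("species %s has no coverage in any sample; skipped", sp)
            continue
        sub = subsample_positions(m, n=config.n_positions, seed=child_seed(config.seed, 1000 + i))
        models[sp] = fit_strains(
            sub,
            K=config.k_strains,
            epsilon=config.epsilon,
            seed=child_seed(config.seed, 2000 + i),
            n_restarts=config.n_restarts,
        )
    table = build_strain_table(models, cov, taxonomy)
    write_strain_table(table, out / "strain_abundance_full.tsv")
    detected = filter_detected(table, config.detect_threshold)
    write_strain_table(detected, out / "strain_abundance.tsv")
    return {
        "n_species_fit": len(models),
        "n_species_skipped": len(skipped),
        "n_strains_detected": int(detected["strain_id"].nunique()),
    }


def _stage_track(config: PipelineConfig, out: Path) -> dict:
    names = ["origin_labels.tsv", "transferability.tsv"]
    if config.resume and _outputs_exist(out, names):
        return {"skipped": True}
    table = read_strain_table(out / "strain_abundance.tsv")
    metadata = read_metadata(out / "metadata.tsv")
    labels = classify_origin(table, metadata, config.detect_threshold)
    _tsv(labels.labels, out / "origin_labels.tsv")
    traj = origin_fraction_trajectories(table, labels, metadata)
    _tsv(traj, out / "origin_trajectories.tsv")
    for ref in ("baseline", "donor"):
        _tsv(similarity_to(table, metadata, ref), out / f"similarity_{ref}.tsv")
    tt = transferability(
        table, labels, metadata,
        timepoint=config.transfer_timepoint, margin=config.transfer_margin,
    )
    _tsv(tt.counts, out / "transferability.tsv")
    # each phylum against the one with the most opportunities
    counts = tt.counts.sort_values("opportunities", ascending=False)
    tests = []
    if len(counts) >= 2:
        ref_ph = counts["phylum"].iloc[0]
        for ph in counts["phylum"].iloc[1:]:
            res = phylum_transfer_test(tt, ph, ref_ph)
            tests.append((ph, ref_ph, res.p_two_sided, res.sample_log_odds))
    _tsv(
        pd.DataFrame(tests, columns=["phylum", "reference_phylum", "p_two_sided", "log_odds"]),
        out / "phylum_transfer_tests.tsv",
    )
    return {
        "n_patients": int(labels.labels["patient"].nunique()),
        "n_phyla": int(len(tt.counts)),
    }


def _profiles_for_clustering(config: PipelineConfig, out: Path) -> dict[str, tuple[pd.DataFrame, str]]:
    table = read_strain_table(out / "strain_abundance.tsv")
    strain_rel = strain_table_pivot(table, "relative_abundance")
    lineages = strain_lineages(table)
    species_rel = aggregate_taxa(strain_rel, lineages, "species")
    profiles = {
        "strain": (strain_rel, "braycurtis"),
        "species": (species_rel, "braycurtis"),
    }
    ba_path = out / "bile_acids.tsv"
    if ba_path.exists():
        profiles["bile_acid"] = (pd.read_csv(ba_path, sep="\t", index_col=0), "cosine")
    genes_path = out / "gene_families.tsv"
    if genes_path.exists():
        profiles["gene"] = (pd.read_csv(genes_path, sep="\t", index_col=0), "cosine")
    return profiles


def _stage_cluster(config: PipelineConfig, out: Path) -> dict:
    names = ["anosim.tsv"]
    if config.resume and _outputs_exist(out, names):
        return {"skipped": True}
    metadata = read_metadata(out / "metadata.tsv")
    patients = metadata[metadata["role"] == "patient"].set_index("sample_id")
    profiles = _profiles_for_clustering(config, out)
    anosim_rows = []
    for name, (prof, metric) in profiles.items():
        cols = [c for c in prof.columns if c in patients.index]
        prof = prof[cols].loc[:, prof[cols].sum(axis=0) > 0]
        d = pairwise_dissimilarity(prof, metric)
        # clustering by patient, pooled over time points
        groups = patients.loc[d.ids, "subject_id"].to_numpy()
        res = anosim(d, groups, n_perm=config.n_perm, seed=child_seed(config.seed, 3000))
        anosim_rows.append((name, "patient", "all", res.R, res.p, res.n_samples))
        # clustering by donor at each time point
        for tp, tp_samples in patients.groupby("timepoint").groups.items():
            ids = [s for s in d.ids if s in set(tp_samples)]
            if len(ids) < 4:
                continue
            sub = d.submatrix(ids)
            g = patients.loc[ids, "donor_assigned"].to_numpy()
            if len(np.unique(g)) < 2:
                continue
            res = anosim(sub, g, n_perm=config.n_perm, seed=child_seed(config.seed, 3001))
            anosim_rows.append((name, "donor", tp, res.R, res.p, res.n_samples))
        coords, stress = nmds(d, k=2, seed=child_seed(config.seed, 3100))
        coords["stress"] = stress
        _tsv(coords, out / f"nmds_{name}.tsv", index=True)
    _tsv(
        pd.DataFrame(
            anosim_rows, columns=["profile", "grouping", "timepoint", "R", "p", "n_samples"]
        ),
        out / "anosim.tsv",
    )
    return {"n_tests": len(anosim_rows)}


def _stage_mantel(config: PipelineConfig, out: Path) -> dict:
    names = ["mantel.tsv"]
    if config.resume and _outputs_exist(out, names):
        return {"skipped": True}
    metadata = read_metadata(out / "metadata.tsv")
    patients = metadata[metadata["role"] == "patient"].set_index("sample_id")
    sample_patient = patients["subject_id"]
    table = read_strain_table(out / "strain_abundance.tsv")
    strain_rel = strain_table_pivot(table, "relative_abundance")
    lineages = strain_lineages(table)
    taxa = {
        "strain": strain_rel,
        "species": aggregate_taxa(strain_rel, lineages, "species"),
        "family": aggregate_taxa(strain_rel, lineages, "family"),
    }
    aux = {}
    for name, fname in (("bile_acid", "bile_acids.tsv"), ("gene", "gene_families.tsv")):
        path = out / fname
        if path.exists():
            aux[name] = pd.read_csv(path, sep="\t", index_col=0)

    keep = [s for s in patients.index if s not in set(config.exclude_samples)]

    def block(profile: pd.DataFrame, metric: str):
        cols = [c for c in profile.columns if c in keep]
        return build_block_matrix(profile[cols], sample_patient, metric)

    rows = []
    seeds = iter(range(4000, 4999))
    for tname, tprof in taxa.items():
        dt = block(tprof, "braycurtis")
        days = patients.loc[dt.ids, "days_since_fmt"]
        ctrl = time_control_matrix(days, sample_patient)
        for aname, aprof in aux.items():
            da = block(aprof[dt.ids], "cosine")
            res = partial_mantel(
                dt, da, ctrl, n_perm=config.n_perm,
                seed=child_seed(config.seed, next(seeds)),
            )
            rows.append((tname, aname, "sqrt_time", res.r, res.p, res.n_pairs))
    if "bile_acid" in aux and "gene" in aux:
        dg = block(aux["gene"], "cosine")
        da = block(aux["bile_acid"][dg.ids], "cosine")
        days = patients.loc[dg.ids, "days_since_fmt"]
        ctrl = time_control_matrix(days, sample_patient)
        res = partial_mantel(
            dg, da, ctrl, n_perm=config.n_perm, seed=child_seed(config.seed, next(seeds))
        )
        rows.append(("gene", "bile_acid", "sqrt_time", res.r, res.p, res.n_pairs))
    if config.mantel_phylum_subsets and "bile_acid" in aux:
        from .ecology import subset_phylum

        phyla = sorted({lineage_taxon(l, "phylum") for l in lineages})
        for ph in phyla:
            try:
                sub = subset_phylum(strain_rel, lineages, ph).dropna(axis=1)
            except ValueError:
                continue
            if sub.shape[1] < 8:
                continue
            dt = block(sub, "braycurtis")
            if dt.pair_indices()[0].size < 3:
                continue
            da = block(aux["bile_acid"][dt.ids], "cosine")
            days = patients.loc[dt.ids, "days_since_fmt"]
            ctrl = time_control_matrix(days, sample_patient)
            res = partial_mantel(
                dt, da, ctrl, n_perm=config.n_perm,
                seed=child_seed(config.seed, next(seeds)),
            )
            rows.append((f"strain[{ph}]", "bile_acid", "sqrt_time", res.r, res.p, res.n_pairs))
    _tsv(
        pd.DataFrame(rows, columns=["profile_a", "profile_b", "control", "r", "p", "n_pairs"]),
        out / "mantel.tsv",
    )
    return {"n_tests": len(rows)}


def _stage_clinical(config: PipelineConfig, out: Path) -> dict:
    names = ["clinical_stats.tsv"]
    if config.resume and _outputs_exist(out, names):
        return {"skipped": True}
    clinical = read_clinical(out / "clinical.tsv")
    metadata = read_metadata(out / "metadata.tsv")
    arms = (
        metadata[metadata["role"] == "patient"]
        .drop_duplicates("subject_id")
        .set_index("subject_id")["arm_abx"]
    )
    rows = []
    for include in (False, True):
        counts = remission_table(clinical, arms, include_withdrawals=include)
        if set(counts.index) >= {"ABX+", "ABX-"}:
            t = [
                [counts.loc["ABX+", "remitted"], counts.loc["ABX+", "not_remitted"]],
                [counts.loc["ABX-", "remitted"], counts.loc["ABX-", "not_remitted"]],
            ]
            res = fisher_exact(t)
            rows.append(
                (
                    "remission_ABX", "incl_withdrawals" if include else "excl_withdrawals",
                    int(t[0][0]), int(t[0][1]), int(t[1][0]), int(t[1][1]),
                    res.p_two_sided, res.sample_log_odds,
                    res.wald_ci_95[0], res.wald_ci_95[1],
                )
            )
    # paired Mayo change and responder count
    d0 = {}
    f1 = {}
    for _, row in clinical.iterrows():
        score = mayo_from_row(row)
        (d0 if row["visit"] == "D0" else f1)[row["subject_id"]] = score
    paired = [(d0[s], f1[s]) for s in d0 if s in f1]
    n_resp = sum(responder(a, b) for a, b in paired)
    n_remit = sum(remission(a, b) for a, b in paired)
    summary = {
        "n_patients": len(d0),
        "n_with_followup": len(paired),
        "n_remission": int(n_remit),
        "n_responders": int(n_resp),
    }
    if paired:
        before = [a.total for a, _ in paired]
        after = [b.total for _, b in paired]
        if any(x != y for x, y in zip(before, after)):
            w = wilcoxon_signed_rank(before, after)
            summary["wilcoxon_mayo_p"] = w.p_two_sided
    _tsv(
        pd.DataFrame(
            rows,
            columns=[
                "test", "variant", "a", "b", "c", "d",
                "p_two_sided", "log_odds", "ci_lo", "ci_hi",
            ],
        ),
        out / "clinical_stats.tsv",
    )
    (out / "clinical_summary.json").write_text(json.dumps(summary, indent=2))
    return summary
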