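"""Donor/patient strain tracking: origin labels, trajectories, transferability.

Given the study-wide strain abundance table and the sample sheet, every
strain is classified per patient as baseline-specific (detected in the
patient's pre-FMT sample but not in the assigned donor), donor-specific
(the converse), shared, or neither.  These labels drive the engraftment
trajectories, the Bray-Curtis similarity curves to baseline/donor, and
the per-phylum transferability index: the fraction of donor-specific
strains, pooled over donor-patient pairs, that are detected in the
patient at first follow-up.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import lineage_taxon
from .clinical import FisherResult, fisher_exact, mann_whitney_u
from .deconvolution import strain_lineages, strain_table_pivot
from .ecology import bray_curtis

METADATA_COLUMNS = [
    "sample_id", "subject_id", "role", "donor_assigned",
    "arm_abx", "arm_maint", "timepoint", "days_since_fmt",
]

ORIGIN_CLASSES = ("baseline-specific", "donor-specific", "shared", "neither")


def read_metadata(path) -> pd.DataFrame:
    md = pd.read_csv(path, sep="\t", dtype={c: str for c in METADATA_COLUMNS[:-1]})
    missing = [c for c in METADATA_COLUMNS if c not in md.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    patients = md[md["role"] == "patient"]
    multi = patients.groupby("subject_id")["donor_assigned"].nunique()
    if (multi > 1).any():
        raise ValueError("each patient must have exactly one assigned donor")
    return md


def write_metadata(md: pd.DataFrame, path) -> None:
    md.to_csv(path, sep="\t", index=False)


def aggregate_donor_profile(
    table: pd.DataFrame, metadata: pd.DataFrame, donor: str
) -> pd.Series:
    """Donor strain profile: coverage summed over the donor's samples, normalised.

    Summing coverage (rather than averaging relative abundances) weights
    the donor's deeper samples more, matching how the pooled profile is
    used for strain detection.
    """
    donor_samples = metadata.loc[
        (metadata["subject_id"] == donor) & (metadata["role"] == "donor"), "sample_id"
    ]
    sub = table[table["sample_id"].isin(donor_samples)]
    if sub.empty:
        raise ValueError(f"donor {donor!r} has no samples in the table")
    summed = sub.groupby("strain_id")["coverage"].sum()
    total = summed.sum()
    if total == 0:
        raise ValueError(f"donor {donor!r} has zero total coverage")
    return summed / total


@dataclass
class OriginLabels:
    """Per (patient, strain) origin classification."""

    labels: pd.DataFrame        # patient, strain_id, label
    detect_threshold: float

    def for_patient(self, patient: str) -> pd.Series:
        sub = self.labels[self.labels["patient"] == patient]
        return sub.set_index("strain_id")["label"]


def classify_origin(
    table: pd.DataFrame,
    metadata: pd.DataFrame,
    detect_threshold: float = 1e-3,
) -> OriginLabels:
    """Label every strain per patient by where it was detected pre-FMT.

    Detection is strictly greater than ``detect_threshold`` on relative
    abundance, in the patient's baseline (B) sample and in the pooled
    donor profile.  The default threshold matches ``filter_detected``'s
    (above the strain-inference noise floor) so origin labels, detected
    strains and transfer successes share one notion of presence.
    Patients without a baseline sample are excluded with a warning.
    """
    rel = strain_table_pivot(table, "relative_abundance")
    strains = rel.index
    patients = metadata[(metadata["role"] == "patient")]
    donor_profiles: dict[str, pd.Series] = {}
    rows = []
    for patient, grp in patients.groupby("subject_id"):
        b = grp.loc[grp["timepoint"] == "B", "sample_id"]
        if b.empty or b.iloc[0] not in rel.columns:
            warnings.warn(f"patient {patient} lacks a baseline sample; excluded")
            continue
        donor = grp["donor_assigned"].iloc[0]
        if donor not in donor_profiles:
            donor_profiles[donor] = aggregate_donor_profile(table, metadata, donor)
        dprof = donor_profiles[donor].reindex(strains).fillna(0.0)
        in_b = rel[b.iloc[0]] > detect_threshold
        in_d = dprof > detect_threshold
        label = np.select(
            [in_b & in_d, in_b & ~in_d, ~in_b & in_d],
            ["shared", "baseline-specific", "donor-specific"],
            default="neither",
        )
        for sid, lab in zip(strains, label):
            rows.append((patient, sid, lab))
    return OriginLabels(
        labels=pd.DataFrame(rows, columns=["patient", "strain_id", "label"]),
        detect_threshold=detect_threshold,
    )


def origin_fraction_trajectories(
    table: pd.DataFrame, labels: OriginLabels, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Fraction of each sample's strain community by origin class.

    Returns a tidy frame (patient, timepoint, days_since_fmt, one
    column per origin class); the four fractions sum to one for every
    sample with nonzero strain coverage.
    """
    rel = strain_table_pivot(table, "relative_abundance")
    rows = []
    patients = metadata[metadata["role"] == "patient"]
    for patient, grp in patients.groupby("subject_id"):
        lab = labels.for_patient(patient)
        if lab.empty:
            continue
        for _, srow in grp.iterrows():
            smp = srow["sample_id"]
            if smp not in rel.columns:
                continue
            v = rel[smp]
            total = v.sum()
            if total == 0:
                continue
            fracs = {
                cls: float(v[lab.reindex(v.index) == cls].sum() / total)
                for cls in ORIGIN_CLASSES
            }
            rows.append(
                {"patient": patient, "timepoint": srow["timepoint"],
                 "days_since_fmt": srow["days_since_fmt"], **fracs}
            )
    return pd.DataFrame(rows)


def similarity_to(
    table: pd.DataFrame, metadata: pd.DataFrame, reference: str = "donor"
) -> pd.DataFrame:
    """Bray-Curtis similarity (1 - dissimilarity) of each patient sample
    to the patient's own baseline or to their assigned donor profile."""
    if reference not in ("baseline", "donor"):
        raise ValueError("reference must be 'baseline' or 'donor'")
    rel = strain_table_pivot(table, "relative_abundance")
    rows = []
    patients = metadata[metadata["role"] == "patient"]
    for patient, grp in patients.groupby("subject_id"):
        if reference == "baseline":
            b = grp.loc[grp["timepoint"] == "B", "sample_id"]
            if b.empty or b.iloc[0] not in rel.columns:
                continue
            ref = rel[b.iloc[0]]
        else:
            donor = grp["donor_assigned"].iloc[0]
            ref = aggregate_donor_profile(table, metadata, donor).reindex(rel.index).fillna(0.0)
        for _, srow in grp.iterrows():
            smp = srow["sample_id"]
            if smp not in rel.columns:
                continue
            v = rel[smp]
            if v.sum() == 0 and ref.sum() == 0:
                continue
            sim = 1.0 - bray_curtis(v.to_numpy(), ref.to_numpy())
            rows.append(
                (patient, srow["timepoint"], srow["days_since_fmt"], sim)
            )
    return pd.DataFrame(
        rows, columns=["patient", "timepoint", "days_since_fmt", "similarity"]
    )


@dataclass
class TransferTable:
    """Per-phylum donor-strain transfer counts and rates."""

    counts: pd.DataFrame        # phylum, opportunities, successes, rate
    timepoint: str
    detect_threshold: float

    def rate(self, phylum: str) -> float:
        row = self.counts.set_index("phylum").loc[phylum]
        return float(row["rate"])


def transferability(
    table: pd.DataFrame,
    labels: OriginLabels,
    metadata: pd.DataFrame,
    timepoint: str = "F1",
    detect_threshold: float | None = None,
    margin: float = 1.0,
) -> TransferTable:
    """Per-phylum transferability index at a follow-up time point.

    Opportunities are (patient, donor-specific strain) pairs pooled
    over all donor/patient pairs; successes are those strains detected
    in the patient's sample at ``timepoint``.  Patients without that
    sample are excluded; a phylum with zero opportunities gets rate NaN.

    ``margin`` > 1 applies a detectability guard band to the
    opportunity definition: a pair is counted only when the strain is
    clearly present in the donor profile (relative abundance >
    margin x threshold, so a transfer would be observable at the
    follow-up sample) and clearly absent from the baseline (<
    threshold / margin, so a retained near-threshold baseline strain
    cannot masquerade as a transfer).  This de-biases the rate against
    detection flips at the threshold; ``margin=1`` is the plain count
    over the classifier's donor-specific labels.
    """
    thr = labels.detect_threshold if detect_threshold is None else detect_threshold
    if margin < 1:
        raise ValueError("margin must be >= 1")
    rel = strain_table_pivot(table, "relative_abundance")
    phylum_of = strain_lineages(table).map(lambda lin: lineage_taxon(lin, "phylum"))
    patients = metadata[metadata["role"] == "patient"]
    donor_profiles: dict[str, pd.Series] = {}
    opp: dict[str, int] = {}
    succ: dict[str, int] = {}
    for patient, grp in patients.groupby("subject_id"):
        smp = grp.loc[grp["timepoint"] == timepoint, "sample_id"]
        if smp.empty or smp.iloc[0] not in rel.columns:
            continue
        if margin == 1.0:
            lab = labels.for_patient(patient)
            donor_specific = lab[lab == "donor-specific"].index
        else:
            b = grp.loc[grp["timepoint"] == "B", "sample_id"]
            if b.empty or b.iloc[0] not in rel.columns:
                continue
            donor = grp["donor_assigned"].iloc[0]
            if donor not in donor_profiles:
                donor_profiles[donor] = aggregate_donor_profile(table, metadata, donor)
            dprof = donor_profiles[donor].reindex(rel.index).fillna(0.0)
            guard = (dprof > margin * thr) & (rel[b.iloc[0]] < thr / margin)
            donor_specific = rel.index[guard]
        detected = rel[smp.iloc[0]] > thr
        for sid in donor_specific:
            ph = phylum_of.get(sid)
            if ph is None:
                continue
            opp[ph] = opp.get(ph, 0) + 1
            if bool(detected.get(sid, False)):
                succ[ph] = succ.get(ph, 0) + 1
    rows = []
    for ph in sorted(opp):
        o, s = opp[ph], succ.get(ph, 0)
        rows.append((ph, o, s, s / o if o > 0 else np.nan))
    return TransferTable(
        counts=pd.DataFrame(rows, columns=["phylum", "opportunities", "successes", "rate"]),
        timepoint=timepoint,
        detect_threshold=thr,
    )


def phylum_transfer_test(
    t: TransferTable, phylum_a: str, phylum_b: str
) -> FisherResult:
    """Two-sided Fisher exact test comparing two phyla's transfer rates."""
    c = t.counts.set_index("phylum")
    for ph in (phylum_a, phylum_b):
        if ph not in c.index or c.loc[ph, "opportunities"] == 0:
            raise ValueError(f"phylum {ph!r} has no transfer opportunities")
    sa, oa = int(c.loc[phylum_a, "successes"]), int(c.loc[phylum_a, "opportunities"])
    sb, ob = int(c.loc[phylum_b, "successes"]), int(c.loc[phylum_b, "opportunities"])
    return fisher_exact([[sa, oa - sa], [sb, ob - sb]])


def detection_fraction_by_arm(
    table: pd.DataFrame,
    labels: OriginLabels,
    metadata: pd.DataFrame,
    timepoint: str = "F1",
    phylum: str | None = None,
):
    """Per-patient fraction of donor-specific strains detected at a time
    point, compared between pretreatment arms by Mann-Whitney U."""
    thr = labels.detect_threshold
    rel = strain_table_pivot(table, "relative_abundance")
    phylum_of = strain_lineages(table).map(lambda lin: lineage_taxon(lin, "phylum"))
    patients = metadata[metadata["role"] == "patient"]
    per_patient = []
    for patient, grp in patients.groupby("subject_id"):
        smp = grp.loc[grp["timepoint"] == timepoint, "sample_id"]
        if smp.empty or smp.iloc[0] not in rel.columns:
            continue
        lab = labels.for_patient(patient)
        ds = lab[lab == "donor-specific"].index
        if phylum is not None:
            ds = [s for s in ds if phylum_of.get(s) == phylum]
        if len(ds) == 0:
            continue
        detected = rel[smp.iloc[0]].reindex(ds).fillna(0.0) > thr
        per_patient.append(
            (patient, grp["arm_abx"].iloc[0], float(np.mean(detected)))
        )
    df = pd.DataFrame(per_patient, columns=["patient", "arm_abx", "fraction"])
    x = df.loc[df["arm_abx"] == "ABX+", "fraction"]
    y = df.loc[df["arm_abx"] == "ABX-", "fraction"]
    test = mann_whitney_u(x, y) if len(x) and len(y) else None
    return df, test
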