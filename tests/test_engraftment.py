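import numpy as np
import pandas as pd
import pytest

from straintrack.engraftment import (
    aggregate_donor_profile,
    classify_origin,
    detection_fraction_by_arm,
    origin_fraction_trajectories,
    phylum_transfer_test,
    similarity_to,
    transferability,
)

LIN = "d__Bacteria;p__{p};c__C;o__O;f__F;g__G;s__S"


def tidy_table(abund: dict, phylum: dict | None = None) -> pd.DataFrame:
    """Build a tidy strain table from {sample: {strain: rel_abund}}."""
    rows = []
    for smp, strains in abund.items():
        for sid, v in strains.items():
            ph = (phylum or {}).get(sid, "P1")
            rows.append((sid, f"sp_{sid}", LIN.format(p=ph), smp, v * 100.0, v))
    return pd.DataFrame(
        rows,
        columns=["strain_id", "species_id", "lineage", "sample_id",
                 "coverage", "relative_abundance"],
    )


def meta(rows):
    return pd.DataFrame(
        rows,
        columns=["sample_id", "subject_id", "role", "donor_assigned",
                 "arm_abx", "arm_maint", "timepoint", "days_since_fmt"],
    )


BASIC_META = meta([
    ("d1", "D01", "donor", "", "", "", "DNR", np.nan),
    ("d2", "D01", "donor", "", "", "", "DNR", np.nan),
    ("p1B", "P01", "patient", "D01", "ABX+", "CAPS", "B", -7.0),
    ("p1F1", "P01", "patient", "D01", "ABX+", "CAPS", "F1", 56.0),
])


class TestDonorProfile:
    def test_single_sample_profile_is_normalised_sample(self):
        table = tidy_table({"d1": {"a": 0.3, "b": 0.7}})
        prof = aggregate_donor_profile(table, BASIC_META, "D01")
        assert prof["a"] == pytest.approx(0.3)
        assert prof["b"] == pytest.approx(0.7)

    def test_two_identical_samples_change_nothing(self):
        table = tidy_table({"d1": {"a": 0.3, "b": 0.7}, "d2": {"a": 0.3, "b": 0.7}})
        prof = aggregate_donor_profile(table, BASIC_META, "D01")
        assert prof["a"] == pytest.approx(0.3)

    def test_coverage_sums_then_normalises(self):
        # coverages (1, 0) and (1, 2) -> summed (2, 2) -> (0.5, 0.5)
        table = pd.DataFrame(
            [
                ("a", "spA", LIN.format(p="P1"), "d1", 1.0, 1.0),
                ("b", "spB", LIN.format(p="P1"), "d1", 0.0, 0.0),
                ("a", "spA", LIN.format(p="P1"), "d2", 1.0, 1 / 3),
                ("b", "spB", LIN.format(p="P1"), "d2", 2.0, 2 / 3),
            ],
            columns=["strain_id", "species_id", "lineage", "sample_id",
                     "coverage", "relative_abundance"],
        )
        prof = aggregate_donor_profile(table, BASIC_META, "D01")
        assert prof["a"] == pytest.approx(0.5)
        assert prof["b"] == pytest.approx(0.5)

    def test_missing_donor_rejected(self):
        table = tidy_table({"d1": {"a": 1.0}})
        with pytest.raises(ValueError, match="D99"):
            aggregate_donor_profile(table, BASIC_META, "D99")


class TestClassifyOrigin:
    def test_six_strain_truth_table(self):
        # detection patterns (baseline, donor) for six strains
        table = tidy_table({
            "d1": {"a": 0.0, "b": 0.4, "c": 0.3, "d": 0.0, "e": 0.3, "f": 0.0},
            "p1B": {"a": 0.4, "b": 0.0, "c": 0.3, "d": 0.0, "e": 0.3, "f": 0.3},
            "p1F1": {"a": 0.2, "b": 0.2, "c": 0.2, "d": 0.2, "e": 0.1, "f": 0.1},
        })
        labels = classify_origin(table, BASIC_META, detect_threshold=0.05)
        lab = labels.for_patient("P01")
        assert lab["a"] == "baseline-specific"
        assert lab["b"] == "donor-specific"
        assert lab["c"] == "shared"
        assert lab["d"] == "neither"
        assert lab["e"] == "shared"
        assert lab["f"] == "baseline-specific"

    def test_detection_is_strictly_greater_than_threshold(self):
        table = tidy_table({
            "d1": {"a": 0.05, "b": 0.95},
            "p1B": {"a": 0.0, "b": 1.0},
            "p1F1": {"a": 0.0, "b": 1.0},
        })
        lab = classify_origin(table, BASIC_META, detect_threshold=0.05).for_patient("P01")
        assert lab["a"] == "neither"  # exactly at threshold in donor

    def test_patient_without_baseline_excluded_with_warning(self):
        md = meta([
            ("d1", "D01", "donor", "", "", "", "DNR", np.nan),
            ("p1F1", "P01", "patient", "D01", "ABX+", "CAPS", "F1", 56.0),
        ])
        table = tidy_table({"d1": {"a": 1.0}, "p1F1": {"a": 1.0}})
        with pytest.warns(UserWarning, match="baseline"):
            labels = classify_origin(table, md)
        assert labels.labels.empty


class TestTrajectoriesAndSimilarity:
    def test_fractions_sum_to_one_and_match_arithmetic(self):
        table = tidy_table({
            "d1": {"x": 0.5, "y": 0.5},
            "p1B": {"a": 0.6, "y": 0.4},
            "p1F1": {"a": 0.5, "x": 0.3, "y": 0.2},
        })
        labels = classify_origin(table, BASIC_META, detect_threshold=0.01)
        traj = origin_fraction_trajectories(table, labels, BASIC_META)
        f1 = traj[traj["timepoint"] == "F1"].iloc[0]
        assert f1["baseline-specific"] == pytest.approx(0.5)
        assert f1["donor-specific"] == pytest.approx(0.3)
        assert f1["shared"] == pytest.approx(0.2)
        total = sum(f1[c] for c in
                    ("baseline-specific", "donor-specific", "shared", "neither"))
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_donor_specific_fraction_zero_at_baseline_on_truth(self, toy_study):
        # truth-derived table: abundances below threshold are exactly zero
        truth = toy_study.truth
        md = toy_study.metadata
        comm = truth.true_community
        rows = []
        phylum = dict(toy_study.pool.strain_phylum)
        for smp in comm.columns:
            col = comm[smp]
            for sid in col.index[col > 0]:
                rows.append((sid, sid.rsplit("_", 1)[0],
                             LIN.format(p=phylum[sid]), smp,
                             col[sid] * 100, col[sid]))
        table = pd.DataFrame(rows, columns=["strain_id", "species_id", "lineage",
                                            "sample_id", "coverage",
                                            "relative_abundance"])
        labels = classify_origin(table, md, detect_threshold=0.0)
        traj = origin_fraction_trajectories(table, labels, md)
        at_b = traj[traj["timepoint"] == "B"]
        assert (at_b["donor-specific"] == 0.0).all()
        sums = traj[list(("baseline-specific", "donor-specific", "shared", "neither"))].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_similarity_examples(self):
        table = tidy_table({
            "d1": {"a": 0.25, "b": 0.25, "c": 0.5},
            "p1B": {"a": 0.5, "b": 0.5},
            "p1F1": {"a": 0.5, "b": 0.5},
        })
        sim_b = similarity_to(table, BASIC_META, "baseline")
        # F1 sample identical to baseline -> similarity 1
        assert sim_b.set_index("timepoint").loc["F1", "similarity"] == pytest.approx(1.0)
        sim_d = similarity_to(table, BASIC_META, "donor")
        # (0.5, 0.5, 0) vs (0.25, 0.25, 0.5) -> BC 0.5 -> similarity 0.5
        assert sim_d.set_index("timepoint").loc["F1", "similarity"] == pytest.approx(0.5)

    def test_disjoint_support_has_zero_similarity(self):
        table = tidy_table({
            "d1": {"a": 1.0},
            "p1B": {"b": 1.0},
            "p1F1": {"b": 1.0},
        })
        sim = similarity_to(table, BASIC_META, "donor")
        assert (sim["similarity"] == 0.0).all()


TWO_PATIENT_META = meta([
    ("d1", "D01", "donor", "", "", "", "DNR", np.nan),
    ("p1B", "P01", "patient", "D01", "ABX+", "CAPS", "B", -7.0),
    ("p1F1", "P01", "patient", "D01", "ABX+", "CAPS", "F1", 56.0),
    ("p2B", "P02", "patient", "D01", "ABX-", "ENMA", "B", -7.0),
    ("p2F1", "P02", "patient", "D01", "ABX-", "ENMA", "F1", 56.0),
])


def _transfer_toy():
    """Phylum X: 4+6 opportunities, 2+1 successes -> rate 0.3."""
    donor = {f"x{i}": 0.05 for i in range(10)}
    donor["shared"] = 0.5
    table = {
        "d1": donor,
        # patient 1 baseline lacks x0..x3 (4 opportunities)
        "p1B": {"shared": 0.4, **{f"x{i}": 0.1 for i in range(4, 10)}},
        # successes: x0, x1 detected at F1
        "p1F1": {"shared": 0.4, "x0": 0.3, "x1": 0.3},
        # patient 2 baseline lacks x0..x5 (6 opportunities)
        "p2B": {"shared": 0.4, **{f"x{i}": 0.1 for i in range(6, 10)}},
        # success: x5
        "p2F1": {"shared": 0.7, "x5": 0.3},
    }
    return tidy_table(table, phylum={k: "X" for k in list(donor)})


class TestTransferability:
    def test_counting_oracle(self):
        table = _transfer_toy()
        labels = classify_origin(table, TWO_PATIENT_META, detect_threshold=0.01)
        tt = transferability(table, labels, TWO_PATIENT_META)
        row = tt.counts.set_index("phylum").loc["X"]
        assert row["opportunities"] == 10
        assert row["successes"] == 3
        assert row["rate"] == pytest.approx(0.3)

    def test_successes_monotone_in_threshold(self):
        table = _transfer_toy()
        labels = classify_origin(table, TWO_PATIENT_META, detect_threshold=0.01)
        prev = None
        for thr in (0.01, 0.1, 0.25, 0.35):
            tt = transferability(table, labels, TWO_PATIENT_META,
                                 detect_threshold=thr)
            s = tt.counts["successes"].sum()
            if prev is not None:
                assert s <= prev
            prev = s

    def test_zero_engraftment_study_has_zero_rates(self, toy_study):
        from straintrack.simulate import SimulationConfig, simulate_study

        eng = {(arm, ph): 0.0 for arm in ("ABX+", "ABX-")
               for ph in SimulationConfig().phylum_weights}
        cfg = SimulationConfig(
            n_donors=2, n_patients=6, n_species=8, donor_sample_counts=(2, 2),
            engraftment_prob=eng, jitter_sigma=0.0, rng_seed=1,
        )
        study = simulate_study(cfg)
        comm = study.truth.true_community
        phylum = dict(study.pool.strain_phylum)
        rows = [
            (sid, sid.rsplit("_", 1)[0], LIN.format(p=phylum[sid]), smp,
             comm.loc[sid, smp] * 100, comm.loc[sid, smp])
            for smp in comm.columns for sid in comm.index[comm[smp] > 0]
        ]
        table = pd.DataFrame(rows, columns=["strain_id", "species_id", "lineage",
                                            "sample_id", "coverage",
                                            "relative_abundance"])
        labels = classify_origin(table, study.metadata, detect_threshold=0.0)
        tt = transferability(table, labels, study.metadata)
        assert (tt.counts["successes"] == 0).all()

    def test_classify_origin_recovers_truth_for_abundant_strains(self, toy_study):
        # on the true community, labels must agree with the generator's
        # origin truth wherever abundances clear 10x the threshold
        comm = toy_study.truth.true_community
        md = toy_study.metadata
        phylum = dict(toy_study.pool.strain_phylum)
        thr = 1e-4
        rows = [
            (sid, sid.rsplit("_", 1)[0], LIN.format(p=phylum[sid]), smp,
             comm.loc[sid, smp] * 100, comm.loc[sid, smp])
            for smp in comm.columns for sid in comm.index[comm[smp] > 0]
        ]
        table = pd.DataFrame(rows, columns=["strain_id", "species_id", "lineage",
                                            "sample_id", "coverage",
                                            "relative_abundance"])
        labels = classify_origin(table, md, detect_threshold=thr)
        rename = {"baseline": "baseline-specific", "donor": "donor-specific",
                  "both": "shared", "neither": "neither"}
        truth = toy_study.truth.origin_truth
        merged = labels.labels.merge(truth, on=["patient", "strain_id"],
                                     suffixes=("_est", "_true"))
        donors = md[md["role"] == "donor"]
        for p, grp in merged.groupby("patient"):
            b = md[(md["subject_id"] == p) & (md["timepoint"] == "B")]["sample_id"].iloc[0]
            donor = md[md["subject_id"] == p]["donor_assigned"].dropna().iloc[0]
            d_samples = donors[donors["subject_id"] == donor]["sample_id"]
            dprof = comm[d_samples].mean(axis=1)
            for _, r in grp.iterrows():
                sid = r["strain_id"]
                b_ab = comm.loc[sid, b]
                d_ab = dprof[sid]
                # only judge strains cleanly above/below detection
                if (b_ab == 0 or b_ab > 10 * thr) and (d_ab == 0 or d_ab > 10 * thr):
                    assert r["label_est"] == rename[r["label_true"]], (p, sid)


class TestPhylumTest:
    def _tt(self, counts):
        """counts: {phylum: (successes, opportunities)}."""
        from straintrack.engraftment import TransferTable

        df = pd.DataFrame(
            [(ph, o, s, s / o if o else np.nan) for ph, (s, o) in counts.items()],
            columns=["phylum", "opportunities", "successes", "rate"],
        )
        return TransferTable(counts=df, timepoint="F1", detect_threshold=1e-4)

    def test_identical_counts_give_p_one(self):
        tt = self._tt({"A": (3, 10), "B": (3, 10)})
        assert phylum_transfer_test(tt, "A", "B").p_two_sided == pytest.approx(1.0)

    def test_trial_scale_counts_are_significant(self):
        tt = self._tt({"Bacteroidota": (362, 1062), "Firmicutes_A": (1138, 4305)})
        assert phylum_transfer_test(tt, "Bacteroidota", "Firmicutes_A").p_two_sided < 0.001

    def test_zero_opportunity_phylum_rejected(self):
        tt = self._tt({"A": (1, 4), "B": (0, 0)})
        with pytest.raises(ValueError, match="B"):
            phylum_transfer_test(tt, "A", "B")


def test_detection_fraction_by_arm_runs(toy_study):
    comm = toy_study.truth.true_community
    md = toy_study.metadata
    phylum = dict(toy_study.pool.strain_phylum)
    rows = [
        (sid, sid.rsplit("_", 1)[0], LIN.format(p=phylum[sid]), smp,
         comm.loc[sid, smp] * 100, comm.loc[sid, smp])
        for smp in comm.columns for sid in comm.index[comm[smp] > 0]
    ]
    table = pd.DataFrame(rows, columns=["strain_id", "species_id", "lineage",
                                        "sample_id", "coverage",
                                        "relative_abundance"])
    labels = classify_origin(table, md)
    df, test = detection_fraction_by_arm(table, labels, md)
    assert set(df["arm_abx"]) <= {"ABX+", "ABX-"}
    assert test is None or 0 < test.p_two_sided <= 1
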