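import itertools

import numpy as np
import pandas as pd
import pytest

from straintrack.ecology import (
    DissimilarityMatrix,
    aggregate_taxa,
    anosim,
    bray_curtis,
    build_block_matrix,
    cosine_dissimilarity,
    mantel,
    nmds,
    pairwise_dissimilarity,
    partial_mantel,
    subset_phylum,
    time_control_matrix,
)


def dm(data, ids=None, defined=None):
    data = np.asarray(data, dtype=float)
    ids = ids or [f"s{i}" for i in range(len(data))]
    return DissimilarityMatrix(ids, data, defined)


class TestDissimilarities:
    def test_bray_curtis_examples(self):
        assert bray_curtis([0.2, 0.8], [0.2, 0.8]) == 0.0
        assert bray_curtis([1, 0], [0, 1]) == 1.0
        assert bray_curtis([0.5, 0.5, 0], [0.25, 0.25, 0.5]) == pytest.approx(0.5)

    def test_bray_curtis_errors(self):
        with pytest.raises(ValueError):
            bray_curtis([0, 0], [0, 0])
        with pytest.raises(ValueError):
            bray_curtis([-1, 1], [1, 0])

    def test_cosine_examples(self):
        assert cosine_dissimilarity([1, 2, 3], [2, 4, 6]) == pytest.approx(0.0)
        assert cosine_dissimilarity([1, 0], [0, 1]) == pytest.approx(1.0)
        assert cosine_dissimilarity([1, 0, 1], [1, 1, 0]) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            cosine_dissimilarity([0, 0], [1, 1])

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x, y = rng.random(6), rng.random(6)
            assert bray_curtis(x, y) == pytest.approx(bray_curtis(y, x))
            assert 0 <= bray_curtis(x, y) <= 1
            assert cosine_dissimilarity(x, y) == pytest.approx(cosine_dissimilarity(y, x))


LINEAGES = pd.Series(
    {
        "a": "d__Bacteria;p__P1;c__C;o__O;f__F1;g__G1;s__S1",
        "b": "d__Bacteria;p__P1;c__C;o__O;f__F1;g__G2;s__S2",
        "c": "d__Bacteria;p__P2;c__C;o__O;f__F2;g__G3;s__S3",
    }
)


class TestAggregation:
    def test_family_sums_within_assignment(self):
        ab = pd.DataFrame(
            {"s1": [0.2, 0.2, 0.6], "s2": [0.1, 0.3, 0.6]}, index=["a", "b", "c"]
        )
        fam = aggregate_taxa(ab, LINEAGES, "family")
        assert fam.loc["F1"].tolist() == [pytest.approx(0.4), pytest.approx(0.4)]
        np.testing.assert_allclose(fam.sum(axis=0), 1.0)

    def test_aggregation_is_associative(self):
        ab = pd.DataFrame({"s1": [0.25, 0.25, 0.5]}, index=["a", "b", "c"])
        direct = aggregate_taxa(ab, LINEAGES, "phylum")
        sp = aggregate_taxa(ab, LINEAGES, "species")
        sp_lineages = pd.Series(
            {"S1": LINEAGES["a"], "S2": LINEAGES["b"], "S3": LINEAGES["c"]}
        )
        via_species = aggregate_taxa(sp, sp_lineages, "phylum")
        pd.testing.assert_frame_equal(direct, via_species)

    def test_malformed_lineage_names_feature(self):
        bad = pd.Series({"a": "not-a-lineage"})
        ab = pd.DataFrame({"s1": [1.0]}, index=["a"])
        with pytest.raises(ValueError, match="'a'"):
            aggregate_taxa(ab, bad, "phylum")

    def test_subset_phylum_renormalises(self):
        ab = pd.DataFrame({"s1": [0.2, 0.2, 0.6]}, index=["a", "b", "c"])
        sub = subset_phylum(ab, LINEAGES, "P1")
        assert sub["s1"].tolist() == [pytest.approx(0.5), pytest.approx(0.5)]

    def test_subset_phylum_masks_absent_sample(self):
        ab = pd.DataFrame({"s1": [0.5, 0.5, 0.0], "s2": [0.0, 0.0, 1.0]},
                          index=["a", "b", "c"])
        sub = subset_phylum(ab, LINEAGES, "P1")
        assert sub["s2"].isna().all()
        assert sub["s1"].sum() == pytest.approx(1.0)
        with pytest.raises(ValueError):
            subset_phylum(ab, LINEAGES, "P9")


class TestNMDS:
    def _euclidean_dm(self, n=10, k=2, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.random((n, k))
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        return dm(D)

    def test_embeddable_input_has_low_stress(self):
        _, stress = nmds(self._euclidean_dm(), k=2, seed=0, n_init=8)
        assert stress < 0.01

    def test_stress_non_increasing_in_dimensions(self):
        d = self._euclidean_dm(n=12, k=3, seed=1)
        _, s2 = nmds(d, k=2, seed=0, n_init=8)
        _, s3 = nmds(d, k=3, seed=0, n_init=8)
        assert s3 <= s2 + 1e-6

    def test_deterministic_under_seed(self):
        d = self._euclidean_dm(n=8)
        c1, s1 = nmds(d, seed=3)
        c2, s2 = nmds(d, seed=3)
        assert s1 == s2
        pd.testing.assert_frame_equal(c1, c2)

    def test_masked_matrix_rejected(self):
        data = np.zeros((3, 3))
        defined = np.ones((3, 3), dtype=bool)
        defined[0, 2] = defined[2, 0] = False
        with pytest.raises(ValueError, match="complete"):
            nmds(dm(data, defined=defined))


def _toy_four_sample():
    # groups {s0, s1} vs {s2, s3}; within-distances small
    data = np.array(
        [
            [0.0, 1.0, 5.0, 6.0],
            [1.0, 0.0, 7.0, 8.0],
            [5.0, 7.0, 0.0, 2.0],
            [6.0, 8.0, 2.0, 0.0],
        ]
    )
    return dm(data), np.array(["g1", "g1", "g2", "g2"])


class TestAnosim:
    def test_perfect_separation_gives_R_one(self):
        d, groups = _toy_four_sample()
        assert anosim(d, groups, n_perm=99, seed=0).R == pytest.approx(1.0)

    def test_toy_matches_hand_ranks_and_enumerated_p(self):
        d, groups = _toy_four_sample()
        # hand computation: ranks of (1,5,6,7,8,2) = (1,3,4,5,6,2);
        # within = {1, 2}, between = {3,4,5,6}; R = (4.5 - 1.5)/(6/2) = 1
        res = anosim(d, groups, n_perm=9999, seed=1)
        assert res.R == pytest.approx(1.0)
        # exact null: 3 distinct 2|2 partitions, only one achieves R = 1
        ranks = np.array([1, 3, 4, 5, 6, 2], dtype=float)
        pairs = list(itertools.combinations(range(4), 2))
        r_null = []
        for grouping in [(0, 1), (0, 2), (0, 3)]:  # partner of sample 0
            w = np.array(
                [(i in (0, grouping[1])) == (j in (0, grouping[1]))
                 for i, j in pairs]
            )
            r_null.append((ranks[~w].mean() - ranks[w].mean()) / 3.0)
        exact_p = np.mean([r >= res.R for r in r_null])
        assert exact_p == pytest.approx(1 / 3)
        assert abs(res.p - exact_p) < 0.02

    def test_matches_scikit_bio(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import anosim as sk_anosim

        rng = np.random.default_rng(4)
        X = rng.random((9, 4))
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        groups = np.array(["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        ours = anosim(dm(D), groups, n_perm=999, seed=0)
        theirs = sk_anosim(
            skbio.DistanceMatrix(D, [f"s{i}" for i in range(9)]),
            grouping=list(groups), permutations=999,
        )
        assert ours.R == pytest.approx(float(theirs["test statistic"]), abs=1e-12)
        assert abs(ours.p - float(theirs["p-value"])) < 0.05

    def test_rank_statistic_invariant_to_monotone_transform(self):
        d, groups = _toy_four_sample()
        d2 = dm(np.sqrt(d.data) * 10)
        assert anosim(d, groups, n_perm=99, seed=0).R == pytest.approx(
            anosim(d2, groups, n_perm=99, seed=0).R
        )

    def test_single_group_rejected(self):
        d, _ = _toy_four_sample()
        with pytest.raises(ValueError):
            anosim(d, ["g"] * 4)

    def test_null_labels_give_calibrated_p(self):
        rng = np.random.default_rng(0)
        rej = 0
        reps = 100
        for r in range(reps):
            X = rng.random((10, 4))
            D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
            groups = np.array(["a"] * 5 + ["b"] * 5)
            if anosim(dm(D), groups, n_perm=199, seed=r).p <= 0.05:
                rej += 1
        assert 0.0 <= rej / reps <= 0.12


class TestBlockMatrix:
    def _profiles(self, n_patients=2, n_per=3, seed=0):
        rng = np.random.default_rng(seed)
        cols = {}
        patient = {}
        for p in range(n_patients):
            for t in range(n_per):
                s = f"p{p}t{t}"
                cols[s] = rng.random(5)
                patient[s] = f"p{p}"
        return pd.DataFrame(cols), pd.Series(patient)

    def test_pair_counting(self):
        prof, pat = self._profiles(2, 3)
        d = build_block_matrix(prof, pat)
        assert d.pair_indices()[0].size == 6  # 3 within-patient pairs each

    def test_single_patient_is_complete(self):
        prof, pat = self._profiles(1, 4)
        d = build_block_matrix(prof, pat)
        assert d.is_complete()

    def test_all_singletons_error_downstream(self):
        prof, pat = self._profiles(3, 1)
        with pytest.warns(UserWarning):
            d = build_block_matrix(prof, pat)
        with pytest.raises(ValueError, match="3 defined pairs"):
            mantel(d, d, n_perm=9)


class TestMantel:
    def test_identical_matrices_correlate_perfectly(self):
        prof = pd.DataFrame(np.random.default_rng(0).random((5, 6)))
        d = pairwise_dissimilarity(prof)
        res = mantel(d, d, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_toy_matches_hand_pearson_and_enumeration(self):
        a = np.array(
            [[0, 1, 2, 3], [1, 0, 4, 5], [2, 4, 0, 6], [3, 5, 6, 0]], dtype=float
        )
        b = np.array(
            [[0, 2, 1, 5], [2, 0, 3, 4], [1, 3, 0, 7], [5, 4, 7, 0]], dtype=float
        )
        da, db = dm(a), dm(b)
        va = a[np.triu_indices(4, 1)]
        vb = b[np.triu_indices(4, 1)]
        r_hand = np.corrcoef(va, vb)[0, 1]
        res = mantel(da, db, n_perm=9999, seed=0)
        assert res.r == pytest.approx(r_hand, abs=1e-12)
        # exhaustive permutation null over all 4! relabelings of db
        hits = 0
        perms = list(itertools.permutations(range(4)))
        for perm in perms:
            bp = b[np.ix_(perm, perm)]
            rp = np.corrcoef(va, bp[np.triu_indices(4, 1)])[0, 1]
            if abs(rp) >= abs(r_hand) - 1e-12:
                hits += 1
        exact_p = hits / len(perms)
        assert abs(res.p - exact_p) < 0.03

    def test_invariant_to_constant_shift_off_diagonal(self):
        rng = np.random.default_rng(2)
        prof = pd.DataFrame(rng.random((5, 6)))
        da = pairwise_dissimilarity(prof)
        shifted = da.data + 0.7
        np.fill_diagonal(shifted, 0.0)
        db = dm(shifted, ids=da.ids)
        assert mantel(da, db, n_perm=99, seed=0).r == pytest.approx(1.0)

    def test_mask_mismatch_rejected(self):
        prof, pat = TestBlockMatrix()._profiles(2, 3)
        d1 = build_block_matrix(prof, pat)
        d2 = pairwise_dissimilarity(prof)
        with pytest.raises(ValueError, match="mask"):
            mantel(d1, d2)


class TestPartialMantel:
    def _triple(self, seed=0):
        rng = np.random.default_rng(seed)
        mats = []
        for _ in range(3):
            prof = pd.DataFrame(rng.random((5, 7)))
            mats.append(pairwise_dissimilarity(prof))
        return mats

    def test_constant_control_equals_plain_mantel(self):
        da, db, _ = self._triple()
        const = np.full((7, 7), 0.4)
        np.fill_diagonal(const, 0.0)
        dc = dm(const, ids=da.ids)
        plain = mantel(da, db, n_perm=99, seed=1)
        part = partial_mantel(da, db, dc, n_perm=99, seed=1)
        assert part.r == pytest.approx(plain.r, abs=1e-9)

    def test_control_identical_to_b_gives_zero(self):
        da, db, _ = self._triple(seed=3)
        res = partial_mantel(da, db, db, n_perm=99, seed=0)
        assert res.r == 0.0

    def test_matches_hand_residual_correlation(self):
        da, db, dc = self._triple(seed=5)
        iu = np.triu_indices(7, 1)
        va, vb, vc = da.data[iu], db.data[iu], dc.data[iu]

        def resid(v, on):
            slope, intercept = np.polyfit(on, v, 1)
            return v - (slope * on + intercept)

        r_hand = np.corrcoef(resid(va, vc), resid(vb, vc))[0, 1]
        res = partial_mantel(da, db, dc, n_perm=99, seed=0)
        assert res.r == pytest.approx(r_hand, abs=1e-9)


def test_time_control_uses_sqrt_of_interval():
    days = pd.Series({"a": 0.0, "b": 9.0, "c": 25.0})
    pat = pd.Series({"a": "p", "b": "p", "c": "p"})
    d = time_control_matrix(days, pat)
    assert d.data[0, 1] == pytest.approx(3.0)
    assert d.data[0, 2] == pytest.approx(5.0)
    assert d.data[1, 2] == pytest.approx(4.0)
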