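"""DSC / HD-95 / FRS / permutation-test contracts, with brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from gliorad import (
    DataError,
    GeometryError,
    LabelVolume,
    RegionMask,
    UndefinedDistanceError,
    delta_mean_hd,
    dice,
    evaluate_scheme,
    frs_rank,
    hd95,
    mean_hd_row,
    permutation_test,
    quality_table,
)
from gliorad.segmentation_eval import SegQuality, _surface_voxels, mean_hd
from conftest import random_blob


def brute_force_hd95(a: RegionMask, b: RegionMask) -> float:
    """O(n^2) all-pairs surface-distance oracle, independent of the KD-tree path."""
    sa = np.argwhere(_surface_voxels(a.data)) * np.asarray(a.spacing)
    sb = np.argwhere(_surface_voxels(b.data)) * np.asarray(b.spacing)
    d = np.sqrt(((sa[:, None, :] - sb[None, :, :]) ** 2).sum(axis=2))
    d_ab = d.min(axis=1)
    d_ba = d.min(axis=0)
    return max(np.percentile(d_ab, 95), np.percentile(d_ba, 95))


class TestDice:
    def test_identical_disjoint_and_half_overlap(self):
        a = np.zeros((6, 6, 6), dtype=bool)
        a[0:2, 0:2, 0] = True  # 4 voxels
        b = np.zeros_like(a)
        b[0:2, 1:3, 0] = True  # 4 voxels, overlap 2
        ma, mb = RegionMask(a), RegionMask(b)
        assert dice(ma, ma) == 1.0
        assert dice(ma, mb) == pytest.approx(0.5)
        c = np.zeros_like(a)
        c[4:, 4:, 4:] = True
        assert dice(ma, RegionMask(c)) == 0.0

    def test_both_empty_is_perfect_agreement(self):
        e = RegionMask(np.zeros((4, 4, 4), dtype=bool))
        assert dice(e, e) == 1.0

    def test_symmetry_on_random_blobs(self, rng):
        for _ in range(10):
            a, b = random_blob(rng), random_blob(rng)
            assert dice(a, b) == pytest.approx(dice(b, a))

    def test_grid_mismatch_raises(self):
        a = RegionMask(np.zeros((4, 4, 4), dtype=bool), spacing=(1, 1, 1))
        b = RegionMask(np.zeros((4, 4, 4), dtype=bool), spacing=(2, 1, 1))
        with pytest.raises(GeometryError):
            dice(a, b)


class TestHD95:
    def test_identical_masks_give_zero(self, rng):
        a = random_blob(rng)
        assert hd95(a, a) == 0.0

    def test_single_voxel_pair_three_apart(self):
        a = np.zeros((8, 8, 8), dtype=bool)
        b = np.zeros_like(a)
        a[2, 2, 2] = True
        b[5, 2, 2] = True
        assert hd95(RegionMask(a), RegionMask(b)) == pytest.approx(3.0)

    def test_spacing_scales_distances(self):
        a = np.zeros((8, 8, 8), dtype=bool)
        b = np.zeros_like(a)
        a[2, 2, 2] = True
        b[5, 2, 2] = True
        assert hd95(RegionMask(a, (2, 1, 1)), RegionMask(b, (2, 1, 1))) == pytest.approx(6.0)

    def test_one_empty_mask_is_undefined(self, rng):
        a = random_blob(rng)
        e = RegionMask(np.zeros(a.shape, dtype=bool))
        with pytest.raises(UndefinedDistanceError):
            hd95(a, e)
        assert hd95(e, e) == 0.0

    def test_matches_brute_force_oracle_on_random_blobs(self, rng):
        for _ in range(30):
            a, b = random_blob(rng), random_blob(rng)
            assert hd95(a, b) == pytest.approx(brute_force_hd95(a, b), abs=1e-9)

    def test_symmetry_and_bounded_by_exact_hausdorff(self, rng):
        for _ in range(10):
            a, b = random_blob(rng), random_blob(rng)
            assert hd95(a, b) == pytest.approx(hd95(b, a))
            assert hd95(a, b) <= hd95(a, b, percentile=100.0) + 1e-12


class TestEvaluateScheme:
    def test_perfect_prediction(self, small_bundle):
        sb = next(iter(small_bundle))
        q = evaluate_scheme(sb.truth, sb.truth, "s", "self")
        assert (q.dsc_wt, q.dsc_tc, q.dsc_ec) == (1.0, 1.0, 1.0)
        assert (q.hd_wt, q.hd_tc, q.hd_ec) == (0.0, 0.0, 0.0)

    def test_deleting_enhancing_core_degrades_wt_and_triggers_penalty(self, small_bundle):
        sb = next(iter(small_bundle))
        pred = LabelVolume(np.where(sb.truth.data == 4, 0, sb.truth.data), sb.truth.spacing)
        q = evaluate_scheme(sb.truth, pred, "s", "noec")
        assert q.dsc_wt < 1.0
        diag = float(np.linalg.norm(np.asarray(sb.truth.shape) * np.asarray(sb.truth.spacing)))
        assert q.hd_ec == pytest.approx(diag)  # empty-prediction penalty

    def test_relabelled_ec_keeps_wt_perfect(self, small_bundle):
        sb = next(iter(small_bundle))
        pred = LabelVolume(np.where(sb.truth.data == 4, 1, sb.truth.data), sb.truth.spacing)
        q = evaluate_scheme(sb.truth, pred, "s", "relabel")
        assert q.dsc_wt == 1.0 and q.dsc_tc == 1.0
        assert q.dsc_ec < 1.0


class TestMeanHD:
    def test_mean_of_record(self):
        q = SegQuality("s", "x", 1, 1, 1, 2.0, 3.0, 4.0)
        assert mean_hd(q) == pytest.approx(3.0)

    @pytest.mark.parametrize(
        "row_a,row_b,expected",
        [
            ((6.6, 5.7, 2.9), (4.4, 4.4, 2.1), 1.43),
            ((5.8, 6.5, 3.2), (4.4, 4.4, 2.1), 1.53),
            ((5.5, 5.6, 3.4), (4.4, 4.4, 2.1), 1.20),
        ],
    )
    def test_cohort_row_differences(self, row_a, row_b, expected):
        assert delta_mean_hd(row_a, row_b) == pytest.approx(expected, abs=0.005)

    def test_identical_rows_give_zero(self):
        assert delta_mean_hd((3, 4, 5), (3, 4, 5)) == 0.0


def _toy_table(values: dict) -> pd.DataFrame:
    """values: {(subject, scheme): (dsc_wt, dsc_tc, dsc_ec, hd_wt, hd_tc, hd_ec)}"""
    rows = []
    for (sid, scheme), v in values.items():
        rows.append(SegQuality(sid, scheme, *v))
    return quality_table(rows)


class TestFRS:
    def test_strictly_dominant_scheme_attains_minimum(self):
        table = _toy_table(
            {
                (s, "good"): (0.95, 0.95, 0.9, 1.0, 1.0, 1.0)
                for s in ("a", "b", "c")
            }
            | {(s, "bad"): (0.7, 0.6, 0.5, 5.0, 6.0, 7.0) for s in ("a", "b", "c")}
        )
        res = frs_rank(table)
        assert res.frs["good"] == pytest.approx(1 / 2)  # rank 1 of 2 schemes
        assert res.ordinal["good"] == 1 and res.ordinal["bad"] == 2

    def test_identical_schemes_share_frs(self):
        row = (0.9, 0.8, 0.7, 2.0, 3.0, 4.0)
        table = _toy_table({(s, m): row for s in ("a", "b") for m in ("x", "y", "z")})
        res = frs_rank(table)
        assert len(set(round(v, 12) for v in res.frs.values())) == 1

    def test_matches_hand_ranked_oracle(self):
        # 3 schemes x 2 subjects, hand-computed competition ranks
        table = _toy_table(
            {
                ("s1", "A"): (0.9, 0.9, 0.9, 1.0, 1.0, 1.0),
                ("s1", "B"): (0.8, 0.9, 0.8, 2.0, 2.0, 2.0),
                ("s1", "C"): (0.7, 0.7, 0.7, 3.0, 3.0, 3.0),
                ("s2", "A"): (0.8, 0.8, 0.8, 2.0, 2.0, 2.0),
                ("s2", "B"): (0.9, 0.9, 0.9, 1.0, 1.0, 1.0),
                ("s2", "C"): (0.7, 0.7, 0.7, 3.0, 3.0, 3.0),
            }
        )
        # s1: A ranks (1,1.5,1,1,1,1)->1.0833; B (2,1.5,2,2,2,2)->1.9167; C all 3
        # s2: A all 2; B all 1; C all 3
        res = frs_rank(table)
        assert res.frs["A"] == pytest.approx(((1.0833333333 + 2) / 2) / 3, abs=1e-6)
        assert res.frs["B"] == pytest.approx(((1.9166666667 + 1) / 2) / 3, abs=1e-6)
        assert res.frs["C"] == pytest.approx(1.0)

    def test_duplicate_subject_leaves_frs_unchanged(self):
        base = {
            ("s1", "A"): (0.9, 0.9, 0.9, 1.0, 1.0, 1.0),
            ("s1", "B"): (0.8, 0.8, 0.8, 2.0, 2.0, 2.0),
        }
        dup = base | {
            ("s1copy", "A"): base[("s1", "A")],
            ("s1copy", "B"): base[("s1", "B")],
        }
        assert frs_rank(_toy_table(base)).frs == frs_rank(_toy_table(dup)).frs

    def test_missing_cells_rejected(self):
        table = _toy_table(
            {
                ("s1", "A"): (0.9, 0.9, 0.9, 1.0, 1.0, 1.0),
                ("s1", "B"): (0.8, 0.8, 0.8, 2.0, 2.0, 2.0),
                ("s2", "A"): (0.9, 0.9, 0.9, 1.0, 1.0, 1.0),
            }
        )
        with pytest.raises(DataError):
            frs_rank(table)


class TestPermutationTest:
    def test_identical_scores_give_p_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert permutation_test(x, x, n_perm=1000, seed=0) == 1.0

    def test_dominant_scheme_is_highly_significant(self, rng):
        a = rng.uniform(1.0, 2.0, size=30)
        b = a + rng.uniform(0.5, 1.0, size=30)  # b worse on all 30 subjects
        assert permutation_test(a, b, n_perm=100000, seed=1) < 0.001

    def test_fewer_than_two_subjects_rejected(self):
        with pytest.raises(DataError):
            permutation_test(np.array([1.0]), np.array([2.0]))

    def test_type_I_error_calibrated_under_null(self):
        # exchangeable null: both schemes draw from the same distribution
        rng = np.random.default_rng(77)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            a = rng.normal(size=15)
            b = rng.normal(size=15)
            p = permutation_test(a, b, n_perm=400, seed=int(rng.integers(2**31)))
            rejections += p < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07, rejections / n_rep
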