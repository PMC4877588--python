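"""Unit and property tests for the nuclei-table statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation
from scipy import stats

from ttfield import quantify as q

from _oracles import hand_pooled_t, hand_welch_t, loop_center, loop_dispersion


def make_table(points, t_h=0.0, **extra):
    points = np.atleast_2d(np.asarray(points, dtype=float))
    base = {
        "id": np.arange(len(points)),
        "t_h": t_h,
        "x_um": points[:, 0],
        "y_um": points[:, 1],
        "z_um": points[:, 2],
        "condition": "control",
        "cell_type": "cancer",
    }
    base.update(extra)
    return pd.DataFrame(base)


UNIT_CUBE = [
    (0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, 0, 1), (0, 1, 1), (1, 1, 1),
]


class TestCenterAndDispersion:
    def test_single_point_center_identity(self):
        assert q.aggregate_center(make_table([(3, 4, 5)])) == (3, 4, 5)

    def test_cube_corner_symmetry(self):
        assert q.aggregate_center(make_table(UNIT_CUBE)) == (0.5, 0.5, 0.5)

    def test_center_matches_loop_oracle(self, rng):
        pts = rng.normal(size=(200, 3)) * 40
        got = q.aggregate_center(make_table(pts))
        expected = loop_center(pts)
        assert np.allclose(got, expected, rtol=1e-12, atol=1e-12)

    def test_single_point_dispersion_zero(self):
        assert q.dispersion(make_table([(7, -2, 9)])) == 0.0

    def test_two_points_half_distance(self):
        d = q.dispersion(make_table([(0, 0, 0), (6, 0, 8)]))
        assert d == pytest.approx(5.0)  # distance 10 → Δ = d/2

    def test_cube_corners(self):
        assert q.dispersion(make_table(UNIT_CUBE)) == pytest.approx(math.sqrt(0.75))

    def test_dispersion_matches_loop_oracle(self, rng):
        for _ in range(20):
            pts = rng.normal(size=(50, 3)) * 25 + rng.normal(size=3) * 100
            got = q.dispersion(make_table(pts))
            expected = loop_dispersion(pts)
            assert got == pytest.approx(expected, rel=1e-12)

    def test_sample_variant_scales_by_constant(self, rng):
        pts = rng.normal(size=(40, 3))
        d0 = q.dispersion(make_table(pts), ddof=0)
        d1 = q.dispersion(make_table(pts), ddof=1)
        assert d1 == pytest.approx(d0 * math.sqrt(40 / 39), rel=1e-12)

    @given(seed=st.integers(0, 10_000))
    @settings(deadline=None, max_examples=40)
    def test_rigid_motion_invariance(self, seed):
        gen = np.random.default_rng(seed)
        pts = gen.normal(size=(30, 3)) * 20
        rot = Rotation.random(rng=gen).as_matrix()
        shift = gen.normal(size=3) * 500
        moved = pts @ rot.T + shift
        d0 = q.dispersion(make_table(pts))
        d1 = q.dispersion(make_table(moved))
        assert abs(d1 - d0) < 1e-9

    @given(scale=st.floats(0.01, 100.0), seed=st.integers(0, 10_000))
    @settings(deadline=None, max_examples=40)
    def test_scaling_homogeneity(self, scale, seed):
        gen = np.random.default_rng(seed)
        pts = gen.normal(size=(25, 3)) * 15
        center = gen.normal(size=3) * 50
        scaled = center + scale * (pts - center)
        d0 = q.dispersion(make_table(pts))
        d1 = q.dispersion(make_table(scaled))
        assert d1 == pytest.approx(scale * d0, rel=1e-9)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            q.dispersion(make_table(np.empty((0, 3))))


class TestNormalizedDispersion:
    def _timecourse(self, frames):
        return pd.concat(
            [make_table(pts, t_h=t) for t, pts in frames], ignore_index=True
        )

    def test_self_normalization_at_t0(self, rng):
        pts = rng.normal(size=(30, 3)) * 20
        table = self._timecourse([(0.0, pts), (24.0, pts * 1.7)])
        results = q.normalized_dispersion(table)
        assert results[0].normalized == 1.0

    def test_homogeneous_scaling_doubles(self, rng):
        pts = rng.normal(size=(30, 3)) * 20
        center = pts.mean(axis=0)
        table = self._timecourse([(0.0, pts), (24.0, center + 2 * (pts - center))])
        results = q.normalized_dispersion(table)
        assert results[1].normalized == pytest.approx(2.0, rel=1e-12)

    def test_rigid_motion_leaves_normalization_at_one(self, rng):
        pts = rng.normal(size=(30, 3)) * 20
        rot = Rotation.random(rng=rng).as_matrix()
        table = self._timecourse([(0.0, pts), (24.0, pts @ rot.T + [100, -50, 30])])
        results = q.normalized_dispersion(table)
        assert results[1].normalized == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_aggregate_rejected(self):
        table = self._timecourse([(0.0, np.zeros((5, 3))), (24.0, np.ones((5, 3)))])
        with pytest.raises(ValueError, match="degenerate"):
            q.normalized_dispersion(table)

    def test_missing_t0_rejected(self, rng):
        table = make_table(rng.normal(size=(5, 3)), t_h=24.0)
        with pytest.raises(ValueError, match="t0"):
            q.normalized_dispersion(table)


class TestCountsAndFractions:
    @pytest.mark.parametrize(
        "n_t, n_0, expected", [(100, 100, 0.0), (150, 100, 50.0), (242, 100, 142.0)]
    )
    def test_proliferation_rate(self, n_t, n_0, expected):
        assert q.proliferation_rate(n_t, n_0) == expected

    def test_proliferation_negative_when_cells_lost(self):
        assert q.proliferation_rate(80, 100) == -20.0

    def test_proliferation_rejects_zero_baseline(self):
        with pytest.raises(ValueError):
            q.proliferation_rate(10, 0)

    def test_cell_density(self):
        roi = q.ROI(0, 200, 0, 500, 0, 200)  # 0.02 mm³
        assert q.cell_density(0, roi) == 0.0
        assert q.cell_density(40, roi) == pytest.approx(2000.0)

    def test_density_invariant_to_roi_splitting(self, rng):
        # uniform points: splitting the ROI in half and pooling the counts
        # reproduces the whole-ROI density
        pts = rng.random((4000, 3)) * [400, 400, 100]
        table = make_table(pts)
        whole = q.ROI(0, 400, 0, 400, 0, 100)
        left = q.ROI(0, 200, 0, 400, 0, 100)
        right = q.ROI(200, 400, 0, 400, 0, 100)
        n_whole = int(whole.contains(table).sum())
        n_split = int(left.contains(table).sum()) + int(right.contains(table).sum())
        assert n_whole == n_split
        pooled = n_split / (left.volume_mm3 + right.volume_mm3)
        assert q.cell_density(n_whole, whole) == pytest.approx(pooled, rel=1e-12)

    def test_positivity_all_negative(self):
        table = make_table(np.zeros((4, 3)), ki67=[0, 0, 0, 0])
        assert q.positivity_fraction(table, "ki67") == 0.0

    def test_positivity_one_of_four(self):
        table = make_table(np.zeros((4, 3)), ki67=[1, 0, 0, 0])
        assert q.positivity_fraction(table, "ki67") == 25.0

    def test_positivity_recovers_bernoulli_probability(self, rng):
        n, p = 10_000, 0.3
        flags = (rng.random(n) < p).astype(int)
        table = make_table(rng.random((n, 3)), ki67=flags)
        se = 100 * math.sqrt(p * (1 - p) / n)
        assert q.positivity_fraction(table, "ki67") == pytest.approx(
            100 * p, abs=3 * se
        )

    def test_unknown_marker_rejected(self):
        with pytest.raises(KeyError):
            q.positivity_fraction(make_table(np.zeros((2, 3))), "nope")


class TestGroupStatistics:
    def test_summarize_constant_sample(self):
        assert q.summarize([5, 5, 5]) == (5.0, 0.0, 3)

    def test_summarize_hand_value(self):
        mean, sem, n = q.summarize([1, 2, 3])
        assert mean == 2.0
        assert sem == pytest.approx(1 / math.sqrt(3), rel=1e-12)
        assert n == 3

    def test_summarize_single_value_flags_undefined_sem(self):
        mean, sem, n = q.summarize([4.2])
        assert mean == 4.2 and n == 1 and math.isnan(sem)

    def test_summarize_matches_scipy_on_random_vectors(self, rng):
        for _ in range(10):
            x = rng.normal(size=rng.integers(2, 30))
            mean, sem, n = q.summarize(x)
            assert mean == pytest.approx(np.mean(x), rel=1e-12)
            assert sem == pytest.approx(stats.sem(x), rel=1e-12)

    def test_identical_groups_give_t_zero_p_one(self):
        comp = q.compare_groups([1, 2, 3], [1, 2, 3])
        assert comp.t_stat == pytest.approx(0.0, abs=1e-12)
        assert comp.p == pytest.approx(1.0)

    def test_pooled_example_against_hand_calculation(self):
        a, b = [1, 2, 3, 4], [2, 3, 4, 5]
        comp = q.compare_groups(a, b, welch=False)
        t, df, p = hand_pooled_t(a, b)
        assert comp.t_stat == pytest.approx(-1.0954, abs=1e-4)
        assert comp.df == 6
        assert comp.p == pytest.approx(0.3153, abs=1e-4)
        assert comp.t_stat == pytest.approx(t, rel=1e-10)
        assert comp.p == pytest.approx(p, rel=1e-10)

    def test_welch_against_hand_calculation(self, rng):
        # strongly unequal variances
        a = rng.normal(0, 1, size=8)
        b = rng.normal(0.5, 10, size=5)
        comp = q.compare_groups(a, b, welch=True)
        t, df, p = hand_welch_t(a, b)
        assert comp.t_stat == pytest.approx(t, rel=1e-10)
        assert comp.df == pytest.approx(df, rel=1e-10)
        assert comp.p == pytest.approx(p, rel=1e-10)

    def test_welch_equals_pooled_for_balanced_equal_variance(self):
        # equal group sizes and identical sample variances
        a = [0.0, 1.0, 2.0, 3.0]
        b = [10.0, 11.0, 12.0, 13.0]
        pooled = q.compare_groups(a, b, welch=False)
        welch = q.compare_groups(a, b, welch=True)
        assert abs(pooled.t_stat - welch.t_stat) < 1e-10
        assert abs(pooled.p - welch.p) < 1e-10

    def test_insufficient_n_rejected(self):
        with pytest.raises(ValueError):
            q.compare_groups([1.0], [2.0, 3.0])

    def test_holm_correction_monotone_and_bounded(self):
        raw = [0.01, 0.04, 0.03, 0.8]
        adj = q.holm_correction(raw)
        assert all(0 <= p <= 1 for p in adj)
        assert all(a >= r for a, r in zip(adj, raw))


class TestTableValidation:
    def test_load_round_trip(self, tmp_path, rng):
        table = make_table(rng.random((5, 3)), ki67=[0, 1, 0, 1, 0])
        path = tmp_path / "nuclei.csv"
        table.to_csv(path, index=False)
        loaded = q.load_nuclei_csv(path)
        pd.testing.assert_frame_equal(loaded, table)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            q.validate_table(pd.DataFrame({"id": [1]}))

    def test_duplicate_ids_within_timepoint_rejected(self):
        table = make_table([(0, 0, 0), (1, 1, 1)])
        table.loc[1, "id"] = table.loc[0, "id"]
        with pytest.raises(ValueError, match="duplicate"):
            q.validate_table(table)

    def test_non_finite_positions_rejected(self):
        table = make_table([(0, 0, 0), (1, 1, np.nan)])
        with pytest.raises(ValueError, match="finite"):
            q.validate_table(table)
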