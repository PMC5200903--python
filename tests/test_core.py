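import numpy as np
import pytest

from tosmat import (
    CellPixels,
    ao_ratio,
    ao_ratio_bounds,
    classify_localization,
    observed_overlap,
    overlap_result,
    select_top_fraction,
    tos,
    tos_matrix,
)
from tosmat.core import DEFAULT_FRACTIONS, selected_count
from tosmat.errors import (
    DegenerateCellError,
    IncompatibleSelectionError,
    InvalidFractionError,
)

from conftest import brute_force_overlap


class TestSelectTopFraction:
    def test_100_pixels_half(self):
        sel = select_top_fraction(np.arange(100.0), 0.5)
        assert sel.selected_count == 50

    def test_100_pixels_tenth(self):
        sel = select_top_fraction(np.arange(100.0), 0.1)
        assert sel.selected_count == 10

    def test_round_half_away_from_zero(self):
        # 7 pixels at fraction 0.5 -> k = round(3.5) = 4 largest
        vals = np.array([5.0, 1.0, 9.0, 3.0, 7.0, 2.0, 8.0])
        sel = select_top_fraction(vals, 0.5)
        assert sel.selected_count == 4
        assert set(sel.selected_indices) == {0, 2, 4, 6}  # 5, 9, 7, 8

    def test_effective_fraction_close_to_requested(self):
        for n in (7, 10, 33, 100):
            for f in (0.1, 0.25, 0.5, 0.9):
                sel = select_top_fraction(np.arange(float(n)), f)
                assert abs(sel.effective_fraction - f) <= 1.0 / n + 1e-12

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.5])
    def test_invalid_fraction(self, bad):
        with pytest.raises(InvalidFractionError):
            select_top_fraction(np.arange(10.0), bad)

    def test_degenerate_cell(self):
        with pytest.raises(DegenerateCellError):
            select_top_fraction(np.array([1.0]), 0.5)

    def test_tie_break_by_index(self):
        vals = np.array([2.0, 2.0, 2.0, 1.0])
        sel = select_top_fraction(vals, 0.5)
        assert list(sel.selected_indices) == [0, 1]

    def test_degenerate_channel_flagged(self):
        sel = select_top_fraction(np.full(10, 3.0), 0.5)
        assert sel.degenerate_channel
        assert sel.selected_count == 5

    def test_never_selects_all_pixels(self):
        # round(0.95*10) = 10 would select everything; clamped to N-1
        sel = select_top_fraction(np.arange(10.0), 0.95)
        assert sel.selected_count == 9


class TestObservedOverlap:
    def test_identical_selections(self):
        v = np.arange(20.0)
        s = select_top_fraction(v, 0.5)
        assert observed_overlap(s, s) == (1.0, 1.0)

    def test_disjoint_selections(self):
        v = np.arange(20.0)
        s1 = select_top_fraction(v, 0.5)
        s2 = select_top_fraction(v[::-1].copy(), 0.5)
        assert observed_overlap(s1, s2) == (0.0, 0.0)

    def test_worked_example_50_10_overlap5(self):
        # ch1 top-50 = indices 50..99; ch2 top-10 = 45..54 -> overlap 5
        s1 = np.arange(100.0)
        s2 = np.zeros(100)
        s2[45:55] = 1.0
        cell = CellPixels(s1, s2)
        res = overlap_result(cell, 0.5, 0.1)
        assert res.ao1 == pytest.approx(0.1)
        assert res.ao2 == pytest.approx(0.5)
        assert res.expected_ao1 == pytest.approx(0.1)
        assert res.ao_ratio == pytest.approx(1.0)

    def test_mismatched_cells_rejected(self):
        s1 = select_top_fraction(np.arange(10.0), 0.5)
        s2 = select_top_fraction(np.arange(12.0), 0.5)
        with pytest.raises(IncompatibleSelectionError):
            observed_overlap(s1, s2)


class TestAORatio:
    def test_full_overlap_half(self, ramp_cell):
        assert overlap_result(ramp_cell, 0.5, 0.5).ao_ratio == pytest.approx(2.0)

    def test_full_overlap_tenth(self, ramp_cell):
        assert overlap_result(ramp_cell, 0.1, 0.1).ao_ratio == pytest.approx(10.0)

    def test_both_directions_agree(self):
        rng = np.random.default_rng(0)
        cell = CellPixels(rng.uniform(0, 1, 50), rng.uniform(0, 1, 50))
        res = overlap_result(cell, 0.3, 0.7)
        assert res.ao1 / res.expected_ao1 == pytest.approx(res.ao2 / res.expected_ao2)

    def test_invalid_expected_fraction(self):
        with pytest.raises(InvalidFractionError):
            ao_ratio(0.5, 0.0)

    def test_uniform_null_ratio_near_one(self):
        rng = np.random.default_rng(42)
        ratios = []
        for _ in range(200):
            cell = CellPixels(rng.uniform(0, 1, 500), rng.uniform(0, 1, 500))
            ratios.append(overlap_result(cell, 0.5, 0.5).ao_ratio)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.05)


class TestAORatioBounds:
    def test_half_half(self):
        assert ao_ratio_bounds(0.5, 0.5) == (0.0, 2.0)

    def test_nine_nine(self):
        rmin, rmax = ao_ratio_bounds(0.9, 0.9)
        assert rmin == pytest.approx(0.8 / 0.81)
        assert rmax == pytest.approx(1.0 / 0.9)

    def test_tenth_half(self):
        assert ao_ratio_bounds(0.1, 0.5) == (0.0, 2.0)

    def test_brute_force_placement_bounds(self):
        # exhaustive overlap counts for k1=k2=90 of N=100
        n, k1, k2 = 100, 90, 90
        ratios = [
            o * n / (k1 * k2) for o in range(max(0, k1 + k2 - n), min(k1, k2) + 1)
        ]
        rmin, rmax = ao_ratio_bounds(k1 / n, k2 / n)
        assert min(ratios) == pytest.approx(rmin)
        assert max(ratios) == pytest.approx(rmax)

    def test_limits(self):
        for f1 in np.linspace(0.05, 0.95, 10):
            for f2 in np.linspace(0.05, 0.95, 10):
                rmin, rmax = ao_ratio_bounds(f1, f2)
                assert 0.0 <= rmin < 1.0
                assert rmax > 1.0


class TestTOS:
    def test_null_value(self):
        for f1, f2 in [(0.5, 0.5), (0.1, 0.9), (0.3, 0.4)]:
            assert tos(1.0, f1, f2) == 0.0

    @pytest.mark.parametrize("f1", DEFAULT_FRACTIONS)
    @pytest.mark.parametrize("f2", DEFAULT_FRACTIONS)
    def test_anchors_all_81_pairs(self, f1, f2):
        rmin, rmax = ao_ratio_bounds(f1, f2)
        assert tos(rmax, f1, f2) == pytest.approx(1.0)
        assert tos(rmin, f1, f2) == pytest.approx(-1.0)
        assert tos(1.0, f1, f2) == 0.0

    def test_nine_tenths_toward_max(self):
        for f1, f2 in [(0.5, 0.5), (0.2, 0.7)]:
            _, rmax = ao_ratio_bounds(f1, f2)
            assert tos(1 + 0.9 * (rmax - 1), f1, f2) == pytest.approx(0.9)

    def test_monotone_in_ratio(self):
        f1, f2 = 0.4, 0.6
        rmin, rmax = ao_ratio_bounds(f1, f2)
        grid = np.linspace(rmin, rmax, 50)
        vals = [tos(r, f1, f2) for r in grid]
        assert np.all(np.diff(vals) > 0)

    def test_out_of_bounds_clamped(self):
        assert tos(100.0, 0.5, 0.5) == 1.0
        assert tos(-1.0, 0.5, 0.5) == -1.0


class TestTOSMatrix:
    def test_identical_ranks_all_plus_one(self, ramp_cell):
        m = tos_matrix(ramp_cell)
        assert m.values.shape == (9, 9)
        np.testing.assert_allclose(m.values, 1.0, atol=1e-12)

    def test_rank_reversal_minus_one_when_disjoint_possible(self, reversed_cell):
        m = tos_matrix(reversed_cell)
        for i, f2 in enumerate(m.fractions):
            for j, f1 in enumerate(m.fractions):
                if f1 + f2 <= 1.0:
                    assert m.values[i, j] == pytest.approx(-1.0), (f1, f2)

    def test_81_entries_and_grid(self, ramp_cell):
        m = tos_matrix(ramp_cell)
        assert m.values.size == 81
        assert m.fractions == tuple(np.round(np.arange(0.9, 0.05, -0.1), 1))
        assert 1.0 not in m.fractions

    def test_features(self, reversed_cell):
        m = tos_matrix(reversed_cell)
        assert m.tos_h == m.values[-1, -1]
        assert m.tos_max == m.values.max()
        assert m.tos_min == m.values.min()
        assert m.tos_min <= m.tos_h <= m.tos_max

    def test_entries_in_range(self, rng):
        cell = CellPixels(rng.uniform(0, 10, 200), rng.uniform(0, 10, 200))
        m = tos_matrix(cell)
        assert np.all(m.values >= -1.0 - 1e-12)
        assert np.all(m.values <= 1.0 + 1e-12)

    def test_channel_symmetry_transpose(self, rng):
        s1 = rng.permutation(np.arange(60.0))
        s2 = rng.permutation(np.arange(60.0))
        m12 = tos_matrix(CellPixels(s1, s2)).values
        m21 = tos_matrix(CellPixels(s2, s1)).values
        np.testing.assert_allclose(m12, m21.T, atol=1e-12)

    def test_rank_invariance(self, rng):
        s1 = rng.uniform(1, 2, 80)
        s2 = rng.uniform(1, 2, 80)
        base = tos_matrix(CellPixels(s1, s2)).values
        warped = tos_matrix(CellPixels(np.exp(3 * s1), s2**5)).values
        np.testing.assert_allclose(base, warped, atol=1e-12)

    def test_degenerate_channel_flag(self):
        m = tos_matrix(CellPixels(np.full(50, 2.0), np.arange(50.0)))
        assert m.degenerate_channel

    def test_csv_json_round_trip(self, ramp_cell, tmp_path):
        import csv
        import json

        m = tos_matrix(ramp_cell)
        m.to_csv(tmp_path / "m.csv")
        with open(tmp_path / "m.csv") as fh:
            rows = list(csv.reader(fh))
        assert len(rows) == 10
        assert [float(x) for x in rows[0][1:]] == list(m.fractions)
        grid = np.array([[float(x) for x in row[1:]] for row in rows[1:]])
        np.testing.assert_allclose(grid, m.values)

        payload = json.loads(m.to_json(tmp_path / "m.json"))
        assert payload["tos_h"] == m.tos_h
        np.testing.assert_allclose(np.array(payload["values"]), m.values)


class TestBruteForceOracle:
    """AO / AO-ratio equivalence against explicit set intersection, N <= 30."""

    @pytest.mark.parametrize("n", [5, 9, 17, 30])
    def test_oracle_equivalence(self, n, rng):
        s1 = rng.uniform(0, 100, n)
        s2 = rng.uniform(0, 100, n)
        cell = CellPixels(s1, s2)
        for f1 in DEFAULT_FRACTIONS:
            for f2 in DEFAULT_FRACTIONS:
                expected = brute_force_overlap(s1, s2, f1, f2)
                res = overlap_result(cell, f1, f2)
                assert res.ao1 == pytest.approx(expected["ao1"])
                assert res.ao2 == pytest.approx(expected["ao2"])
                assert res.ao_ratio == pytest.approx(expected["ratio"])

    def test_oracle_equivalence_with_ties(self, rng):
        s1 = rng.integers(0, 4, 20).astype(float)
        s2 = rng.integers(0, 4, 20).astype(float)
        cell = CellPixels(s1, s2)
        for f1, f2 in [(0.1, 0.5), (0.5, 0.5), (0.9, 0.3)]:
            expected = brute_force_overlap(s1, s2, f1, f2)
            res = overlap_result(cell, f1, f2)
            assert res.ao1 == pytest.approx(expected["ao1"])
            assert res.ao_ratio == pytest.approx(expected["ratio"])


class TestClassify:
    def test_inside_band(self):
        assert classify_localization(0.05, 0.1) == "non-colocalization"

    def test_strongly_negative(self):
        assert classify_localization(-0.95) == "anti-colocalization"

    def test_boundary_is_closed(self):
        assert classify_localization(0.1, 0.1) == "non-colocalization"
        assert classify_localization(-0.1, 0.1) == "non-colocalization"
        assert classify_localization(0.1000001, 0.1) == "colocalization"

    def test_negative_band_rejected(self):
        with pytest.raises(InvalidFractionError):
            classify_localization(0.5, -0.1)


class TestCellPixels:
    def test_validation(self):
        with pytest.raises(DegenerateCellError):
            CellPixels(np.array([1.0, 2.0]), np.array([1.0]))
        with pytest.raises(DegenerateCellError):
            CellPixels(np.array([1.0, np.nan]), np.array([1.0, 2.0]))
        with pytest.raises(DegenerateCellError):
            CellPixels(np.array([-1.0, 2.0]), np.array([1.0, 2.0]))

    def test_csv_round_trip(self, tmp_path, rng):
        cell = CellPixels(rng.uniform(0, 9, 25), rng.uniform(0, 9, 25))
        cell.to_csv(tmp_path / "cell.csv")
        back = CellPixels.from_csv(tmp_path / "cell.csv")
        np.testing.assert_allclose(back.signal1, cell.signal1)
        np.testing.assert_allclose(back.signal2, cell.signal2)

    def test_selected_count_helper(self):
        assert selected_count(0.5, 7) == 4
        assert selected_count(0.1, 100) == 10
        assert selected_count(0.01, 10) == 1
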