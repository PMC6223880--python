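"""Reference centres, TRE, observer averaging, ranking and summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from conftest import make_mask

from liverloc.evaluate import (
    StudyTable,
    TRERecord,
    average_observers,
    centre_of_gravity,
    rank_methods,
    summarize,
    tre,
)
from liverloc.transforms import RigidTransform


class TestCentreOfGravity:
    def test_single_voxel(self):
        data = np.zeros((6, 6, 6), bool)
        data[2, 3, 4] = True
        np.testing.assert_array_equal(centre_of_gravity(make_mask(data)), [2.0, 3.0, 4.0])

    def test_two_voxels_average(self):
        data = np.zeros((6, 6, 6), bool)
        data[0, 2, 2] = data[2, 2, 2] = True
        np.testing.assert_array_equal(centre_of_gravity(make_mask(data)), [1.0, 2.0, 2.0])

    def test_rasterised_sphere_centroid(self):
        idx = np.indices((61, 61, 61)).transpose(1, 2, 3, 0)
        mask = make_mask(np.linalg.norm(idx - [30, 30, 30], axis=-1) <= 10.0)
        c = centre_of_gravity(mask)
        assert np.all(np.abs(c - 30.0) < 0.5)

    def test_respects_world_geometry(self):
        data = np.zeros((4, 4, 4), bool)
        data[1, 2, 3] = True
        mask = make_mask(data, spacing=(2.0, 3.0, 0.5), origin=(10.0, -5.0, 1.0))
        np.testing.assert_allclose(centre_of_gravity(mask), [12.0, 1.0, 2.5])

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            centre_of_gravity(make_mask(np.zeros((3, 3, 3), bool)))


class TestTRE:
    def test_perfect_match_is_zero(self):
        assert tre((1.0, 2.0, 3.0), (1.0, 2.0, 3.0)) == 0.0

    def test_three_four_five(self):
        assert tre((3.0, 4.0, 0.0), (0.0, 0.0, 0.0)) == 5.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        coords=hst.lists(hst.floats(-100, 100), min_size=6, max_size=6),
        angles=hst.lists(hst.floats(-180, 180), min_size=3, max_size=3),
        shift=hst.lists(hst.floats(-50, 50), min_size=3, max_size=3),
    )
    def test_invariant_under_common_rigid_transform(self, coords, angles, shift):
        a, b = np.array(coords[:3]), np.array(coords[3:])
        t = RigidTransform.from_euler_deg(angles, shift)
        assert abs(tre(a, b) - tre(t.apply(a)[0], t.apply(b)[0])) < 1e-9

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            tre((np.nan, 0, 0), (0, 0, 0))


class TestAverageObservers:
    def test_identical_observers(self):
        ann = np.tile([[1.0, 2.0, 3.0]], (4, 1)).reshape(4, 1, 3)
        np.testing.assert_array_equal(average_observers(ann), [[1.0, 2.0, 3.0]])

    def test_two_observer_mean(self):
        ann = np.array([[[0.0, 0.0, 0.0]], [[2.0, 0.0, 0.0]]])
        np.testing.assert_array_equal(average_observers(ann), [[1.0, 0.0, 0.0]])

    def test_missing_annotation_reported(self):
        ann = np.zeros((2, 2, 3))
        ann[1, 0] = np.nan
        with pytest.raises(ValueError, match=r"observer 1, tumour 0"):
            average_observers(ann)

    def test_mean_tre_bounded_by_mean_of_individual_tres(self):
        # Jensen: ||mean error|| <= mean ||error||, over 100 simulated sets
        rng = np.random.default_rng(42)
        truth = np.zeros(3)
        for _ in range(100):
            ann = rng.normal(0, 5, size=(4, 1, 3))
            tre_of_mean = tre(average_observers(ann)[0], truth)
            mean_of_tres = np.mean([tre(a[0], truth) for a in ann])
            assert tre_of_mean <= mean_of_tres + 1e-12


def build_table(tre_by_method: dict, failed: dict | None = None) -> StudyTable:
    """tre_by_method: {method: {tumour_id: tre}}."""
    failed = failed or {}
    table = StudyTable()
    for method, values in tre_by_method.items():
        for tid, val in values.items():
            is_failed = (method, tid) in failed
            table.add(
                TRERecord(
                    tumour_id=tid,
                    method=method,
                    annotated_centre_mm=None if is_failed else np.array([val, 0.0, 0.0]),
                    truth_centre_mm=np.zeros(3),
                    tre_mm=None if is_failed else val,
                    failed=is_failed,
                )
            )
    return table


class TestRanking:
    def test_clinical_winner_percentages(self):
        # 42 / 7 / 3 winners of 52 ranked tumours
        winners = {"non-rigid": 42, "rigid": 7, "mental": 3}
        tre_by = {m: {} for m in winners}
        tid = 0
        for method, n in winners.items():
            for _ in range(n):
                key = f"t{tid}"
                for m in winners:
                    tre_by[m][key] = 1.0 if m == method else 5.0 + tid % 3
                tid += 1
        out = rank_methods(build_table(tre_by))
        assert out.loc["non-rigid", "wins"] == 42
        assert out.loc["non-rigid", "percent"] == 80.8
        assert out.loc["rigid", "percent"] == 13.5
        assert out.loc["mental", "percent"] == 5.8

    def test_single_tumour_median_row_winner(self):
        # the clinical median TREs, forced as one tumour's values
        tre_by = {"non-rigid": {"t": 3.9}, "rigid": {"t": 9.0}, "mental": {"t": 10.9}}
        out = rank_methods(build_table(tre_by))
        assert out.loc["non-rigid", "wins"] == 1
        assert out["wins"].sum() == 1

    def test_extreme_rigid_outlier_loses_to_mental(self):
        tre_by = {"rigid": {"t3": 133.4}, "mental": {"t3": 20.4}}
        out = rank_methods(build_table(tre_by))
        assert out.loc["mental", "wins"] == 1 and out.loc["rigid", "wins"] == 0

    def test_exact_tie_yields_no_winner_with_warning(self):
        tre_by = {"a": {"t0": 2.0, "t1": 1.0}, "b": {"t0": 2.0, "t1": 3.0}}
        with pytest.warns(UserWarning, match="tie"):
            out = rank_methods(build_table(tre_by))
        assert out["wins"].sum() == 1
        assert out.attrs["ties"] == 1

    def test_wins_plus_ties_cover_all_ranked(self):
        rng = np.random.default_rng(3)
        tre_by = {
            m: {f"t{i}": float(rng.integers(1, 5)) for i in range(30)} for m in ("a", "b", "c")
        }
        import warnings as w

        with w.catch_warnings():
            w.simplefilter("ignore")
            out = rank_methods(build_table(tre_by))
        assert out["wins"].sum() + out.attrs["ties"] == 30

    def test_failed_tumour_excluded_from_all_methods(self):
        tre_by = {
            "a": {"t0": 1.0, "t1": 2.0},
            "b": {"t0": 2.0, "t1": 1.0},
        }
        table = build_table(tre_by, failed={("a", "t1")})
        assert table.excluded_tumours() == ["t1"]
        assert table.ranked_tumours() == ["t0"]
        summary = summarize(table)
        assert (summary["n"] == 1).all()  # t1 gone from *both* methods


class TestSummarize:
    def test_simple_values(self):
        table = build_table({"a": {"t0": 1.0, "t1": 2.0, "t2": 3.0}})
        s = summarize(table)
        assert s.loc["a", "median_tre_mm"] == 2.0
        assert s.loc["a", "mean_tre_mm"] == 2.0
        assert s.loc["a", "sd_tre_mm"] == 1.0

    def test_single_record_sd_absent(self):
        s = summarize(build_table({"a": {"t0": 4.2}}))
        assert s.loc["a", "median_tre_mm"] == 4.2
        assert np.isnan(s.loc["a", "sd_tre_mm"])

    def test_matches_independent_recomputation(self):
        rng = np.random.default_rng(9)
        values = {f"t{i}": float(rng.gamma(2.0, 2.0)) for i in range(25)}
        s = summarize(build_table({"m": values}))
        ref = pd.Series(list(values.values()))
        assert s.loc["m", "median_tre_mm"] == pytest.approx(ref.median())
        assert s.loc["m", "mean_tre_mm"] == pytest.approx(ref.mean())
        assert s.loc["m", "sd_tre_mm"] == pytest.approx(ref.std(ddof=1))
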