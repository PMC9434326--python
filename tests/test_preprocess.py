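"""Conditioning chain: filtering, imputation, scaling, detrending, smoothing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from circatrend.preprocess import (
    Design,
    ExpressionMatrix,
    detrend_linear,
    impute_missing,
    paired_presence_filter,
    preprocess,
    presence_filter,
    smooth,
    zscore_rows,
)


def make_matrix(rows, times=None, reps=None, ids=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    n = rows.shape[1]
    if times is None:
        times = np.arange(n, dtype=float) * 2
        reps = np.ones(n, dtype=int)
    design = Design(times=np.asarray(times, float), reps=np.asarray(reps, int))
    ids = ids or [f"f{i}" for i in range(rows.shape[0])]
    return ExpressionMatrix(pd.DataFrame(rows, index=ids, columns=design.column_labels()), design)


class TestPresenceFilter:
    def test_boundary_inclusive_and_order_preserved(self):
        nan = np.nan
        m = make_matrix(
            [
                [1, 2, 3, 4, 5, 6, 7, nan, nan, nan],  # 7/10 kept at 0.70
                [1, 2, 3, 4, 5, 6, nan, nan, nan, nan],  # 6/10 removed
                [nan] * 10,  # all-missing removed
                [1] * 10,
            ]
        )
        out = presence_filter(m, 0.70)
        assert list(out.feature_ids) == ["f0", "f3"]

    def test_monotone_in_fraction(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(30, 10))
        vals[rng.random(vals.shape) < 0.3] = np.nan
        m = make_matrix(vals)
        kept = [set(presence_filter(m, f).feature_ids) for f in (0.3, 0.5, 0.7, 0.9)]
        for small, large in zip(kept[1:], kept):
            assert small <= large

    def test_empty_matrix_passes_through(self):
        m = make_matrix(np.empty((0, 4)))
        assert presence_filter(m, 0.7).n_features == 0

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            presence_filter(make_matrix([[1.0, 2.0]]), 0.0)


class TestImputeMissing:
    def test_linear_midpoint(self):
        m = make_matrix([[1, np.nan, 3]], times=[0, 2, 4], reps=[1, 1, 1])
        np.testing.assert_allclose(impute_missing(m).values, [[1, 2, 3]])

    def test_identity_when_complete(self):
        m = make_matrix([[1.0, 5.0, 2.0]])
        np.testing.assert_array_equal(impute_missing(m).values, m.values)

    def test_single_point_mean_fallback(self):
        m = make_matrix([[5, np.nan, np.nan]], times=[0, 2, 4], reps=[1, 1, 1])
        np.testing.assert_allclose(impute_missing(m).values, [[5, 5, 5]])

    def test_edge_extrapolation_is_constant(self):
        m = make_matrix([[np.nan, 2, 4, np.nan]], times=[0, 2, 4, 6], reps=[1] * 4)
        np.testing.assert_allclose(impute_missing(m).values, [[2, 2, 4, 4]])

    def test_replicate_series_imputed_independently(self):
        # two replicates interleaved: missing value in rep 1 must use rep-1
        # neighbors only
        m = make_matrix(
            [[0.0, 100.0, np.nan, 100.0, 4.0, 100.0]],
            times=[0, 0, 2, 2, 4, 4],
            reps=[1, 2, 1, 2, 1, 2],
        )
        out = impute_missing(m)
        assert out.values[0, 2] == pytest.approx(2.0)

    def test_observed_entries_never_change(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(5, 12))
        mask = rng.random(vals.shape) < 0.2
        vals_missing = np.where(mask, np.nan, vals)
        m = make_matrix(vals_missing, times=np.repeat(np.arange(4) * 2.0, 3), reps=np.tile([1, 2, 3], 4))
        out = impute_missing(m)
        assert np.all(np.isfinite(out.values))
        np.testing.assert_array_equal(out.values[~mask], vals[~mask])


class TestZscoreRows:
    def test_mean_zero_sd_one(self):
        out = zscore_rows(make_matrix([[1.0, 2.0, 3.0]]))
        assert out.values.mean() == pytest.approx(0, abs=1e-9)
        assert out.values.std(ddof=1) == pytest.approx(1, abs=1e-9)

    def test_constant_row_maps_to_zeros(self):
        np.testing.assert_array_equal(zscore_rows(make_matrix([[4.0, 4.0, 4.0]])).values, [[0, 0, 0]])

    def test_two_point_row_sample_sd_convention(self):
        # (0 - 5)/7.0711 with ddof=1
        np.testing.assert_allclose(
            zscore_rows(make_matrix([[0.0, 10.0]])).values,
            [[-0.7071067811865475, 0.7071067811865475]],
            atol=1e-12,
        )

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        m = make_matrix(rng.normal(2, 5, size=(6, 20)))
        once = zscore_rows(m)
        twice = zscore_rows(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-9)


class TestDetrendLinear:
    def test_perfect_line_becomes_zero(self):
        t = np.arange(10) * 2.0
        m = make_matrix([3 * t + 1], times=t, reps=np.ones(10, int))
        np.testing.assert_allclose(detrend_linear(m).values, np.zeros((1, 10)), atol=1e-9)

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        m = make_matrix(rng.normal(size=(4, 16)))
        once = detrend_linear(m)
        np.testing.assert_allclose(detrend_linear(once).values, once.values, atol=1e-9)

    def test_cosine_nearly_unchanged(self):
        t = np.arange(0, 49, 2.0)
        y = np.cos(2 * np.pi * t / 24.0)
        m = make_matrix([y], times=t, reps=np.ones(t.size, int))
        out = detrend_linear(m).values[0]
        # OLS slope of a near-integer number of cycles is ~0
        slope = np.polyfit(t, y, 1)[0]
        assert abs(slope) < 5e-3
        np.testing.assert_allclose(out, y - y.mean() - slope * (t - t.mean()), atol=1e-9)

    def test_residual_mean_and_slope_zero(self):
        rng = np.random.default_rng(4)
        t = np.arange(0, 48, 4.0)
        m = make_matrix(rng.normal(size=(3, t.size)), times=t, reps=np.ones(t.size, int))
        out = detrend_linear(m)
        for row in out.values:
            assert row.mean() == pytest.approx(0, abs=1e-9)
            assert np.polyfit(t, row, 1)[0] == pytest.approx(0, abs=1e-9)


class TestSmooth:
    def test_constant_series_unchanged(self):
        m = make_matrix([[2.0] * 7])
        np.testing.assert_allclose(smooth(m).values, m.values, atol=1e-12)

    def test_interior_weighted_average(self):
        m = make_matrix([[0.0, 3.0, 0.0]])
        out = smooth(m, (1, 2, 1))
        assert out.values[0, 1] == pytest.approx(1.5)

    def test_boundary_renormalization(self):
        m = make_matrix([[4.0, 0.0, 0.0, 0.0]])
        out = smooth(m, (1, 2, 1))
        assert out.values[0, 0] == pytest.approx(8.0 / 3.0)

    def test_fewer_than_three_timepoints_identity(self):
        m = make_matrix([[1.0, 9.0]], times=[0, 2], reps=[1, 1])
        np.testing.assert_array_equal(smooth(m).values, m.values)

    def test_replicates_smoothed_separately(self):
        # identical per-replicate series must smooth as if alone
        single = make_matrix([[0.0, 3.0, 0.0]])
        both = make_matrix(
            [[0.0, 0.0, 3.0, 3.0, 0.0, 0.0]], times=[0, 0, 2, 2, 4, 4], reps=[1, 2, 1, 2, 1, 2]
        )
        out = smooth(both).values[0]
        expected = smooth(single).values[0]
        np.testing.assert_allclose(out[[0, 2, 4]], expected)
        np.testing.assert_allclose(out[[1, 3, 5]], expected)


class TestPairedPresenceFilter:
    def test_intersection_in_first_matrix_order(self):
        a = make_matrix(np.ones((3, 4)), ids=["a", "b", "c"])
        b = make_matrix(np.ones((3, 4)), ids=["c", "b", "d"])
        fa, fb = paired_presence_filter(a, b)
        assert list(fa.feature_ids) == ["b", "c"] == list(fb.feature_ids)

    def test_identical_sets_unchanged(self):
        a = make_matrix(np.ones((2, 4)), ids=["x", "y"])
        fa, fb = paired_presence_filter(a, a)
        assert list(fa.feature_ids) == ["x", "y"]

    def test_disjoint_sets_warn_and_empty(self):
        a = make_matrix(np.ones((1, 4)), ids=["a"])
        b = make_matrix(np.ones((1, 4)), ids=["b"])
        with pytest.warns(UserWarning):
            fa, fb = paired_presence_filter(a, b)
        assert fa.n_features == 0 and fb.n_features == 0


class TestFullChain:
    def test_pipeline_completes_and_never_leaves_missing(self):
        rng = np.random.default_rng(5)
        design = Design.regular(np.arange(0, 49, 2.0), 3)
        vals = rng.normal(size=(20, design.n_samples))
        vals[rng.random(vals.shape) < 0.1] = np.nan
        m = ExpressionMatrix(
            pd.DataFrame(vals, index=[f"g{i}" for i in range(20)], columns=design.column_labels()),
            design,
        )
        out = preprocess(m)
        assert np.all(np.isfinite(out.values))
        assert out.n_features > 0

    @given(st.integers(0, 2**31 - 1))
    def test_chain_deterministic(self, seed):
        rng = np.random.default_rng(seed)
        m = make_matrix(rng.normal(size=(3, 10)))
        a = preprocess(m, smooth_weights=(1, 2, 1)).values
        b = preprocess(m, smooth_weights=(1, 2, 1)).values
        np.testing.assert_array_equal(a, b)
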