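"""Constrained DTW against independent path-enumeration oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ricesist.dtw import DTWConfig, DTWResult, band_mask, dtw_distance, dtw_distance_batch
from ricesist.errors import InfeasibleBandError, InvalidInputError

finite_lai = st.floats(min_value=0.0, max_value=8.0, allow_nan=False)
series = st.lists(finite_lai, min_size=1, max_size=10).map(np.array)


def enumerate_min_path_cost(a, b, r=None, squared=False):
    """Oracle: minimum summed cost over ALL admissible monotone paths,
    found by plain depth-first recursion (no dynamic-programming reuse)."""
    m, n = len(a), len(b)
    mask = band_mask(m, n, r)

    def local(i, j):
        d = a[i] - b[j]
        return d * d if squared else abs(d)

    def best_from(i, j):
        if not mask[i, j]:
            return np.inf
        here = local(i, j)
        if i == m - 1 and j == n - 1:
            return here
        options = []
        if i + 1 < m:
            options.append(best_from(i + 1, j))
        if j + 1 < n:
            options.append(best_from(i, j + 1))
        if i + 1 < m and j + 1 < n:
            options.append(best_from(i + 1, j + 1))
        return here + min(options)

    return best_from(0, 0)


class TestBandMask:
    def test_square_zero_radius_is_diagonal(self):
        mask = band_mask(5, 5, 0)
        assert np.array_equal(mask, np.eye(5, dtype=bool))

    def test_radius_covering_grid_admits_everything(self):
        assert band_mask(20, 20, 20).all()

    def test_rectangular_band_matches_direct_inequality(self):
        mask = band_mask(4, 2, 0.5)
        expected = np.zeros((4, 2), dtype=bool)
        for i in range(1, 5):
            for j in range(1, 3):
                expected[i - 1, j - 1] = abs(j - (2 / 4) * i) <= 0.5
        assert np.array_equal(mask, expected)


class TestDTWDistance:
    def test_identity_zero_with_diagonal_path(self):
        a = np.array([0.3, 1.2, 3.4, 5.9, 4.2])
        result = dtw_distance(a, a, DTWConfig(return_path=True))
        assert result.distance == 0.0
        assert result.path == tuple((k, k) for k in range(1, 6))

    def test_three_by_two_grid(self):
        # oracle by enumeration over the 3x2 grid
        result = dtw_distance([1, 2, 3], [1, 3], DTWConfig(band_radius_r=None))
        assert result.distance == pytest.approx(1.0)

    def test_two_constant_series(self):
        result = dtw_distance([0, 0], [1, 1], DTWConfig(band_radius_r=None))
        assert result.distance == pytest.approx(2.0)

    def test_shifted_series_cheaper_than_aligned_distance(self):
        a = np.array([0.0, 1.0, 0.0, 0.0])
        b = np.array([0.0, 0.0, 1.0, 0.0])
        d = dtw_distance(a, b).distance
        assert d < np.abs(a - b).sum()

    def test_symmetry_for_equal_lengths(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.random(rng.integers(2, 9))
            b = rng.random(len(a))
            cfg = DTWConfig(band_radius_r=None)
            assert dtw_distance(a, b, cfg).distance == pytest.approx(
                dtw_distance(b, a, cfg).distance, abs=1e-12
            )

    def test_tighter_band_never_cheaper(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a, b = rng.random(12), rng.random(12)
            dists = [
                dtw_distance(a, b, DTWConfig(band_radius_r=r)).distance
                for r in (0, 1, 2, 4, 12)
            ]
            assert all(x >= y - 1e-12 for x, y in zip(dists, dists[1:]))

    def test_diagonal_upper_bound_equal_lengths(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a, b = rng.random(10), rng.random(10)
            assert dtw_distance(a, b).distance <= np.abs(a - b).sum() + 1e-12

    def test_matches_enumeration_on_small_series(self):
        rng = np.random.default_rng(3)
        for _ in range(40):
            a = rng.random(rng.integers(1, 8))
            b = rng.random(rng.integers(1, 8))
            d = dtw_distance(a, b, DTWConfig(band_radius_r=None)).distance
            assert d == pytest.approx(enumerate_min_path_cost(a, b), abs=1e-12)

    def test_matches_enumeration_with_band_and_squared_cost(self):
        rng = np.random.default_rng(4)
        checked = 0
        while checked < 20:
            a = rng.random(rng.integers(2, 8))
            b = rng.random(rng.integers(2, 8))
            r = float(rng.integers(1, 4))
            cfg = DTWConfig(band_radius_r=r, local_distance="squared")
            try:
                d = dtw_distance(a, b, cfg).distance
            except InfeasibleBandError:
                continue
            assert d == pytest.approx(
                enumerate_min_path_cost(a, b, r=r, squared=True), abs=1e-12
            )
            checked += 1

    def test_path_achieves_reported_distance(self):
        rng = np.random.default_rng(5)
        a, b = rng.random(15), rng.random(15)
        res = dtw_distance(a, b, DTWConfig(band_radius_r=3, return_path=True))
        # path invariants: endpoints, step set, band membership
        assert res.path[0] == (1, 1) and res.path[-1] == (15, 15)
        steps = {
            (q[0] - p[0], q[1] - p[1]) for p, q in zip(res.path, res.path[1:])
        }
        assert steps <= {(1, 0), (1, 1), (0, 1)}
        mask = band_mask(15, 15, 3)
        total = 0.0
        for i, j in res.path:
            assert mask[i - 1, j - 1]
            total += abs(a[i - 1] - b[j - 1])
        assert total == pytest.approx(res.distance, abs=1e-12)

    def test_infeasible_band_raises(self):
        with pytest.raises(InfeasibleBandError):
            dtw_distance([1, 2, 3, 4, 5], [1, 2], DTWConfig(band_radius_r=0))

    def test_empty_series_rejected(self):
        with pytest.raises(InvalidInputError):
            dtw_distance([], [1.0])


class TestMetricProperties:
    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(a=series)
    def test_self_distance_zero(self, a):
        assert dtw_distance(a, a, DTWConfig(band_radius_r=None)).distance == 0.0

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(a=series, b=series)
    def test_non_negative_and_symmetric(self, a, b):
        cfg = DTWConfig(band_radius_r=None)
        d_ab = dtw_distance(a, b, cfg).distance
        d_ba = dtw_distance(b, a, cfg).distance
        assert d_ab >= 0.0
        assert d_ab == pytest.approx(d_ba, abs=1e-9)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(a=series, b=series)
    def test_bounded_by_enumeration_oracle(self, a, b):
        d = dtw_distance(a, b, DTWConfig(band_radius_r=None)).distance
        assert d == pytest.approx(enumerate_min_path_cost(a, b), abs=1e-9)


class TestBatch:
    def test_batch_equals_scalar_calls(self):
        rng = np.random.default_rng(6)
        A = rng.random((30, 20))
        B = rng.random((30, 20))
        cfg = DTWConfig(band_radius_r=3)
        batch = dtw_distance_batch(A, B, cfg)
        scalar = np.array([dtw_distance(a, b, cfg).distance for a, b in zip(A, B)])
        np.testing.assert_allclose(batch, scalar, atol=1e-12)

    def test_mismatched_pixel_counts_rejected(self):
        with pytest.raises(InvalidInputError):
            dtw_distance_batch(np.ones((3, 5)), np.ones((4, 5)))
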