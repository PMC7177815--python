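"""Stress level, temporal dissimilarity/stability, and normalization."""

import numpy as np
import pytest

from ricesist.crop import CANONICAL_DOYS, LAISeries, simulate_lai, simulate_lai_daily, sample_canonical
from ricesist.dtw import DTWConfig, dtw_distance
from ricesist.errors import DegenerateRangeError, InvalidInputError
from ricesist.raster import SceneStack
from ricesist.scenes import synthetic_meteo
from ricesist.stress import (
    combined_stress,
    normalize_minmax,
    reference_series,
    stress_level,
    stress_surfaces,
    temporal_dissimilarity,
    temporal_stability,
)


def make_stack(series_grid, year=2017, mask=None):
    """Build a SceneStack from a (rows, cols) nested list of length-20 series."""
    rows, cols = len(series_grid), len(series_grid[0])
    lai = np.full((20, rows, cols), np.nan)
    if mask is None:
        mask = np.ones((rows, cols), dtype=bool)
    for r in range(rows):
        for c in range(cols):
            if mask[r, c]:
                lai[:, r, c] = series_grid[r][c]
    return SceneStack(year=year, lai=lai, rice_mask=np.asarray(mask, dtype=bool))


class TestNormalizeMinmax:
    def test_linear_map(self):
        arr = np.array([[2.0, 4.0, 6.0]])
        norm, vmin, vmax = normalize_minmax(arr, np.ones_like(arr, dtype=bool))
        np.testing.assert_allclose(norm, [[0.0, 0.5, 1.0]])
        assert (vmin, vmax) == (2.0, 6.0)

    def test_negative_values(self):
        arr = np.array([[-1.0, 0.0, 3.0]])
        norm, _, _ = normalize_minmax(arr, np.ones_like(arr, dtype=bool))
        np.testing.assert_allclose(norm, [[0.0, 0.25, 1.0]])

    def test_single_pixel_degenerate(self):
        arr = np.array([[5.0]])
        norm, _, _ = normalize_minmax(arr, np.ones_like(arr, dtype=bool))
        assert norm[0, 0] == 0.0

    def test_mask_excludes_extrema(self):
        arr = np.array([[0.0, 100.0], [2.0, 4.0]])
        mask = np.array([[False, False], [True, True]])
        norm, vmin, vmax = normalize_minmax(arr, mask)
        assert (vmin, vmax) == (2.0, 4.0)
        assert np.isnan(norm[0]).all()

    def test_empty_mask_rejected(self):
        with pytest.raises(DegenerateRangeError):
            normalize_minmax(np.ones((2, 2)), np.zeros((2, 2), dtype=bool))


class TestReferenceSeries:
    def test_is_unstressed_simulation(self, default_params, meteo_2017):
        ref = reference_series(default_params, meteo_2017, 2017)
        sim = simulate_lai(default_params, meteo_2017, 1.0, year=2017)
        np.testing.assert_array_equal(ref.values, sim.values)

    def test_identical_forcing_identical_reference(self, default_params, meteo_2017):
        a = reference_series(default_params, meteo_2017, 2017)
        b = reference_series(default_params, meteo_2017, 2018)
        np.testing.assert_array_equal(a.values, b.values)

    def test_lower_radiation_lowers_reference(self, default_params, meteo_2017):
        dimmer = [
            type(d)(
                doy=d.doy,
                tmax=d.tmax,
                tmin=d.tmin,
                sunshine_hours=d.sunshine_hours * 0.3,
                latitude_deg=d.latitude_deg,
            )
            for d in meteo_2017
        ]
        bright = reference_series(default_params, meteo_2017, 2017)
        dim = reference_series(default_params, dimmer, 2017)
        assert np.all(dim.values <= bright.values + 1e-12)


class TestStressLevel:
    def test_identical_to_reference_is_zero(self, default_params, meteo_2017):
        ref = reference_series(default_params, meteo_2017, 2017)
        stack = make_stack([[ref.values, ref.values]])
        s = stress_level(stack, ref)
        np.testing.assert_allclose(s, 0.0)

    def test_stronger_depression_scores_higher(self, default_params, meteo_2017):
        ref = reference_series(default_params, meteo_2017, 2017)
        stack = make_stack([[ref.values * 0.5, ref.values * 0.8]])
        s = stress_level(stack, ref)
        assert s[0, 0] > s[0, 1] > 0

    def test_raster_matches_scalar_dtw_calls(self, default_params, meteo_2017):
        rng = np.random.default_rng(0)
        ref = reference_series(default_params, meteo_2017, 2017)
        grid = [[np.maximum(ref.values + rng.normal(0, 0.5, 20), 0) for _ in range(2)]
                for _ in range(2)]
        stack = make_stack(grid)
        s = stress_level(stack, ref)
        cfg = DTWConfig()
        for r in range(2):
            for c in range(2):
                expected = dtw_distance(ref.values, grid[r][c], cfg).distance
                assert s[r, c] == pytest.approx(expected, abs=1e-12)

    def test_non_rice_is_nan(self, default_params, meteo_2017):
        ref = reference_series(default_params, meteo_2017, 2017)
        mask = np.array([[True, False]])
        stack = make_stack([[ref.values, ref.values]], mask=mask)
        s = stress_level(stack, ref)
        assert np.isnan(s[0, 1]) and np.isfinite(s[0, 0])


class TestCombinedStress:
    def test_endpoints_and_mean(self):
        mask = np.ones((1, 3), dtype=bool)
        a = np.array([[0.0, 1.0, 0.2]])
        b = np.array([[0.0, 1.0, 0.8]])
        out = combined_stress(a, b, mask)
        np.testing.assert_allclose(out, [[0.0, 1.0, 0.5]])

    def test_random_elementwise_mean(self):
        rng = np.random.default_rng(1)
        a, b = rng.random((4, 4)), rng.random((4, 4))
        mask = rng.random((4, 4)) < 0.7
        out = combined_stress(a, b, mask)
        np.testing.assert_allclose(out[mask], (a[mask] + b[mask]) / 2)
        assert np.isnan(out[~mask]).all()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            combined_stress(np.zeros((2, 2)), np.zeros((2, 3)), np.ones((2, 2), bool))


class TestTemporalDissimilarity:
    def _yearly_series(self, default_params, f_curves, shift=0):
        """Simulate one pixel under per-day f curves for two years."""
        out = []
        for year, f in zip((2017, 2018), f_curves):
            meteo = synthetic_meteo(year, seed=0)
            daily = simulate_lai_daily(default_params, meteo, f)
            out.append(sample_canonical(daily, shift if year == 2018 else 0))
        return out

    def test_identical_series_zero(self):
        series = np.linspace(0.3, 5, 20)
        a = make_stack([[series]], year=2017)
        b = make_stack([[series]], year=2018)
        assert temporal_dissimilarity(a, b)[0, 0] == 0.0

    def test_abrupt_stress_more_dissimilar_than_chronic(self, default_params):
        ones = np.ones(96)
        chronic = 0.6 * ones
        window = ones.copy()
        window[30:50] = 0.4
        hm_17, hm_18 = self._yearly_series(default_params, [chronic, chronic])
        ab_17, ab_18 = self._yearly_series(default_params, [window, ones])
        a17 = make_stack([[hm_17, ab_17]], year=2017)
        a18 = make_stack([[hm_18, ab_18]], year=2018)
        td = temporal_dissimilarity(a17, a18)
        assert td[0, 1] > td[0, 0]

    def test_phenology_shift_below_aligned_distance(self, default_params):
        ones = np.ones(96)
        s17, s18 = self._yearly_series(default_params, [ones, ones], shift=1)
        td = temporal_dissimilarity(
            make_stack([[s17]], 2017), make_stack([[s18]], 2018)
        )[0, 0]
        assert td < np.abs(np.asarray(s17) - np.asarray(s18)).sum()

    def test_mask_mismatch_rejected(self):
        series = np.linspace(0.3, 5, 20)
        a = make_stack([[series, series]], 2017, mask=np.array([[True, True]]))
        b = make_stack([[series, series]], 2018, mask=np.array([[True, False]]))
        with pytest.raises(InvalidInputError):
            temporal_dissimilarity(a, b)


class TestTemporalStability:
    def test_linear_complement(self):
        td = np.array([[0.0, 5.0, 10.0]])
        mask = np.ones_like(td, dtype=bool)
        ts, tdmin, tdmax = temporal_stability(td, mask)
        np.testing.assert_allclose(ts, [[1.0, 0.5, 0.0]])
        assert (tdmin, tdmax) == (0.0, 10.0)

    def test_constant_field_is_maximally_stable(self):
        td = np.full((2, 2), 3.3)
        ts, _, _ = temporal_stability(td, np.ones((2, 2), bool))
        np.testing.assert_allclose(ts, 1.0)

    def test_equals_one_minus_minmax(self):
        rng = np.random.default_rng(2)
        td = rng.random((5, 5)) * 7
        mask = rng.random((5, 5)) < 0.8
        ts, _, _ = temporal_stability(td, mask)
        norm, _, _ = normalize_minmax(td, mask)
        np.testing.assert_allclose(ts[mask], 1.0 - norm[mask])


class TestStressSurfaces:
    def test_bounds_and_nodata_propagation(self, default_params, meteo_2017):
        rng = np.random.default_rng(3)
        ref17 = reference_series(default_params, meteo_2017, 2017)
        mask = np.array([[True, True, False], [True, True, True]])
        grid17 = [[np.maximum(ref17.values * rng.uniform(0.4, 1.0)
                              + rng.normal(0, 0.1, 20), 0)
                   for _ in range(3)] for _ in range(2)]
        grid18 = [[np.maximum(ref17.values * rng.uniform(0.4, 1.0)
                              + rng.normal(0, 0.1, 20), 0)
                   for _ in range(3)] for _ in range(2)]
        a = make_stack(grid17, 2017, mask)
        b = make_stack(grid18, 2018, mask)
        surf = stress_surfaces(a, b, ref17, ref17)
        for arr in (surf.s_norm[2017], surf.s_norm[2018], surf.s_final, surf.ts):
            assert np.isnan(arr[~mask]).all()
            vals = arr[mask]
            assert np.all((vals >= -1e-12) & (vals <= 1 + 1e-12))
        assert set(surf.extrema) == {
            "smin_2017", "smax_2017", "smin_2018", "smax_2018", "tdmin", "tdmax",
        }
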