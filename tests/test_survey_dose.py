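"""Count -> kerma -> dose conversion, factor fits, summaries and rasters."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from carborne.survey import (
    CalibrationConstants,
    SurveyPoint,
    annual_effective_dose,
    assign_regions_by_polygon,
    fit_conversion_factor,
    fit_shielding_factor,
    grid_dose_map,
    kerma_from_counts,
    round_sig,
    summarize_regions,
)
from carborne.synthetic import (
    coastal_strip_field,
    serpentine_route,
    simulate_survey_track,
)


class TestFactorFits:
    def test_exact_line_recovers_shielding_factor(self, rng):
        inside = rng.uniform(1000.0, 9000.0, 34)
        assert fit_shielding_factor(inside, 1.47 * inside) == \
            pytest.approx(1.47)

    def test_identical_pairs_give_unity(self, rng):
        x = rng.uniform(100.0, 500.0, 10)
        assert fit_shielding_factor(x, x) == pytest.approx(1.0)

    def test_exact_conversion_factor(self, rng):
        cpm = rng.uniform(2e4, 3e5, 35)
        assert fit_conversion_factor(cpm, 0.00244 * cpm) == \
            pytest.approx(0.00244)

    def test_zero_kerma_everywhere_gives_zero(self, rng):
        cpm = rng.uniform(1e4, 1e5, 10)
        assert fit_conversion_factor(cpm, np.zeros(10)) == 0.0

    def test_poisson_noised_recovery_within_3se(self, rng):
        true_r = 1.47
        mean_in = rng.uniform(3000.0, 20000.0, 34)
        n_in = rng.poisson(mean_in)
        n_out = rng.poisson(true_r * mean_in)
        slope = fit_shielding_factor(n_in, n_out)
        resid = n_out - slope * n_in
        se = np.sqrt(resid @ resid / (34 - 1) / (n_in @ n_in))
        assert abs(slope - true_r) < 3 * se

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            fit_shielding_factor([100.0], [147.0])


class TestDoseEquations:
    def test_hand_evaluated_count_conversion(self):
        assert kerma_from_counts(10000) == pytest.approx(71.736)

    def test_zero_counts(self):
        assert kerma_from_counts(0) == 0.0

    def test_linearity_in_conversion_factor(self):
        half = CalibrationConstants(conversion_factor_ngy_h_per_cpm=0.00122)
        assert kerma_from_counts(5000, half) == \
            pytest.approx(kerma_from_counts(5000) / 2)

    @pytest.mark.parametrize("kerma, dose_2sf", [
        (2141.0, 13.0),
        (2021.0, 12.0),
        (0.0, 0.0),
    ])
    def test_annual_dose_examples(self, kerma, dose_2sf):
        assert round_sig(annual_effective_dose(kerma)) == \
            pytest.approx(dose_2sf)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(n=st.integers(0, 10**6))
    def test_dose_is_linear_in_counts(self, n):
        k1 = kerma_from_counts(n)
        k2 = kerma_from_counts(2 * n)
        assert k2 == pytest.approx(2 * k1)
        assert annual_effective_dose(2 * k1) == \
            pytest.approx(2 * annual_effective_dose(k1))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            kerma_from_counts(-1)


def _pt(lat, lon, counts, region="R", kerma=None):
    return SurveyPoint("2013-09-23T00:00:00", lat, lon, counts,
                       region=region, kerma_ngy_h=kerma)


class TestRegionSummaries:
    def test_single_point_collapses_statistics(self):
        s, = summarize_regions([_pt(9.0, 76.5, 8000)])
        assert s.n == 1
        assert s.mean_msv_y == s.median_msv_y == s.min_msv_y == s.max_msv_y
        assert s.cv_kerma_percent == 0.0

    def test_constant_region_has_zero_cv(self):
        pts = [_pt(9.0, 76.5 + i * 1e-3, 5000) for i in range(10)]
        s, = summarize_regions(pts)
        assert s.cv_kerma_percent == pytest.approx(0.0)

    def test_moments_match_direct_recomputation(self, rng):
        counts = rng.poisson(12000.0, 200)
        pts = [_pt(9.0, 76.5 + i * 1e-4, int(c))
               for i, c in enumerate(counts)]
        s, = summarize_regions(pts)
        dose = annual_effective_dose(
            np.array([kerma_from_counts(int(c)) for c in counts]))
        assert s.mean_msv_y == pytest.approx(round_sig(dose.mean()))
        assert s.median_msv_y == pytest.approx(round_sig(np.median(dose)))
        assert s.fraction_above_1msv == pytest.approx(np.mean(dose > 1.0))

    def test_permutation_invariance(self, rng):
        counts = rng.poisson(9000.0, 50)
        pts = [_pt(9.0, 76.5 + i * 1e-4, int(c))
               for i, c in enumerate(counts)]
        a = summarize_regions(pts)
        order = rng.permutation(len(pts))
        b = summarize_regions([pts[i] for i in order])
        assert a == b

    def test_unlabelled_point_rejected(self):
        with pytest.raises(ValueError):
            summarize_regions([_pt(9.0, 76.5, 100, region=None)])


class TestRoundSig:
    @pytest.mark.parametrize("x, expected", [
        (13.128, 13.0), (12.39, 12.0), (0.6543, 0.65),
        (2141.0, 2100.0), (2.141, 2.1), (0.0, 0.0),
    ])
    def test_two_significant_figures(self, x, expected):
        assert round_sig(x) == pytest.approx(expected)


class TestDoseGrid:
    def test_single_point_single_cell(self):
        g = grid_dose_map([_pt(9.001, 76.501, 10000)], cell_deg=0.005)
        assert (g.occupancy > 0).sum() == 1
        iy, ix = g.argmax_cell()
        assert g.values[iy, ix] == pytest.approx(kerma_from_counts(10000))

    def test_translation_shifts_raster_identically(self):
        pts = [_pt(9.0 + i * 1e-3, 76.5 + i * 2e-3, 1000 * (i + 1))
               for i in range(8)]
        moved = [_pt(p.lat + 0.05, p.lon + 0.1, p.counts) for p in pts]
        a = grid_dose_map(pts, cell_deg=0.005)
        b = grid_dose_map(moved, cell_deg=0.005)
        av, bv = a.values[a.occupancy > 0], b.values[b.occupancy > 0]
        assert np.allclose(np.sort(av), np.sort(bv))
        assert np.allclose(b.lon_edges[0] - a.lon_edges[0], 0.1)

    def test_hotspot_argmax_within_one_cell(self):
        field, coast = coastal_strip_field(seed=4)
        pts = simulate_survey_track(field, serpentine_route(field.extent),
                                    seed=4)
        labelled = [SurveyPoint(p.timestamp, p.lat, p.lon, p.counts,
                                region="x",
                                kerma_ngy_h=kerma_from_counts(p.counts))
                    for p in pts]
        cell = 0.005
        g = grid_dose_map(labelled, cell_deg=cell)
        iy, ix = g.argmax_cell()
        h = max(field.hotspots,
                key=lambda h: sum(h.peak_bq_kg.values()))
        assert abs(g.lon_centers[ix] - h.lon) <= 1.5 * cell
        assert abs(g.lat_centers[iy] - h.lat) <= 1.5 * cell

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            grid_dose_map([])


def test_polygon_region_assignment():
    fc = {"type": "FeatureCollection", "features": [{
        "type": "Feature",
        "properties": {"name": "West"},
        "geometry": {"type": "Polygon", "coordinates": [[
            [76.4, 8.9], [76.5, 8.9], [76.5, 9.1], [76.4, 9.1], [76.4, 8.9],
        ]]},
    }]}
    pts = [_pt(9.0, 76.45, 10, region=None), _pt(9.0, 76.55, 10,
                                                 region="East")]
    out = assign_regions_by_polygon(pts, fc)
    assert out[0].region == "West"
    assert out[1].region == "East"
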