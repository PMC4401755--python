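"""Background subtraction, unfolding and the 3x3 activity estimation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from carborne.response import ResolutionModel, ResponseMatrix
from carborne.unfolding import (
    BinnedCounts,
    EnergyBinSpectrum,
    cosmic_template,
    estimate_activities,
    kerma_total,
    subtract_cosmic,
    subtract_pmt_background,
    unfold,
)


class TestCosmicSubtraction:
    def test_pure_template_goes_to_zero(self, bins):
        t = cosmic_template(bins)
        b = BinnedCounts(t * 120.0, 300.0, bins=bins)
        out = subtract_cosmic(b)
        assert np.allclose(out.counts, 0.0, atol=1e-9)
        assert "cosmic_subtracted" in out.flags

    def test_zero_bin22_is_noop(self, bins, rng):
        c = rng.poisson(100.0, 22).astype(float)
        c[-1] = 0.0
        b = BinnedCounts(c, 300.0, bins=bins)
        out = subtract_cosmic(b)
        assert np.array_equal(out.counts, c)

    def test_terrestrial_bins_survive(self, bins, rng):
        terr = rng.uniform(500.0, 2000.0, 22)
        terr[-1] = 0.0
        cosmic = cosmic_template(bins) * 90.0
        b = BinnedCounts(terr + cosmic, 300.0, bins=bins)
        out = subtract_cosmic(b)
        sigma = np.sqrt(out.var)
        assert np.all(np.abs(out.counts[:-1] - terr[:-1]) <= 2 * sigma[:-1]
                      + 1e-6)
        assert out.counts[-1] == 0.0

    def test_template_without_bin22_content_rejected(self, bins):
        bad = np.ones(22)
        bad[-1] = 0.0
        with pytest.raises(ValueError):
            subtract_cosmic(BinnedCounts(np.ones(22), 10.0, bins=bins), bad)


class TestPmtSubtraction:
    def test_zero_background_is_identity(self, bins, rng):
        c = rng.poisson(50.0, 22).astype(float)
        b = BinnedCounts(c, 300.0, bins=bins)
        out = subtract_pmt_background(b, np.zeros(22))
        assert np.array_equal(out.counts, c)

    def test_background_equal_to_input_zeroes_it(self, bins):
        c = np.full(22, 60.0)
        b = BinnedCounts(c, 300.0, bins=bins)
        out = subtract_pmt_background(b, c / 300.0)
        assert np.allclose(out.counts, 0.0)


class TestUnfold:
    def test_identity_response_returns_count_rate(self, bins, rng):
        eye = ResponseMatrix(np.eye(22), bins, ResolutionModel())
        c = rng.poisson(300.0, 22).astype(float)
        spec = unfold(BinnedCounts(c, 100.0, bins=bins), eye)
        assert np.allclose(spec.flux, c / 100.0)

    def test_noise_free_round_trip(self, bins, response, library, rng):
        flux = (library.flux.T @ np.array([800.0, 300.0, 1200.0]))
        counts = response.matrix @ flux * 300.0
        spec = unfold(BinnedCounts(counts, 300.0, bins=bins), response)
        nz = flux > 1e-12
        assert np.max(np.abs(spec.flux[nz] - flux[nz]) / flux[nz]) < 0.01

    def test_singular_response_rejected(self, bins):
        m = np.zeros((22, 22))
        m[0, 0] = 1.0
        sing = ResponseMatrix(m, bins, ResolutionModel())
        with pytest.raises(ValueError, match="cond"):
            unfold(BinnedCounts(np.ones(22), 10.0, bins=bins), sing)

    def test_kerma_error_scale_at_moderate_kerma(self, bins, response,
                                                 library):
        """A 300-s spectrum at ~600 nGy/h carries a propagated kerma
        statistical error of order a percent."""
        a = np.array([300.0, 150.0, 800.0])
        flux = library.flux.T @ a
        counts = response.matrix @ flux * 300.0
        spec = unfold(BinnedCounts(counts, 300.0, bins=bins), response)
        est = estimate_activities(spec, library)
        assert 300.0 < est.total_kerma_ngy_h < 900.0
        assert 0.1 < est.kerma_percent_error < 6.0


class TestEstimateActivities:
    def _spectrum(self, bins, flux, cov=None):
        return EnergyBinSpectrum(flux=flux, errors=np.sqrt(np.abs(flux)),
                                 bins=bins, cov=cov)

    def test_single_nuclide_recovery(self, bins, library):
        flux = library.column("Th232_series") * 1000.0
        est = estimate_activities(self._spectrum(bins, flux), library)
        assert est.activities_bq_kg[2] == pytest.approx(1000.0, rel=1e-3)
        assert est.activities_bq_kg[0] == pytest.approx(0.0, abs=1e-6)
        assert est.activities_bq_kg[1] == pytest.approx(0.0, abs=1e-3)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(a_k=st.floats(0.0, 3000.0), a_u=st.floats(0.0, 3000.0),
           a_th=st.floats(0.0, 3000.0))
    def test_mixture_matches_direct_solve(self, bins, library, a_k, a_u,
                                          a_th):
        truth = np.array([a_k, a_u, a_th])
        flux = library.flux.T @ truth
        est = estimate_activities(self._spectrum(bins, flux), library)
        direct = np.linalg.solve(
            library.interference_matrix(),
            np.array([flux[13], flux[15] + flux[17], flux[19]]))
        assert np.allclose(est.activities_bq_kg, np.clip(direct, 0, None),
                           rtol=1e-3, atol=1e-6)
        assert np.allclose(est.activities_bq_kg, truth, rtol=1e-3, atol=1e-6)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(a_k=st.floats(10.0, 3000.0), a_u=st.floats(10.0, 3000.0),
           a_th=st.floats(10.0, 3000.0))
    def test_contributions_sum_to_100(self, bins, library, a_k, a_u, a_th):
        flux = library.flux.T @ np.array([a_k, a_u, a_th])
        est = estimate_activities(self._spectrum(bins, flux), library)
        assert abs(int(est.contributions_percent.sum()) - 100) <= 1
        assert est.total_kerma_ngy_h == pytest.approx(
            est.kerma_components_ngy_h.sum())

    def test_monotone_in_thorium(self, bins, library):
        base = np.array([500.0, 200.0, 400.0])
        ests = []
        for a_th in (400.0, 800.0, 1600.0):
            flux = library.flux.T @ np.array([base[0], base[1], a_th])
            ests.append(estimate_activities(self._spectrum(bins, flux),
                                            library))
        th = [e.activities_bq_kg[2] for e in ests]
        th_kerma = [e.kerma_components_ngy_h[2] for e in ests]
        assert th[0] < th[1] < th[2]
        assert th_kerma[0] < th_kerma[1] < th_kerma[2]

    def test_negative_flux_rejected(self, bins, library):
        flux = np.zeros(22)
        flux[5] = -1.0
        with pytest.raises(ValueError):
            estimate_activities(
                EnergyBinSpectrum(flux=flux, errors=np.zeros(22), bins=bins),
                library)


class TestKermaTotal:
    @pytest.mark.parametrize("components, total", [
        ((40.0, 558.0, 1543.0), 2141.0),
        ((40.0, 521.0, 1460.0), 2021.0),
        ((0.0, 0.0, 0.0), 0.0),
    ])
    def test_component_sums(self, components, total):
        assert kerma_total(components) == pytest.approx(total)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            kerma_total([1.0, 2.0])
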