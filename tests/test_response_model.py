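"""Energy bins, detector response, DEF and the ground-source flux library."""

import numpy as np
import pytest

from carborne.nucdata import NUCLIDES, line_library
from carborne.response import (
    EnergyBinScheme,
    ResolutionModel,
    ResponseMatrix,
    apply_def,
    build_energy_bins,
    build_response_matrix,
    build_unit_flux_library,
    kerma_from_flux,
    kerma_per_unit_flux,
    primary_flux_analytic,
    read_flux_library,
    read_response_matrix,
    write_flux_library,
    write_response_matrix,
)
from carborne.unfolding import BinnedCounts, unfold


@pytest.mark.parametrize("number, lo, hi", [
    (14, 1.39, 1.54),
    (16, 1.69, 1.84),
    (18, 2.10, 2.31),
    (20, 2.51, 2.72),
    (22, 3.0, 3.2),
])
def test_anchor_bins(bins, number, lo, hi):
    assert bins.bin_range(number) == pytest.approx((lo, hi))


def test_bins_tile_the_analysis_range(bins):
    assert bins.n_bins == 22
    assert bins.edges[0] == 0.0
    assert bins.edges[-1] == pytest.approx(3.2)
    assert np.all(np.diff(bins.edges) > 0)


def test_line_libraries_hold_the_calibration_lines():
    assert any(e == 1.464 for e, _ in line_library("K40").lines)
    u = [e for e, _ in line_library("U238_series").lines]
    assert 1.765 in u and 2.205 in u
    th = [e for e, _ in line_library("Th232_series").lines]
    assert 2.615 in th
    for n in NUCLIDES:
        for e, p in line_library(n).lines:
            assert 0 < e <= 2.615
            assert 0 < p <= 1


def test_response_column_kinematics(bins, response):
    # monoenergetic flux in bin 20 (2.615 MeV): photopeak mass in bin 20,
    # Compton continuum below the edge (2.38 MeV, inside bin 19), and
    # nothing beyond resolution tails above the peak
    col = response.matrix[:, 19]
    edge_bin = bins.index_of(2.0 * 2.615**2 / (0.511 + 2 * 2.615))
    assert edge_bin == 18
    assert col[19] > col.sum() * 0.1          # photopeak carries real mass
    assert col[: edge_bin + 1].sum() > 0      # continuum below the edge
    assert col[21] < 1e-9 * col[19]           # bin 22 is out of reach


def test_perfect_resolution_puts_peak_in_source_bin(bins):
    sharp = build_response_matrix(bins, ResolutionModel(1e-4))
    for j in range(bins.n_bins):
        col = sharp.matrix[:, j]
        peak_mass = col[j]
        # everything that is not continuum must sit in the source bin
        above = col[j + 1:].sum()
        assert above <= 1e-9 * max(peak_mass, 1.0)


def test_response_is_well_conditioned(response):
    assert np.isfinite(response.condition_number)
    assert response.condition_number < 1e3


def test_forward_unfold_round_trip_on_th_column(bins, response, library):
    flux = library.column("Th232_series") * 1000.0
    counts = response.matrix @ flux * 600.0
    spec = unfold(BinnedCounts(counts, 600.0, bins=bins), response)
    nz = flux > 0
    assert np.max(np.abs(spec.flux[nz] - flux[nz]) / flux[nz]) < 0.01


class TestDEF:
    def test_identity_when_measured_equals_model(self, response):
        res = response.resolution
        out = apply_def(response, {1.464: float(res.fwhm(1.464)),
                                   2.615: float(res.fwhm(2.615))})
        assert np.allclose(out.matrix, response.matrix, atol=1e-9)

    def test_doubled_fwhm_leaks_into_neighbours(self, bins, response):
        res = response.resolution
        out = apply_def(response, {1.464: 2 * float(res.fwhm(1.464)),
                                   2.615: 2 * float(res.fwhm(2.615))})
        for j in (13, 19):  # K-40 and Tl-208 photopeak columns
            neighbours = out.matrix[j - 1, j] + out.matrix[j + 1, j]
            before = response.matrix[j - 1, j] + response.matrix[j + 1, j]
            assert neighbours > before

    def test_column_sums_conserved(self, response):
        res = response.resolution
        out = apply_def(response, {1.464: 2 * float(res.fwhm(1.464)),
                                   2.615: 2 * float(res.fwhm(2.615))})
        rel = np.abs(out.column_sums() / response.column_sums() - 1.0)
        assert np.max(rel) <= 0.005

    def test_overwide_fwhm_flagged(self, response):
        out = apply_def(response, {1.464: 0.2, 2.615: 0.25})
        assert any("exceeds" in w for w in out.warnings)


class TestUnitFluxLibrary:
    def test_k40_flux_confined_below_its_photopeak_bin(self, library):
        k = library.column("K40")
        assert np.all(k[14:] == 0)     # nothing above bin 14
        assert k[13] > 0               # primary line in bin 14
        assert library.scattered[0, :13].sum() > 0

    def test_scatter_sits_below_each_line(self, library):
        # Th-232 series tops out at 2.615 MeV (bin 20): bins 21-22 empty
        th = library.column("Th232_series")
        assert np.all(th[20:] == 0)

    def test_primary_tally_matches_closed_form(self, library):
        phi_mc = library.primary[0].sum()
        phi_an = primary_flux_analytic(1.464, 0.107)
        assert phi_mc == pytest.approx(phi_an, rel=0.03)

    def test_kerma_coefficient_ordering(self, library):
        k, u, th = (library.kerma_coefficient(n) for n in NUCLIDES)
        assert th > u > k > 0

    def test_convergence_with_more_histories(self, bins):
        small = build_unit_flux_library(bins, histories=30_000, seed=11)
        big = build_unit_flux_library(bins, histories=60_000, seed=12)
        for i in range(3):
            a = small.kerma_coefficients[i]
            b = big.kerma_coefficients[i]
            se = np.sqrt(
                np.sum((small.stat_error[i] * small.kerma_per_flux) ** 2)
                + np.sum((big.stat_error[i] * big.kerma_per_flux) ** 2))
            assert abs(a - b) < max(4.0 * se, 0.05 * a)

    def test_empty_line_library_rejected(self, bins):
        with pytest.raises(ValueError):
            build_unit_flux_library(bins, libraries={}, histories=10)

    def test_interference_matrix_structure(self, library):
        m = library.interference_matrix()
        assert np.all(m[:, 2] > 0)       # Th feeds all three groups
        assert m[1, 0] == 0 and m[2, 0] == 0   # K absent above bin 14
        assert m[2, 1] == 0              # U absent from the Tl-208 group


class TestKermaFromFlux:
    def test_zero_flux(self, bins):
        assert kerma_from_flux(np.zeros(22), bins) == 0.0

    def test_linearity(self, bins, library, rng):
        f = library.column("U238_series") * 500.0
        assert kerma_from_flux(2 * f, bins) == pytest.approx(
            2 * kerma_from_flux(f, bins))

    def test_negative_flux_rejected(self, bins):
        f = np.zeros(22)
        f[3] = -1e-6
        with pytest.raises(ValueError):
            kerma_from_flux(f, bins)

    def test_th_column_scales_to_table_magnitude(self, bins, library):
        # 2374 Bq/kg of Th-232 series should produce ~1543 nGy/h
        k = kerma_from_flux(library.column("Th232_series") * 2374.0, bins)
        assert k == pytest.approx(1543.0, rel=0.25)


def test_serialization_round_trips(tmp_path, bins, response, library):
    p = tmp_path / "resp.txt"
    write_response_matrix(response, p)
    back = read_response_matrix(p)
    assert np.allclose(back.matrix, response.matrix)
    assert np.allclose(back.bins.edges, bins.edges)

    q = tmp_path / "lib.txt"
    write_flux_library(library, q)
    lib2 = read_flux_library(q)
    assert np.allclose(lib2.flux, library.flux)
    assert lib2.histories == library.histories
    with pytest.raises(ValueError):
        read_response_matrix(q)
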