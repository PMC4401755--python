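"""Detector response and ground-source flux modelling.

This module builds the pieces that turn a measured 22-bin pulse-height
spectrum into physics:

* the fixed 22-bin energy scheme spanning 0-3.2 MeV, with the four
  anchor bins that hold the K-40 (1.464 MeV), Bi-214 (1.765 and
  2.205 MeV) and Tl-208 (2.615 MeV) photopeaks and the 3.0-3.2 MeV
  cosmic-ray index bin;
* an analytic 22x22 response matrix for a 3-in x 3-in NaI(Tl) crystal
  in an isotropic field (Gaussian photopeak + flat Compton shelf per
  incident energy), including DEF re-broadening to a measured detector
  resolution;
* a per-nuclide library of gamma-ray flux densities 1 m above a
  semi-infinite homogeneous ground source, per unit activity
  concentration, computed with a one-dimensional Monte Carlo photon
  transport (analog Compton scattering, layered soil/air geometry,
  plane-crossing flux estimator), split into primary and scattered
  components;
* flux -> air-kerma-rate folding coefficients.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expn, ndtr

from . import nucdata
from .nucdata import (
    AIR_DENSITY_G_CM3,
    ELECTRON_REST_MEV,
    KERMA_UNIT_NGY_H,
    NAI_DENSITY_G_CM3,
    NUCLIDES,
    SOIL_DENSITY_G_CM3,
    NuclideLineLibrary,
    compton_edge,
    compton_mu_rho,
    line_library,
    mu_en_rho_air,
    mu_rho_air,
    mu_rho_nai,
    mu_rho_soil,
    photofraction,
)

__all__ = [
    "BIN_EDGES_MEV",
    "EnergyBinScheme",
    "build_energy_bins",
    "ResolutionModel",
    "ResponseMatrix",
    "build_response_matrix",
    "apply_def",
    "UnitFluxLibrary",
    "build_unit_flux_library",
    "primary_flux_analytic",
    "kerma_from_flux",
    "kerma_per_unit_flux",
    "write_response_matrix",
    "read_response_matrix",
    "write_flux_library",
    "read_flux_library",
]

# 23 edges -> 22 bins.  Bins 14, 16, 18, 20 and 22 (1-based) are fixed by the
# unfolding scheme; the remaining edges are this package's own tiling of
# [0, 3.2] MeV with widths growing with energy.
BIN_EDGES_MEV = np.array(
    [0.00, 0.05, 0.11, 0.18, 0.26, 0.35, 0.45, 0.56, 0.68, 0.81, 0.95,
     1.09, 1.24, 1.39, 1.54, 1.69, 1.84, 2.10, 2.31, 2.51, 2.72, 3.00, 3.20]
)

#: 1-based numbers of the anchor bins and the line energy each one holds
ANCHOR_LINES = {14: 1.464, 16: 1.765, 18: 2.205, 20: 2.615}

#: 1-based bin groups used by the 3x3 activity solve: K-40, Bi-214, Tl-208
KEY_BIN_GROUPS = ((14,), (16, 18), (20,))

# 3"x3" cylinder (R = 3.81 cm, L = 7.62 cm) in an isotropic field:
# mean projected area = S/4, mean chord = 4V/S.
DETECTOR_PROJECTED_AREA_CM2 = 68.43
DETECTOR_MEAN_CHORD_CM = 5.08


@dataclass(frozen=True)
class EnergyBinScheme:
    """Contiguous energy bins over [0, 3.2] MeV."""

    edges: np.ndarray = field(default_factory=lambda: BIN_EDGES_MEV.copy())

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if e.ndim != 1 or e.size != 23:
            raise ValueError("expected 23 edges for 22 bins")
        if not np.all(np.diff(e) > 0):
            raise ValueError("edges must be strictly increasing")
        object.__setattr__(self, "edges", e)

    @property
    def n_bins(self) -> int:
        return self.edges.size - 1

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.edges)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def bin_range(self, number: int) -> tuple[float, float]:
        """Edges of 1-based bin ``number``."""
        if not 1 <= number <= self.n_bins:
            raise ValueError(f"bin number {number} out of range")
        return float(self.edges[number - 1]), float(self.edges[number])

    def index_of(self, energy_mev: float) -> int:
        """0-based bin index containing ``energy_mev`` (right-open bins)."""
        i = int(np.searchsorted(self.edges, energy_mev, side="right")) - 1
        if i < 0 or i >= self.n_bins:
            raise ValueError(f"{energy_mev} MeV outside [0, 3.2)")
        return i

    @property
    def representative_energies(self) -> np.ndarray:
        """Energy assigned to flux in each bin: the anchored photopeak line
        where one exists, otherwise the bin centre."""
        rep = self.centers.copy()
        for number, e_line in ANCHOR_LINES.items():
            rep[number - 1] = e_line
        return rep


def build_energy_bins() -> EnergyBinScheme:
    """Return the fixed 22-bin scheme (see :data:`BIN_EDGES_MEV`)."""
    return EnergyBinScheme()


# --- resolution ------------------------------------------------------------


@dataclass(frozen=True)
class ResolutionModel:
    """Gaussian energy resolution with FWHM proportional to sqrt(E).

    ``fwhm_frac_662`` is FWHM/E at 0.662 MeV (default 7.5 %, a typical
    NaI(Tl) figure), so FWHM(E) = fwhm_frac_662 * sqrt(0.662 * E).
    """

    fwhm_frac_662: float = 0.075

    def fwhm(self, energy_mev):
        return self.fwhm_frac_662 * np.sqrt(0.662 * np.asarray(energy_mev, float))

    def sigma(self, energy_mev):
        return self.fwhm(energy_mev) / (2.0 * np.sqrt(2.0 * np.log(2.0)))

    @classmethod
    def from_measured_fwhms(cls, energies_mev, fwhms_mev) -> "ResolutionModel":
        """Least-squares fit of FWHM = c*sqrt(E) through measured peaks."""
        e = np.asarray(energies_mev, float)
        f = np.asarray(fwhms_mev, float)
        if np.any(f <= 0):
            raise ValueError("measured FWHMs must be positive")
        c = float(np.sum(f * np.sqrt(e)) / np.sum(e))
        return cls(fwhm_frac_662=c / np.sqrt(0.662))


# --- response matrix -------------------------------------------------------


def _interaction_probability(energy_mev):
    mu = mu_rho_nai(energy_mev) * NAI_DENSITY_G_CM3
    return 1.0 - np.exp(-mu * DETECTOR_MEAN_CHORD_CM)


def _response_column(energy_mev: float, out_edges: np.ndarray,
                     resolution: ResolutionModel) -> np.ndarray:
    """Detected count rate per unit incident flux density of a single
    energy, distributed over pulse-height intervals ``out_edges``.

    The model is a Gaussian full-energy peak carrying the photofraction
    plus a flat-in-energy Compton shelf from 0 up to the Compton edge.
    The peak Gaussian is renormalised over the covered pulse-height
    range so the column total is independent of the resolution.
    """
    eps_tot = DETECTOR_PROJECTED_AREA_CM2 * _interaction_probability(energy_mev)
    f_peak = float(photofraction(energy_mev))
    sigma = float(resolution.sigma(energy_mev))

    z = (out_edges - energy_mev) / sigma
    cdf = ndtr(z)
    peak_shape = np.diff(cdf)
    captured = cdf[-1] - cdf[0]
    if captured > 0:
        peak_shape = peak_shape / captured

    edge = float(compton_edge(energy_mev))
    lo = np.clip(out_edges[:-1], 0.0, edge)
    hi = np.clip(out_edges[1:], 0.0, edge)
    cont_shape = np.clip(hi - lo, 0.0, None)
    if cont_shape.sum() > 0:
        cont_shape = cont_shape / cont_shape.sum()

    return eps_tot * (f_peak * peak_shape + (1.0 - f_peak) * cont_shape)


@dataclass(frozen=True)
class ResponseMatrix:
    """22x22 detector response: count rate in pulse-height bin i per unit
    incident flux density in energy bin j."""

    matrix: np.ndarray
    bins: EnergyBinScheme
    resolution: ResolutionModel
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (self.bins.n_bins, self.bins.n_bins):
            raise ValueError("response matrix must be 22x22")
        if np.any(m < 0):
            raise ValueError("response matrix has negative elements")
        object.__setattr__(self, "matrix", m)

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))

    def column_sums(self) -> np.ndarray:
        return self.matrix.sum(axis=0)


def build_response_matrix(bins: EnergyBinScheme | None = None,
                          resolution: ResolutionModel | None = None,
                          ) -> ResponseMatrix:
    """Build the analytic standard response matrix.

    Column j uses the bin's representative energy (the photopeak line
    for the anchored bins, the bin centre otherwise).
    """
    bins = bins or build_energy_bins()
    resolution = resolution or ResolutionModel()
    cols = [_response_column(e, bins.edges, resolution)
            for e in bins.representative_energies]
    return ResponseMatrix(np.column_stack(cols), bins, resolution)


def apply_def(matrix: ResponseMatrix, measured_fwhms: dict[float, float],
              ) -> ResponseMatrix:
    """Diagonal-elements fitting: re-broaden the photopeaks so the model
    FWHM(E) interpolates the FWHMs measured on this detector (normally at
    1.464 and 2.615 MeV).  The Compton continuum is untouched and column
    sums are conserved.
    """
    energies = np.array(sorted(measured_fwhms))
    fwhms = np.array([measured_fwhms[e] for e in energies])
    new_res = ResolutionModel.from_measured_fwhms(energies, fwhms)
    rebuilt = build_response_matrix(matrix.bins, new_res)
    warns = list(matrix.warnings)
    for e, f in zip(energies, fwhms):
        i = matrix.bins.index_of(float(e))
        span = matrix.bins.widths[i]
        if f > span:
            warns.append(
                f"measured FWHM {f:.3f} MeV at {e:.3f} MeV exceeds its "
                f"bin span {span:.2f} MeV")
    return replace(rebuilt, warnings=tuple(warns))


# --- semi-infinite ground source flux --------------------------------------


@dataclass(frozen=True)
class UnitFluxLibrary:
    """Gamma flux densities 1 m above ground per unit activity concentration.

    ``primary``/``scattered`` are (3, 22) arrays in cm^-2 s^-1 per Bq/kg
    for (K40, U238_series, Th232_series); ``kerma_per_flux`` converts a
    unit flux density in each bin into nGy/h.
    """

    bins: EnergyBinScheme
    primary: np.ndarray
    scattered: np.ndarray
    kerma_per_flux: np.ndarray
    histories: int
    seed: int
    nuclides: tuple[str, ...] = NUCLIDES
    stat_error: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("primary", "scattered"):
            a = np.asarray(getattr(self, name), dtype=float)
            if a.shape != (len(self.nuclides), self.bins.n_bins):
                raise ValueError(f"{name} must be (3, 22)")
            if np.any(a < 0):
                raise ValueError(f"{name} has negative flux")
            object.__setattr__(self, name, a)

    @property
    def flux(self) -> np.ndarray:
        """Total (primary + scattered) flux, (3, 22)."""
        return self.primary + self.scattered

    def column(self, nuclide: str) -> np.ndarray:
        return self.flux[self.nuclides.index(nuclide)]

    def kerma_coefficient(self, nuclide: str) -> float:
        """Air kerma rate per unit activity, nGy/h per Bq/kg."""
        return float(self.column(nuclide) @ self.kerma_per_flux)

    @property
    def kerma_coefficients(self) -> np.ndarray:
        return self.flux @ self.kerma_per_flux

    def interference_matrix(self) -> np.ndarray:
        """3x3 matrix of key-bin-group flux per unit activity.

        Rows: groups {14}, {16,18}, {20} (1-based); columns: K, U, Th.
        """
        m = np.zeros((3, 3))
        for g, group in enumerate(KEY_BIN_GROUPS):
            for number in group:
                m[g, :] += self.flux[:, number - 1]
        return m


def kerma_per_unit_flux(bins: EnergyBinScheme) -> np.ndarray:
    """nGy/h produced by a unit flux density (cm^-2 s^-1) in each bin,
    evaluated at the bin's representative energy."""
    e = bins.representative_energies
    return e * mu_en_rho_air(e) * KERMA_UNIT_NGY_H


def kerma_from_flux(flux: np.ndarray, bins: EnergyBinScheme | None = None,
                    ) -> float:
    """Fold a 22-bin flux density spectrum into an air kerma rate, nGy/h."""
    bins = bins or build_energy_bins()
    f = np.asarray(flux, dtype=float)
    if f.shape != (bins.n_bins,):
        raise ValueError("flux must have 22 bins")
    if np.any(f < 0):
        raise ValueError("negative flux bin; clip upstream before folding")
    return float(f @ kerma_per_unit_flux(bins))


def primary_flux_analytic(energy_mev: float, intensity: float,
                          height_m: float = 1.0,
                          soil_density: float = SOIL_DENSITY_G_CM3) -> float:
    """Closed-form uncollided flux at ``height_m`` above a semi-infinite
    uniform source, cm^-2 s^-1 per Bq/kg: S_v / (2 mu_s) * E2(mu_a h).

    Used as the independent check on the Monte Carlo primary tally.
    """
    s_v = soil_density * 1e-3 * intensity  # photons cm^-3 s^-1 per Bq/kg
    mu_s = mu_rho_soil(energy_mev) * soil_density
    tau_air = mu_rho_air(energy_mev) * AIR_DENSITY_G_CM3 * height_m * 100.0
    return float(s_v / (2.0 * mu_s) * expn(2, tau_air))


def _sample_compton(rng: np.random.Generator, e: np.ndarray,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Sample scattered energy and polar scattering cosine from the
    Klein-Nishina distribution (rejection on eps = E'/E)."""
    alpha = e / ELECTRON_REST_MEV
    eps_min = 1.0 / (1.0 + 2.0 * alpha)
    f_max = eps_min + 1.0 / eps_min
    n = e.size
    eps = np.empty(n)
    pending = np.ones(n, dtype=bool)
    while pending.any():
        idx = np.nonzero(pending)[0]
        trial = rng.uniform(eps_min[idx], 1.0)
        cos_t = 1.0 + 1.0 / alpha[idx] - 1.0 / (alpha[idx] * trial)
        f = trial + 1.0 / trial - (1.0 - cos_t**2)
        accept = rng.uniform(0.0, f_max[idx]) < f
        eps[idx[accept]] = trial[accept]
        pending[idx[accept]] = False
    cos_theta = 1.0 + 1.0 / alpha - 1.0 / (alpha * eps)
    return e * eps, cos_theta


def build_unit_flux_library(bins: EnergyBinScheme | None = None,
                            libraries: dict[str, NuclideLineLibrary] | None = None,
                            histories: int = 1_000_000,
                            seed: int = 0,
                            height_m: float = 1.0,
                            soil_density: float = SOIL_DENSITY_G_CM3,
                            max_depth_mfp: float = 10.0,
                            ) -> UnitFluxLibrary:
    """One-dimensional Monte Carlo transport of ``histories`` photons per
    nuclide through a layered soil/air half-space.

    Photons are born uniformly in depth down to ``max_depth_mfp`` mean
    free paths (deeper emission cannot reach the surface at any relevant
    level), assigned to gamma lines in proportion to emission intensity,
    and tracked with analog Compton scattering and photoelectric/pair
    absorption.  Flux at ``height_m`` is tallied with a plane-crossing
    estimator w/|mu| (|mu| floored at 0.02, a sub-percent bias), split
    into primary (uncollided) and scattered components.
    """
    bins = bins or build_energy_bins()
    if libraries is None:
        libraries = {n: line_library(n) for n in NUCLIDES}
    for n in NUCLIDES:
        if n not in libraries or not libraries[n].lines:
            raise ValueError(f"line library missing or empty for {n}")
    if histories < 1:
        raise ValueError("histories must be >= 1")

    rng = np.random.default_rng(seed)
    h_cm = height_m * 100.0
    e_min = 0.03       # kill threshold, MeV
    mu_floor = 0.02    # plane-crossing estimator floor on |mu|
    z_kill = 1.0e5     # cm; photons this high in air cannot contribute

    primary = np.zeros((3, bins.n_bins))
    scattered = np.zeros((3, bins.n_bins))
    sq_sum = np.zeros((3, bins.n_bins))

    for i_nuc, name in enumerate(NUCLIDES):
        lib = libraries[name]
        energies = lib.energies
        intensities = lib.intensities
        i_total = intensities.sum()

        line_idx = rng.choice(energies.size, size=histories,
                              p=intensities / i_total)
        e = energies[line_idx].astype(float)
        # uniform emission depth down to max_depth_mfp mfp at the line energy
        depth_cm = max_depth_mfp / (mu_rho_soil(e) * soil_density)
        z = -rng.uniform(0.0, 1.0, histories) * depth_cm
        mu = rng.uniform(-1.0, 1.0, histories)
        # source density per Bq/kg: rho[g/cm3] * 1e-3[kg/g] * intensity
        w = soil_density * 1e-3 * i_total * depth_cm / histories
        n_coll = np.zeros(histories, dtype=np.int64)
        alive = np.ones(histories, dtype=bool)

        for _ in range(200):
            if not alive.any():
                break
            idx = np.nonzero(alive)[0]
            ze, mue, ee, we = z[idx], mu[idx], e[idx], w[idx]

            in_soil = ze < 0.0
            mu_med = np.where(
                in_soil,
                mu_rho_soil(ee) * soil_density,
                mu_rho_air(ee) * AIR_DENSITY_G_CM3,
            )
            mu_other = np.where(
                in_soil,
                mu_rho_air(ee) * AIR_DENSITY_G_CM3,
                mu_rho_soil(ee) * soil_density,
            )
            tau = rng.exponential(size=idx.size)
            with np.errstate(divide="ignore", invalid="ignore"):
                d_collide = tau / mu_med
                # distance to the soil/air interface along the flight
                toward = np.where(in_soil, mue > 0, mue < 0)
                d_bound = np.where(toward, np.abs(ze / np.where(mue == 0, np.inf, mue)),
                                   np.inf)
            with np.errstate(invalid="ignore"):
                cross = d_collide > d_bound
                d_total = np.where(
                    cross,
                    d_bound + (tau - mu_med * d_bound) / mu_other,
                    d_collide,
                )
            z_new = ze + mue * d_total

            # tally detector-plane crossing (z monotone along the flight)
            hit = ((ze - h_cm) * (z_new - h_cm) < 0.0)
            if hit.any():
                hi = np.nonzero(hit)[0]
                contrib = we[hi] / np.maximum(np.abs(mue[hi]), mu_floor)
                b = np.searchsorted(bins.edges, ee[hi], side="right") - 1
                ok = (b >= 0) & (b < bins.n_bins)
                prim = n_coll[idx[hi]] == 0
                np.add.at(primary[i_nuc], b[ok & prim], contrib[ok & prim])
                np.add.at(scattered[i_nuc], b[ok & ~prim], contrib[ok & ~prim])
                np.add.at(sq_sum[i_nuc], b[ok], contrib[ok] ** 2)

            z[idx] = z_new

            # collision: scatter or absorb (density cancels in mu_c/mu_tot)
            mu_tot_mass = np.where(z_new < 0.0, mu_rho_soil(ee), mu_rho_air(ee))
            p_scatter = np.clip(compton_mu_rho(ee) / mu_tot_mass, 0.0, 1.0)
            survive = rng.uniform(size=idx.size) < p_scatter

            e_new, cos_t = _sample_compton(rng, ee)
            phi = rng.uniform(0.0, 2.0 * np.pi, idx.size)
            sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, None))
            mu_new = (mue * cos_t
                      + np.sqrt(np.clip(1.0 - mue**2, 0.0, None)) * sin_t
                      * np.cos(phi))
            mu_new = np.clip(mu_new, -1.0, 1.0)

            dead = (~survive) | (e_new < e_min) | (z_new > z_kill) \
                | (z_new < -1.5 * depth_cm[idx] - 200.0)
            alive[idx[dead]] = False
            keep = ~dead
            e[idx[keep]] = e_new[keep]
            mu[idx[keep]] = mu_new[keep]
            n_coll[idx[keep]] += 1

    total = primary + scattered
    var = np.clip(sq_sum - total**2 / max(histories, 1), 0.0, None)
    stat_error = np.sqrt(var)

    return UnitFluxLibrary(
        bins=bins,
        primary=primary,
        scattered=scattered,
        kerma_per_flux=kerma_per_unit_flux(bins),
        histories=histories,
        seed=seed,
        stat_error=stat_error,
    )


# --- plain-text serialization ----------------------------------------------

_MATRIX_MAGIC = "# carborne response-matrix v1"
_LIBRARY_MAGIC = "# carborne flux-library v1"


def write_response_matrix(matrix: ResponseMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(_MATRIX_MAGIC + "\n")
        fh.write("# edges_mev " + " ".join(f"{e:.6g}" for e in matrix.bins.edges) + "\n")
        fh.write(f"# fwhm_frac_662 {matrix.resolution.fwhm_frac_662:.8g}\n")
        np.savetxt(fh, matrix.matrix, fmt="%.8e")


def read_response_matrix(path) -> ResponseMatrix:
    with open(path) as fh:
        magic = fh.readline().strip()
        if magic != _MATRIX_MAGIC:
            raise ValueError(f"not a response-matrix file: {magic!r}")
        edges = np.array(fh.readline().split()[2:], dtype=float)
        fwhm = float(fh.readline().split()[2])
        m = np.loadtxt(fh)
    return ResponseMatrix(m, EnergyBinScheme(edges), ResolutionModel(fwhm))


def write_flux_library(lib: UnitFluxLibrary, path) -> None:
    with open(path, "w") as fh:
        fh.write(_LIBRARY_MAGIC + "\n")
        fh.write("# edges_mev " + " ".join(f"{e:.6g}" for e in lib.bins.edges) + "\n")
        fh.write(f"# histories {lib.histories}\n")
        fh.write(f"# seed {lib.seed}\n")
        fh.write("# rows: primary x3 (K, U, Th), scattered x3, kerma_per_flux\n")
        data = np.vstack([lib.primary, lib.scattered, lib.kerma_per_flux[None, :]])
        np.savetxt(fh, data, fmt="%.8e")


def read_flux_library(path) -> UnitFluxLibrary:
    with open(path) as fh:
        magic = fh.readline().strip()
        if magic != _LIBRARY_MAGIC:
            raise ValueError(f"not a flux-library file: {magic!r}")
        edges = np.array(fh.readline().split()[2:], dtype=float)
        histories = int(fh.readline().split()[2])
        seed = int(fh.readline().split()[2])
        fh.readline()
        data = np.loadtxt(fh)
    return UnitFluxLibrary(
        bins=EnergyBinScheme(edges),
        primary=data[0:3],
        scattered=data[3:6],
        kerma_per_flux=data[6],
        histories=histories,
        seed=seed,
    )
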