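"""Nuclear and atomic data used across the package.

Gamma line libraries for the three terrestrial emitters (``K40``,
``U238_series``, ``Th232_series``), mass attenuation / energy-absorption
tables for dry soil, air and NaI, and a photofraction model for a
3-in x 3-in NaI(Tl) crystal in an isotropic field.

The series libraries assume secular equilibrium, so one activity
concentration (Bq/kg of the series parent) describes every daughter.
Intensities are photons per parent decay; daughters with a branching
fraction (e.g. Tl-208 at 35.9 % of Th-232 decays) carry that factor
already folded in.  Values are the Beck-style line lists commonly used
for environmental gamma spectrometry, trimmed to lines with intensity
above about 1 % per decay.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NuclideLineLibrary",
    "NUCLIDES",
    "line_library",
    "mu_rho_soil",
    "mu_rho_air",
    "mu_en_rho_air",
    "mu_rho_nai",
    "compton_mu_rho",
    "photofraction",
    "SOIL_DENSITY_G_CM3",
    "AIR_DENSITY_G_CM3",
    "NAI_DENSITY_G_CM3",
    "ELECTRON_REST_MEV",
    "KERMA_UNIT_NGY_H",
    "compton_edge",
]

NUCLIDES = ("K40", "U238_series", "Th232_series")

#: electron rest energy, MeV
ELECTRON_REST_MEV = 0.5110

#: bulk density of dry soil assumed for the semi-infinite ground source, g/cm3
SOIL_DENSITY_G_CM3 = 1.6

#: air density at ~20 C, sea level, g/cm3
AIR_DENSITY_G_CM3 = 1.205e-3

NAI_DENSITY_G_CM3 = 3.667

#: converts flux * E(MeV) * mu_en/rho(cm2/g) into nGy/h
#: 1 MeV g^-1 s^-1 = 1.602e-10 Gy/s -> x3600 -> 5.767e-7 Gy/h = 576.7 nGy/h
KERMA_UNIT_NGY_H = 1.602176634e-10 * 3600.0 * 1e9


@dataclass(frozen=True)
class NuclideLineLibrary:
    """Discrete gamma lines of one emitter.

    Parameters
    ----------
    nuclide
        One of ``K40``, ``U238_series``, ``Th232_series``.
    lines
        Sequence of ``(energy_MeV, photons_per_parent_decay)``.
    """

    nuclide: str
    lines: tuple[tuple[float, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.nuclide not in NUCLIDES:
            raise ValueError(f"unknown nuclide {self.nuclide!r}")
        if not self.lines:
            raise ValueError("empty line library")
        for e, p in self.lines:
            if not (0.0 < e <= 2.615):
                raise ValueError(f"line energy {e} MeV outside (0, 2.615]")
            if not (0.0 < p <= 1.0):
                raise ValueError(f"emission probability {p} outside (0, 1]")

    @property
    def energies(self) -> np.ndarray:
        return np.array([e for e, _ in self.lines])

    @property
    def intensities(self) -> np.ndarray:
        return np.array([p for _, p in self.lines])


# (energy MeV, photons per decay of the series parent).  Sources noted per line.
_K40_LINES = (
    (1.464, 0.107),     # K-40 EC gamma, 10.7 %
)

_U238_LINES = (
    # Pb-214
    (0.242, 0.074),
    (0.295, 0.184),
    (0.352, 0.356),
    # Bi-214
    (0.609, 0.455),
    (0.665, 0.015),
    (0.768, 0.049),
    (0.806, 0.012),
    (0.934, 0.031),
    (1.120, 0.149),
    (1.155, 0.017),
    (1.238, 0.058),
    (1.281, 0.014),
    (1.378, 0.040),
    (1.408, 0.025),
    (1.509, 0.021),
    (1.661, 0.011),
    (1.730, 0.029),
    (1.765, 0.153),
    (1.847, 0.020),
    (2.118, 0.012),
    (2.205, 0.049),
    (2.448, 0.015),
)

_TH232_LINES = (
    # Pb-212
    (0.239, 0.436),
    (0.300, 0.033),
    # Ac-228
    (0.209, 0.039),
    (0.270, 0.035),
    (0.328, 0.030),
    (0.338, 0.113),
    (0.463, 0.044),
    (0.794, 0.043),
    (0.835, 0.017),
    (0.911, 0.258),
    (0.964, 0.050),
    (0.969, 0.158),
    (1.588, 0.032),
    (1.630, 0.015),
    # Bi-212
    (0.727, 0.066),
    (0.785, 0.011),
    (1.621, 0.015),
    # Tl-208 (35.9 % branch of the series folded in)
    (0.277, 0.023),
    (0.511, 0.081),
    (0.583, 0.304),
    (0.861, 0.045),
    (2.615, 0.358),
)

_LIBRARIES = {
    "K40": NuclideLineLibrary("K40", _K40_LINES),
    "U238_series": NuclideLineLibrary("U238_series", _U238_LINES),
    "Th232_series": NuclideLineLibrary("Th232_series", _TH232_LINES),
}


def line_library(nuclide: str) -> NuclideLineLibrary:
    """Return the built-in gamma line library for one emitter."""
    try:
        return _LIBRARIES[nuclide]
    except KeyError:
        raise ValueError(f"unknown nuclide {nuclide!r}") from None


# --- attenuation data ------------------------------------------------------
# Log-log interpolation grids, cm2/g.  Values follow the standard tabulations
# (NIST XCOM style); soil is modelled as quartz-like dry soil (SiO2), a common
# surrogate when the actual composition is unknown.

_E_GRID = np.array(
    [0.03, 0.05, 0.08, 0.10, 0.15, 0.20, 0.30, 0.40, 0.50,
     0.60, 0.80, 1.00, 1.25, 1.50, 2.00, 3.00]
)

_MU_RHO_AIR = np.array(
    [0.3538, 0.2080, 0.1662, 0.1541, 0.1356, 0.1233, 0.1067, 0.09549,
     0.08712, 0.08055, 0.07074, 0.06358, 0.05687, 0.05175, 0.04447, 0.03581]
)

_MU_EN_RHO_AIR = np.array(
    [0.1501, 0.04098, 0.02407, 0.02325, 0.02496, 0.02672, 0.02872, 0.02949,
     0.02966, 0.02953, 0.02882, 0.02789, 0.02666, 0.02547, 0.02345, 0.02057]
)

_MU_RHO_SOIL = np.array(
    [0.872, 0.3184, 0.1935, 0.1681, 0.1394, 0.1255, 0.1076, 0.0959,
     0.0874, 0.0807, 0.0708, 0.0637, 0.0570, 0.0519, 0.0447, 0.0363]
)

_MU_RHO_NAI = np.array(
    [10.0, 5.00, 1.70, 1.669, 0.578, 0.316, 0.145, 0.106,
     0.0870, 0.0776, 0.0656, 0.0584, 0.0530, 0.0486, 0.0438, 0.0409]
)


def _loglog_interp(energy, grid_y):
    e = np.clip(np.asarray(energy, dtype=float), _E_GRID[0], _E_GRID[-1])
    return np.exp(np.interp(np.log(e), np.log(_E_GRID), np.log(grid_y)))


def mu_rho_air(energy_mev):
    """Mass attenuation coefficient of air, cm2/g."""
    return _loglog_interp(energy_mev, _MU_RHO_AIR)


def mu_en_rho_air(energy_mev):
    """Mass energy-absorption coefficient of air, cm2/g."""
    return _loglog_interp(energy_mev, _MU_EN_RHO_AIR)


def mu_rho_soil(energy_mev):
    """Mass attenuation coefficient of quartz-like dry soil, cm2/g."""
    return _loglog_interp(energy_mev, _MU_RHO_SOIL)


def mu_rho_nai(energy_mev):
    """Mass attenuation coefficient of NaI, cm2/g."""
    return _loglog_interp(energy_mev, _MU_RHO_NAI)


def compton_mu_rho(energy_mev, z_over_a=0.499):
    """Compton (incoherent) mass attenuation coefficient, cm2/g.

    Integrated Klein-Nishina cross section per electron times the
    electron density Z/A * N_A; Z/A defaults to 0.499 (air, water and
    quartz all sit near 0.50).
    """
    e = np.asarray(energy_mev, dtype=float)
    k = e / ELECTRON_REST_MEV
    # total KN cross section, units of the Thomson-scale prefactor
    term1 = (1.0 + k) / k**2 * (2.0 * (1.0 + k) / (1.0 + 2.0 * k)
                                - np.log(1.0 + 2.0 * k) / k)
    term2 = np.log(1.0 + 2.0 * k) / (2.0 * k)
    term3 = -(1.0 + 3.0 * k) / (1.0 + 2.0 * k) ** 2
    sigma_kn = 2.0 * np.pi * (2.817940e-13) ** 2 * (term1 + term2 + term3)
    return sigma_kn * 6.02214076e23 * z_over_a


def compton_edge(energy_mev):
    """Compton edge energy (maximum electron energy), MeV."""
    e = np.asarray(energy_mev, dtype=float)
    return 2.0 * e**2 / (ELECTRON_REST_MEV + 2.0 * e)


# Photofraction (photopeak / total detected) for a 3x3 NaI(Tl) crystal in an
# isotropic field; coarse literature-style curve, log-E interpolated.
_PF_E = np.array([0.05, 0.10, 0.20, 0.30, 0.40, 0.50, 0.662,
                  0.80, 1.00, 1.25, 1.50, 2.00, 2.615, 3.20])
_PF = np.array([0.98, 0.96, 0.90, 0.80, 0.72, 0.65, 0.56,
                0.50, 0.44, 0.38, 0.34, 0.28, 0.235, 0.21])


def photofraction(energy_mev):
    """Fraction of detected events landing in the full-energy peak."""
    e = np.clip(np.asarray(energy_mev, dtype=float), _PF_E[0], _PF_E[-1])
    return np.interp(np.log(e), np.log(_PF_E), _PF)
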