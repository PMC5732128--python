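"""Photon-interaction data for the Monte Carlo transport model.

The transport model covers the two bulk media that matter for torso-phantom
imaging with a 99mTc tracer: air and water (soft tissue is water-equivalent
at 140.5 keV to within a few percent).  Two interaction channels are
modelled per material:

* photoelectric absorption, from a compact embedded table of mass
  attenuation coefficients (cm^2/g) versus energy, log-log interpolated
  (approximate values, 2-3 significant figures, from a standard reference
  compilation of photon cross sections);
* incoherent (Compton) scattering, computed from the closed-form
  Klein-Nishina total cross-section per electron multiplied by the electron
  density N_A * (Z/A) of the material.

Deriving the incoherent channel from the Klein-Nishina cross-section keeps
the attenuation coefficients exactly consistent with the scattering-angle
distribution sampled during transport (which is also Klein-Nishina).
Electron binding and Doppler broadening are neglected, and coherent
(Rayleigh) scattering is omitted entirely: it changes no photon energy and
deflects by small angles only, and leaving it out of both the attenuation
and the scattering model keeps the transport self-consistent.

All energies are keV, mass attenuation coefficients cm^2/g, densities
g/cm^3 and linear attenuation coefficients 1/mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

AIR = 0
WATER = 1
MATERIAL_NAMES = ("air", "water")

#: principal gamma emission of 99mTc (keV)
EMISSION_ENERGY_KEV = 140.5
#: gammas emitted per decay for the 140.5-keV line of 99mTc
PHOTONS_PER_DECAY = 0.885

ELECTRON_REST_KEV = 510.998_95
CLASSICAL_ELECTRON_RADIUS_CM = 2.817_940_3262e-13
AVOGADRO = 6.022_140_76e23

#: electrons per atomic mass unit, Z/A (dimensionless)
Z_OVER_A = {AIR: 0.499_19, WATER: 0.555_09}
#: bulk densities used by the phantom generators (g/cm^3)
DENSITY_G_CM3 = {AIR: 0.001_29, WATER: 1.0}

# Photoelectric mass attenuation coefficients (cm^2/g).  Approximate values
# from a standard compilation of photon cross sections; adequate for the
# sub-percent photoelectric fraction above 100 keV in low-Z media.
_PE_ENERGIES = np.array(
    [10.0, 15.0, 20.0, 30.0, 40.0, 50.0, 60.0, 80.0, 100.0, 150.0, 200.0, 300.0]
)
_PE_TABLE = {
    WATER: np.array(
        [4.94, 1.37, 0.544, 0.151, 0.0600, 0.0294, 0.0163,
         0.00626, 0.00294, 7.67e-4, 2.89e-4, 8.6e-5]
    ),
    AIR: np.array(
        [4.60, 1.27, 0.503, 0.139, 0.0553, 0.0271, 0.0150,
         0.00577, 0.00271, 7.07e-4, 2.67e-4, 8.0e-5]
    ),
}


def kn_cross_section(energy_kev):
    """Total Klein-Nishina cross-section per electron (cm^2).

    Closed form for unpolarized photons on free electrons at rest; valid at
    all energies, used here for the 10-300 keV range.
    """
    e = np.asarray(energy_kev, dtype=float)
    if np.any(e <= 0):
        raise ValueError("energy must be positive")
    a = e / ELECTRON_REST_KEV
    t = 1.0 + 2.0 * a
    log_t = np.log(t)
    term1 = (1.0 + a) / a**2 * (2.0 * (1.0 + a) / t - log_t / a)
    term2 = log_t / (2.0 * a)
    term3 = -(1.0 + 3.0 * a) / t**2
    sigma = 2.0 * np.pi * CLASSICAL_ELECTRON_RADIUS_CM**2 * (term1 + term2 + term3)
    return sigma if sigma.shape else float(sigma)


def incoherent_mu_over_rho(material: int, energy_kev):
    """Incoherent (Compton) mass attenuation coefficient, cm^2/g."""
    return AVOGADRO * Z_OVER_A[material] * np.asarray(kn_cross_section(energy_kev))


def compton_scattered_energy(energy_kev, cos_theta):
    """Photon energy after Compton scattering through angle theta (keV)."""
    e = np.asarray(energy_kev, dtype=float)
    return e / (1.0 + (e / ELECTRON_REST_KEV) * (1.0 - np.asarray(cos_theta)))


def _loglog_resample(x_src, y_src, x_dst):
    return np.exp(np.interp(np.log(x_dst), np.log(x_src), np.log(y_src)))


@dataclass(frozen=True)
class PhysicsTables:
    """Per-material mass attenuation coefficients on a common energy grid.

    Channels are ``photoelectric``, ``incoherent`` and their sum ``total``;
    arrays are shaped (n_materials, n_energies) with the material axis
    indexed by the module constants :data:`AIR` and :data:`WATER`.
    """

    energies: np.ndarray
    photoelectric: np.ndarray
    incoherent: np.ndarray
    emission_energy: float = EMISSION_ENERGY_KEV

    def __post_init__(self):
        if self.photoelectric.shape != self.incoherent.shape:
            raise ValueError("channel tables must share one shape")
        if self.photoelectric.shape[1] != self.energies.size:
            raise ValueError("table width must match the energy grid")
        if np.any(self.photoelectric < 0) or np.any(self.incoherent < 0):
            raise ValueError("mass attenuation coefficients must be >= 0")

    @property
    def total(self) -> np.ndarray:
        return self.photoelectric + self.incoherent

    @classmethod
    def default(cls, spacing_kev: float = 10.0, max_kev: float = 300.0) -> "PhysicsTables":
        """Tables for air and water on a uniform grid (default 10-keV spacing)."""
        energies = np.arange(10.0, max_kev + 0.5 * spacing_kev, spacing_kev)
        pe = np.vstack(
            [_loglog_resample(_PE_ENERGIES, _PE_TABLE[mat], energies) for mat in (AIR, WATER)]
        )
        inc = np.vstack(
            [incoherent_mu_over_rho(mat, energies) for mat in (AIR, WATER)]
        )
        return cls(energies=energies, photoelectric=pe, incoherent=inc)

    def mu_over_rho(self, material: int, energy_kev, channel: str = "total"):
        """Log-log interpolated mass attenuation coefficient (cm^2/g)."""
        table = {
            "total": self.total,
            "photoelectric": self.photoelectric,
            "incoherent": self.incoherent,
        }[channel]
        e = np.clip(np.asarray(energy_kev, dtype=float),
                    self.energies[0], self.energies[-1])
        out = _loglog_resample(self.energies, table[material], e)
        return out if out.shape else float(out)

    def mu_linear(self, material: int, energy_kev, density_g_cm3):
        """Linear attenuation coefficient in 1/mm."""
        return self.mu_over_rho(material, energy_kev) * np.asarray(density_g_cm3) / 10.0

    def kernel_arrays(self):
        """(log-energy grid, log photoelectric, log incoherent) for the jit kernels."""
        tiny = 1e-300
        return (
            np.log(self.energies),
            np.log(np.maximum(self.photoelectric, tiny)),
            np.log(np.maximum(self.incoherent, tiny)),
        )


def water_mu_linear(energy_kev: float, tables: PhysicsTables | None = None) -> float:
    """Linear attenuation coefficient of unit-density water (1/mm)."""
    tables = tables or PhysicsTables.default()
    return float(tables.mu_linear(WATER, energy_kev, 1.0))
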