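"""Material bookkeeping: densities and photon interaction coefficients.

Each material carries a density and, per photon energy, the mass
attenuation coefficient mu/rho and the mass energy-absorption coefficient
mu_en/rho, split into partial channels (photoelectric, incoherent, pair
production) so the transport code can sample interaction types.

Coefficients are generated from a compact physical model rather than a
bulky embedded table:

* incoherent (Compton) scattering from the free-electron Klein--Nishina
  cross section, integrated numerically per grid energy (total and
  energy-transfer moments);
* photoelectric absorption as a per-family power law ``tau0 * (E0/E)**p``
  calibrated to standard reference coefficients at 15 keV;
* pair production above 1.022 MeV as a Z^2/A-scaled threshold form
  calibrated to the 10 MeV water coefficient.

Coherent (Rayleigh) scattering is deliberately excluded everywhere, both
from path sampling and from the tabulated mu/rho.  Four coefficient
families are provided (water-like soft tissue, cortical-bone-like, air,
lung tissue = soft family); soft tissues differ only by density, which is
the first-order quantity for broad-beam organ dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# classical electron radius squared times 2*pi, in cm^2
_TWO_PI_RE2 = 2.0 * np.pi * (2.8179403262e-13) ** 2
_AVOGADRO = 6.02214076e23
_ELECTRON_REST_MEV = 0.51099895

# Default tabulation grid: log-spaced, wider than the supported beam range
# [0.01, 20] MeV because Compton down-scatter reaches the 2 keV cutoff.
DEFAULT_ENERGY_GRID = np.geomspace(0.002, 20.0, 96)

MEV_PER_G_TO_PGY = 1.602176634e-10 * 1e12  # 1 MeV/g in pGy


def klein_nishina_moments(energy_mev: np.ndarray, n_theta: int = 2000):
    """Total and energy-transfer Klein--Nishina cross sections per electron.

    Integrates the free-electron differential cross section over scattering
    angle on a fine cos(theta) grid.  Returns ``(sigma, sigma_tr)`` in cm^2:
    ``sigma`` is the total incoherent cross section, ``sigma_tr`` weights
    each scatter by the fraction of energy transferred to the electron.
    """
    e = np.atleast_1d(np.asarray(energy_mev, dtype=float))
    k = e / _ELECTRON_REST_MEV
    mu = np.linspace(-1.0, 1.0, n_theta)[None, :]  # cos(theta)
    kk = k[:, None]
    ratio = 1.0 / (1.0 + kk * (1.0 - mu))  # E'/E
    dsigma = 0.5 * _TWO_PI_RE2 * ratio**2 * (ratio + 1.0 / ratio - (1.0 - mu**2))
    sigma = np.trapezoid(dsigma, mu[0], axis=1)
    sigma_tr = np.trapezoid(dsigma * (1.0 - ratio), mu[0], axis=1)
    return sigma, sigma_tr


@dataclass(frozen=True)
class CoefficientFamily:
    """Composition-level parameters shared by materials of one tissue class."""

    name: str
    z_over_a: float          # electrons per atomic mass unit, mol e-/g
    z2_over_a: float         # sum of w_i * Z_i^2 / A_i, drives pair production
    photo_tau_15kev: float   # photoelectric mu/rho at 15 keV, cm^2/g
    photo_exponent: float    # power-law exponent in energy

    def coefficients(self, energy_grid: np.ndarray):
        """Return (mu_rho, mu_en_rho, photo, incoh, pair) on the grid, cm^2/g."""
        e = np.asarray(energy_grid, dtype=float)
        sigma, sigma_tr = klein_nishina_moments(e)
        incoh = self.z_over_a * _AVOGADRO * sigma
        incoh_tr = self.z_over_a * _AVOGADRO * sigma_tr
        photo = self.photo_tau_15kev * (0.015 / e) ** self.photo_exponent
        k = e / _ELECTRON_REST_MEV
        pair = np.zeros_like(e)
        above = k > 2.0
        # threshold form calibrated to water at 10 MeV
        pair[above] = (
            _PAIR_CONSTANT * self.z2_over_a * ((k[above] - 2.0) / k[above]) ** 3 * np.log(k[above])
        )
        pair_tr = np.where(e > 0, pair * np.clip((e - 2.0 * _ELECTRON_REST_MEV) / e, 0.0, 1.0), 0.0)
        mu_rho = photo + incoh + pair
        mu_en_rho = photo + incoh_tr + pair_tr
        return mu_rho, mu_en_rho, photo, incoh, pair


_PAIR_CONSTANT = 6.45e-4  # cm^2/g per unit Z^2/A at G(k)=1; water 10 MeV anchor

# Families: Z/A and Z^2/A from standard elemental compositions; photoelectric
# amplitudes calibrated to reference mu/rho at 15 keV with the coherent part
# removed.
SOFT_FAMILY = CoefficientFamily("soft", z_over_a=0.5551, z2_over_a=3.663,
                                photo_tau_15kev=1.365, photo_exponent=3.28)
BONE_FAMILY = CoefficientFamily("bone", z_over_a=0.5148, z2_over_a=5.42,
                                photo_tau_15kev=8.40, photo_exponent=3.10)
AIR_FAMILY = CoefficientFamily("air", z_over_a=0.4992, z2_over_a=3.674,
                               photo_tau_15kev=1.325, photo_exponent=3.30)

# Densities in g/cm^3.  Lung tissue and blood follow the reference lung
# inventory (compressed lung 0.382, blood 1.06); other soft tissues use
# standard ICRP-style values; the residual-tissue density 1.03 is a
# documented assumption.
LUNG_TISSUE_DENSITY = 0.382
BLOOD_DENSITY = 1.06
RESIDUAL_DENSITY = 1.03


@dataclass
class Material:
    material_id: int
    name: str
    density: float
    family: CoefficientFamily


@dataclass
class MaterialTable:
    """Per-material density plus energy-indexed interaction coefficients.

    ``mu_rho`` etc. are arrays of shape ``(n_materials, n_energies)`` indexed
    by material ID; the energy grid is shared and strictly increasing.
    """

    energy_grid: np.ndarray
    materials: dict[int, Material]
    mu_rho: np.ndarray = field(repr=False, default=None)
    mu_en_rho: np.ndarray = field(repr=False, default=None)
    photo: np.ndarray = field(repr=False, default=None)
    incoh: np.ndarray = field(repr=False, default=None)
    pair: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        self.energy_grid = np.asarray(self.energy_grid, dtype=float)
        if np.any(np.diff(self.energy_grid) <= 0):
            raise ValueError("energy grid must be strictly increasing")
        n_mat = max(self.materials) + 1
        n_e = self.energy_grid.size
        if self.mu_rho is None:
            self.mu_rho = np.zeros((n_mat, n_e))
            self.mu_en_rho = np.zeros((n_mat, n_e))
            self.photo = np.zeros((n_mat, n_e))
            self.incoh = np.zeros((n_mat, n_e))
            self.pair = np.zeros((n_mat, n_e))
            for mid, mat in self.materials.items():
                if mat.density <= 0:
                    raise ValueError(f"material {mid} ({mat.name}): density must be positive")
                mu, muen, ph, inc, pr = mat.family.coefficients(self.energy_grid)
                self.mu_rho[mid] = mu
                self.mu_en_rho[mid] = muen
                self.photo[mid] = ph
                self.incoh[mid] = inc
                self.pair[mid] = pr

    @property
    def densities(self) -> np.ndarray:
        out = np.zeros(self.mu_rho.shape[0])
        for mid, mat in self.materials.items():
            out[mid] = mat.density
        return out

    def density_of(self, material_id: int) -> float:
        return self.materials[material_id].density


def lookup_mu(materials: MaterialTable, material_id: int, energy_mev: float):
    """Interpolate (mu/rho, mu_en/rho) at ``energy_mev`` for one material.

    Log-log linear interpolation on the shared grid; exact at grid points.
    Energies outside the tabulated range are an error, not an extrapolation.
    """
    grid = materials.energy_grid
    if not (grid[0] <= energy_mev <= grid[-1]):
        raise ValueError(
            f"energy {energy_mev} MeV outside tabulated range "
            f"[{grid[0]}, {grid[-1]}] MeV"
        )
    if material_id not in materials.materials:
        raise KeyError(f"unknown material ID {material_id}")
    loge = np.log(energy_mev)
    lg = np.log(grid)
    mu = np.exp(np.interp(loge, lg, np.log(materials.mu_rho[material_id])))
    muen = np.exp(np.interp(loge, lg, np.log(materials.mu_en_rho[material_id])))
    return mu, muen


# --- default material inventory -------------------------------------------

AIR, SKIN, MUSCLE, RESIDUAL, BONE, HEART_TISSUE, LIVER_TISSUE, LUNG_TISSUE, BLOOD = range(9)


def default_materials(energy_grid: np.ndarray | None = None) -> MaterialTable:
    """The standard material inventory used by the template phantom."""
    grid = DEFAULT_ENERGY_GRID if energy_grid is None else energy_grid
    mats = {
        AIR: Material(AIR, "air", 1.205e-3, AIR_FAMILY),
        SKIN: Material(SKIN, "skin", 1.09, SOFT_FAMILY),
        MUSCLE: Material(MUSCLE, "muscle", 1.05, SOFT_FAMILY),
        RESIDUAL: Material(RESIDUAL, "residual tissue", RESIDUAL_DENSITY, SOFT_FAMILY),
        BONE: Material(BONE, "bone", 1.40, BONE_FAMILY),
        HEART_TISSUE: Material(HEART_TISSUE, "heart", 1.05, SOFT_FAMILY),
        LIVER_TISSUE: Material(LIVER_TISSUE, "liver", 1.06, SOFT_FAMILY),
        LUNG_TISSUE: Material(LUNG_TISSUE, "lung tissue", LUNG_TISSUE_DENSITY, SOFT_FAMILY),
        BLOOD: Material(BLOOD, "blood", BLOOD_DENSITY, SOFT_FAMILY),
    }
    return MaterialTable(energy_grid=grid, materials=mats)
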