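"""Broad parallel-beam photon Monte Carlo with track-length kerma scoring.

Analog photon transport on the labeled voxel grid: free paths are sampled
from the local linear attenuation (coherent scattering excluded), photons
are ray-traced voxel-by-voxel, and collision kerma is scored with the
track-length estimator ``w * E * (mu_en/rho) * rho * l`` summed per organ
label — the kerma approximation at every energy, i.e. secondary electrons
deposit on the spot.  Interactions: photoelectric absorption (history
ends), incoherent scattering with free-electron Klein--Nishina sampling
(Kahn's rejection method), and pair production above 1.022 MeV (the
history ends and two back-to-back 0.511 MeV annihilation photons with an
isotropic axis are emitted).  Photons below 2 keV deposit locally.

Organ dose per fluence (the LADF for the lung) is reported in pGy cm^2:
``D/Phi`` with ``Phi = N_h / A`` for the parallel and rotational beams
(A = irradiated source-plane area) and ``Phi = N_h / (pi R^2)`` for the
isotropic field (R = bounding-sphere radius of the grid plus margin).

All randomness is consumed in a fixed documented order from one seeded
generator, so a (phantom, beam, seed) triple reproduces bit-identical
results.  Statistical errors come from 25 equal history batches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import grid as g
from .materials import MEV_PER_G_TO_PGY, MaterialTable

GEOMETRIES = ("AP", "PA", "LLAT", "RLAT", "ROT", "ISO")
_GEO_CODE = {name: i for i, name in enumerate(GEOMETRIES)}

ENERGY_CUTOFF_MEV = 0.002
N_BATCHES = 25

# The photon energy grid of the reference broad-beam tables, MeV.
TABLE_ENERGIES = (0.015, 0.02, 0.03, 0.04, 0.05, 0.06, 0.08, 0.1, 0.15, 0.2,
                  0.3, 0.4, 0.5, 0.6, 0.8, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0, 6.0,
                  8.0, 10.0)


@dataclass
class BeamConfig:
    """One irradiation: geometry, mono-energy, histories, seed, margin."""

    geometry: str = "AP"
    energy_mev: float = 1.0
    histories: int = 100_000
    seed: int = 0
    margin_cm: float = 5.0

    def __post_init__(self):
        if self.geometry not in GEOMETRIES:
            raise ValueError(f"geometry must be one of {GEOMETRIES}, got {self.geometry!r}")
        if not (0.01 <= self.energy_mev <= 20.0):
            raise ValueError(f"photon energy must lie in [0.01, 20] MeV, got {self.energy_mev}")
        if self.histories < 1:
            raise ValueError("history count must be >= 1")
        if self.margin_cm < 0:
            raise ValueError("beam margin must be non-negative")


@dataclass
class DoseResult:
    """Per-organ kerma scores and dose-per-fluence for one beam."""

    energy_mev: float
    geometry: str
    histories: int
    beam_area_cm2: float               # fluence normalization: Phi = N_h / A
    label_edep_mev: np.ndarray         # (n_labels,) deposited energy, MeV
    label_batch_mev: np.ndarray        # (n_labels, N_BATCHES)
    label_mass_g: np.ndarray           # (n_labels,)
    total_edep_mev: float
    lung_labels: frozenset = g.LUNG_LABELS
    edep_map_mev: np.ndarray | None = field(default=None, repr=False)
    first_flight_cm: np.ndarray | None = field(default=None, repr=False)

    def organ_edep_per_history(self, organ_ids) -> float:
        return float(sum(self.label_edep_mev[i] for i in organ_ids)) / self.histories

    def organ_mass(self, organ_ids) -> float:
        return float(sum(self.label_mass_g[i] for i in organ_ids))

    def dose_per_fluence(self, organ_ids) -> float:
        """Organ absorbed dose per unit incident fluence, pGy cm^2."""
        mass = self.organ_mass(organ_ids)
        if mass <= 0:
            raise ValueError(f"organ set {sorted(organ_ids)} has zero mass")
        edep = sum(self.label_edep_mev[i] for i in organ_ids)
        dose = edep / mass * MEV_PER_G_TO_PGY        # pGy summed over histories
        return float(dose * self.beam_area_cm2 / self.histories)

    def relative_error(self, organ_ids) -> float:
        """Relative MC standard error of the organ dose (batch statistics)."""
        batches = sum(self.label_batch_mev[i] for i in organ_ids)
        mean = batches.mean()
        if mean == 0:
            return np.inf
        se = batches.std(ddof=1) / np.sqrt(batches.size)
        return float(se / mean)

    @property
    def lung_ladf(self) -> float:
        return self.dose_per_fluence(self.lung_labels)

    @property
    def lung_rel_err(self) -> float:
        return self.relative_error(self.lung_labels)


# --------------------------------------------------------------------------
# numba kernel
# --------------------------------------------------------------------------

@njit(cache=False)
def _kahn_compton(k):
    """Sample x = E/E' from the Klein--Nishina distribution (Kahn).

    Consumes uniforms in triplets (branch, invert, accept) until accepted.
    """
    while True:
        r1 = np.random.random()
        r2 = np.random.random()
        r3 = np.random.random()
        if r1 <= (2.0 * k + 1.0) / (2.0 * k + 9.0):
            x = 1.0 + 2.0 * k * r2
            if r3 <= 4.0 * (x - 1.0) / (x * x):
                return x
        else:
            x = (1.0 + 2.0 * k) / (1.0 + 2.0 * k * r2)
            cost = 1.0 - (x - 1.0) / k
            if r3 <= 0.5 * (cost * cost + 1.0 / x):
                return x


@njit(cache=False)
def _rotate(ux, uy, uz, cost, phi):
    """Rotate a unit vector by polar angle (cost) about itself, azimuth phi."""
    sint = np.sqrt(max(0.0, 1.0 - cost * cost))
    cosp = np.cos(phi)
    sinp = np.sin(phi)
    if abs(uz) < 0.99999:
        denom = np.sqrt(1.0 - uz * uz)
        vx = ux * uz / denom
        vy = uy * uz / denom
        vz = -denom
        wx = -uy / denom
        wy = ux / denom
        wz = 0.0
    else:
        vx, vy, vz = 1.0, 0.0, 0.0
        wx, wy, wz = 0.0, 1.0, 0.0
    nx = cost * ux + sint * (cosp * vx + sinp * wx)
    ny = cost * uy + sint * (cosp * vy + sinp * wy)
    nz = cost * uz + sint * (cosp * vz + sinp * wz)
    norm = np.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=False)
def _interp_tables(e, log_grid, log_mu, log_muen, f_photo, f_pair, rho,
                   mu_lin, muen_lin, fph, fpr):
    x = np.log(e)
    n = log_grid.size
    j = np.searchsorted(log_grid, x) - 1
    if j < 0:
        j = 0
    if j > n - 2:
        j = n - 2
    f = (x - log_grid[j]) / (log_grid[j + 1] - log_grid[j])
    for m in range(rho.size):
        mu = np.exp(log_mu[m, j] * (1.0 - f) + log_mu[m, j + 1] * f)
        muen = np.exp(log_muen[m, j] * (1.0 - f) + log_muen[m, j + 1] * f)
        mu_lin[m] = mu * rho[m]
        muen_lin[m] = muen * rho[m]
        fph[m] = f_photo[m, j] * (1.0 - f) + f_photo[m, j + 1] * f
        fpr[m] = f_pair[m, j] * (1.0 - f) + f_pair[m, j + 1] * f


@njit(cache=False)
def _run_kernel(labels, mat_of_label, rho, log_grid, log_mu, log_muen,
                f_photo, f_pair, extent, spacing, geo_code, e0, n_hist,
                seed, margin, score_map, edep_map, edep_batch, n_ff, ff_out):
    np.random.seed(seed)
    nx, ny, nz = labels.shape
    ex, ey, ez = extent
    dx, dy, dz = spacing[0], spacing[1], spacing[2]
    n_mat = rho.size
    mu_lin = np.zeros(n_mat)
    muen_lin = np.zeros(n_mat)
    fph = np.zeros(n_mat)
    fpr = np.zeros(n_mat)
    total_edep = 0.0

    cx, cy, cz = 0.5 * ex, 0.5 * ey, 0.5 * ez
    r_rot = np.sqrt(cx * cx + cy * cy) + margin
    r_iso = np.sqrt(cx * cx + cy * cy + cz * cz) + margin

    # small stack for annihilation photons: (x, y, z, ux, uy, uz, E)
    stack = np.zeros((8, 7))

    for hist in range(n_hist):
        ibatch = hist * N_BATCHES // n_hist
        # --- primary sampling, per geometry ---
        if geo_code == 0:    # AP: +y
            px = -margin + np.random.random() * (ex + 2.0 * margin)
            pz = -margin + np.random.random() * (ez + 2.0 * margin)
            py = -1.0
            ux, uy, uz = 0.0, 1.0, 0.0
        elif geo_code == 1:  # PA: -y
            px = -margin + np.random.random() * (ex + 2.0 * margin)
            pz = -margin + np.random.random() * (ez + 2.0 * margin)
            py = ey + 1.0
            ux, uy, uz = 0.0, -1.0, 0.0
        elif geo_code == 2:  # LLAT: -x from the left face (x large)
            py = -margin + np.random.random() * (ey + 2.0 * margin)
            pz = -margin + np.random.random() * (ez + 2.0 * margin)
            px = ex + 1.0
            ux, uy, uz = -1.0, 0.0, 0.0
        elif geo_code == 3:  # RLAT: +x
            py = -margin + np.random.random() * (ey + 2.0 * margin)
            pz = -margin + np.random.random() * (ez + 2.0 * margin)
            px = -1.0
            ux, uy, uz = 1.0, 0.0, 0.0
        elif geo_code == 4:  # ROT: parallel beam, uniform azimuth, normal to z
            phi = 2.0 * np.pi * np.random.random()
            ax0 = np.cos(phi)
            ay0 = np.sin(phi)
            ux, uy, uz = -ax0, -ay0, 0.0
            off = (2.0 * np.random.random() - 1.0) * r_rot
            px = cx + ax0 * (r_rot + 1.0) - ay0 * off
            py = cy + ay0 * (r_rot + 1.0) + ax0 * off
            pz = -margin + np.random.random() * (ez + 2.0 * margin)
        else:                # ISO: uniform directions, offsets on the disc
            cost = 2.0 * np.random.random() - 1.0
            phi = 2.0 * np.pi * np.random.random()
            sint = np.sqrt(max(0.0, 1.0 - cost * cost))
            ux = sint * np.cos(phi)
            uy = sint * np.sin(phi)
            uz = cost
            # orthonormal basis perpendicular to the direction
            if abs(uz) < 0.99999:
                den = np.sqrt(1.0 - uz * uz)
                e1x, e1y, e1z = ux * uz / den, uy * uz / den, -den
                e2x, e2y, e2z = -uy / den, ux / den, 0.0
            else:
                e1x, e1y, e1z = 1.0, 0.0, 0.0
                e2x, e2y, e2z = 0.0, 1.0, 0.0
            rr = r_iso * np.sqrt(np.random.random())
            aphi = 2.0 * np.pi * np.random.random()
            oa = rr * np.cos(aphi)
            ob = rr * np.sin(aphi)
            px = cx - ux * 2.0 * r_iso + e1x * oa + e2x * ob
            py = cy - uy * 2.0 * r_iso + e1y * oa + e2y * ob
            pz = cz - uz * 2.0 * r_iso + e1z * oa + e2z * ob

        n_stack = 0
        e = e0
        w = 1.0
        alive = True
        first_flight = True
        while True:
            if not alive:
                if n_stack > 0:
                    n_stack -= 1
                    px = stack[n_stack, 0]
                    py = stack[n_stack, 1]
                    pz = stack[n_stack, 2]
                    ux = stack[n_stack, 3]
                    uy = stack[n_stack, 4]
                    uz = stack[n_stack, 5]
                    e = stack[n_stack, 6]
                    alive = True
                else:
                    break
            _interp_tables(e, log_grid, log_mu, log_muen, f_photo, f_pair,
                           rho, mu_lin, muen_lin, fph, fpr)
            # ray-box entry (slab method)
            t0 = 0.0
            t1 = 1e30
            inside = True
            for a in range(3):
                if a == 0:
                    p, u, hi = px, ux, ex
                elif a == 1:
                    p, u, hi = py, uy, ey
                else:
                    p, u, hi = pz, uz, ez
                if abs(u) < 1e-12:
                    if p < 0.0 or p > hi:
                        inside = False
                        break
                else:
                    ta = (0.0 - p) / u
                    tb = (hi - p) / u
                    if ta > tb:
                        ta, tb = tb, ta
                    if ta > t0:
                        t0 = ta
                    if tb < t1:
                        t1 = tb
            if (not inside) or t1 <= t0:
                alive = False
                continue
            if t0 > 0.0:
                px += (t0 + 1e-9) * ux
                py += (t0 + 1e-9) * uy
                pz += (t0 + 1e-9) * uz
            # voxel traversal (Amanatides--Woo) until the optical depth runs out
            tau = -np.log(np.random.random() + 1e-300)
            ix = int(px / dx)
            iy = int(py / dy)
            iz = int(pz / dz)
            if ix < 0: ix = 0
            if iy < 0: iy = 0
            if iz < 0: iz = 0
            if ix > nx - 1: ix = nx - 1
            if iy > ny - 1: iy = ny - 1
            if iz > nz - 1: iz = nz - 1
            step_x = 1 if ux > 0 else -1
            step_y = 1 if uy > 0 else -1
            step_z = 1 if uz > 0 else -1
            big = 1e30
            if abs(ux) > 1e-12:
                t_max_x = (((ix + (1 if ux > 0 else 0)) * dx) - px) / ux
                t_dx = dx / abs(ux)
            else:
                t_max_x = big
                t_dx = big
            if abs(uy) > 1e-12:
                t_max_y = (((iy + (1 if uy > 0 else 0)) * dy) - py) / uy
                t_dy = dy / abs(uy)
            else:
                t_max_y = big
                t_dy = big
            if abs(uz) > 1e-12:
                t_max_z = (((iz + (1 if uz > 0 else 0)) * dz) - pz) / uz
                t_dz = dz / abs(uz)
            else:
                t_max_z = big
                t_dz = big
            t_cur = 0.0
            collided = False
            cix, ciy, ciz = ix, iy, iz
            while True:
                lab = labels[ix, iy, iz]
                m = mat_of_label[lab]
                mu = mu_lin[m]
                if t_max_x < t_max_y:
                    if t_max_x < t_max_z:
                        t_next = t_max_x
                        axis = 0
                    else:
                        t_next = t_max_z
                        axis = 2
                else:
                    if t_max_y < t_max_z:
                        t_next = t_max_y
                        axis = 1
                    else:
                        t_next = t_max_z
                        axis = 2
                seg = t_next - t_cur
                if seg < 0.0:
                    seg = 0.0
                if mu * seg >= tau:
                    # collision inside this voxel
                    ell = tau / mu if mu > 0.0 else seg
                    c = w * e * muen_lin[m] * ell
                    edep_batch[lab, ibatch] += c
                    total_edep += c
                    if score_map:
                        edep_map[ix, iy, iz] += c
                    t_cur += ell
                    collided = True
                    cix, ciy, ciz = ix, iy, iz
                    break
                # full segment in this voxel
                c = w * e * muen_lin[m] * seg
                edep_batch[lab, ibatch] += c
                total_edep += c
                if score_map:
                    edep_map[ix, iy, iz] += c
                tau -= mu * seg
                t_cur = t_next
                if axis == 0:
                    ix += step_x
                    t_max_x += t_dx
                    if ix < 0 or ix >= nx:
                        break
                elif axis == 1:
                    iy += step_y
                    t_max_y += t_dy
                    if iy < 0 or iy >= ny:
                        break
                else:
                    iz += step_z
                    t_max_z += t_dz
                    if iz < 0 or iz >= nz:
                        break
            if first_flight and hist < n_ff:
                if collided:
                    ff_out[hist] = t_cur
                else:
                    ff_out[hist] = np.inf
            first_flight = False
            if not collided:
                alive = False
                continue
            px += t_cur * ux
            py += t_cur * uy
            pz += t_cur * uz
            # interaction sampling at the collision voxel's material
            lab = labels[cix, ciy, ciz]
            m = mat_of_label[lab]
            r = np.random.random()
            if r < fph[m]:
                alive = False            # photoelectric absorption
            elif r < fph[m] + fpr[m] and e > 1.022:
                # pair production: back-to-back annihilation photons
                cost = 2.0 * np.random.random() - 1.0
                phi = 2.0 * np.pi * np.random.random()
                sint = np.sqrt(max(0.0, 1.0 - cost * cost))
                axx = sint * np.cos(phi)
                axy = sint * np.sin(phi)
                axz = cost
                if n_stack < stack.shape[0]:
                    stack[n_stack, 0] = px
                    stack[n_stack, 1] = py
                    stack[n_stack, 2] = pz
                    stack[n_stack, 3] = -axx
                    stack[n_stack, 4] = -axy
                    stack[n_stack, 5] = -axz
                    stack[n_stack, 6] = 0.51099895
                    n_stack += 1
                ux, uy, uz = axx, axy, axz
                e = 0.51099895
            else:
                # incoherent scattering, Kahn sampling
                k = e / 0.51099895
                x = _kahn_compton(k)
                cost = 1.0 - (x - 1.0) / k
                phi = 2.0 * np.pi * np.random.random()
                ux, uy, uz = _rotate(ux, uy, uz, cost, phi)
                e = e / x
                if e < ENERGY_CUTOFF_MEV:
                    # terminate with local deposit
                    c = w * e
                    edep_batch[lab, ibatch] += c
                    total_edep += c
                    if score_map:
                        edep_map[cix, ciy, ciz] += c
                    alive = False
    return total_edep


# --------------------------------------------------------------------------
# python-side API
# --------------------------------------------------------------------------

def sample_primary(beam: BeamConfig, bounding_box, rng: np.random.Generator):
    """Sample one (position, direction) pair for a beam, for diagnostics.

    ``bounding_box`` is ((x0, y0, z0), (x1, y1, z1)) in cm.  Mirrors the
    kernel's source model; positions are absolute cm.
    """
    (x0, y0, z0), (x1, y1, z1) = bounding_box
    ex, ey, ez = x1 - x0, y1 - y0, z1 - z0
    m = beam.margin_cm
    geo = beam.geometry
    if geo in ("AP", "PA"):
        px = x0 - m + rng.random() * (ex + 2 * m)
        pz = z0 - m + rng.random() * (ez + 2 * m)
        if geo == "AP":
            return np.array([px, y0 - 1.0, pz]), np.array([0.0, 1.0, 0.0])
        return np.array([px, y1 + 1.0, pz]), np.array([0.0, -1.0, 0.0])
    if geo in ("LLAT", "RLAT"):
        py = y0 - m + rng.random() * (ey + 2 * m)
        pz = z0 - m + rng.random() * (ez + 2 * m)
        if geo == "LLAT":
            return np.array([x1 + 1.0, py, pz]), np.array([-1.0, 0.0, 0.0])
        return np.array([x0 - 1.0, py, pz]), np.array([1.0, 0.0, 0.0])
    cx, cy, cz = x0 + ex / 2, y0 + ey / 2, z0 + ez / 2
    if geo == "ROT":
        r_rot = np.hypot(ex / 2, ey / 2) + m
        phi = 2 * np.pi * rng.random()
        a = np.array([np.cos(phi), np.sin(phi), 0.0])
        v = np.array([-a[1], a[0], 0.0])
        off = (2 * rng.random() - 1) * r_rot
        pz = z0 - m + rng.random() * (ez + 2 * m)
        pos = np.array([cx, cy, 0.0]) + a * (r_rot + 1.0) + v * off
        pos[2] = pz
        return pos, -a
    # ISO
    r_iso = np.sqrt((ex / 2) ** 2 + (ey / 2) ** 2 + (ez / 2) ** 2) + m
    cost = 2 * rng.random() - 1
    phi = 2 * np.pi * rng.random()
    sint = np.sqrt(1 - cost**2)
    d = np.array([sint * np.cos(phi), sint * np.sin(phi), cost])
    e1 = np.cross(d, [0.0, 0.0, 1.0])
    if np.linalg.norm(e1) < 1e-9:
        e1 = np.array([1.0, 0.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    rr = r_iso * np.sqrt(rng.random())
    aphi = 2 * np.pi * rng.random()
    pos = (np.array([cx, cy, cz]) - d * 2 * r_iso
           + e1 * rr * np.cos(aphi) + e2 * rr * np.sin(aphi))
    return pos, d


def beam_area_cm2(beam: BeamConfig, phantom: g.LabeledVolume) -> float:
    """Source-plane area defining the fluence normalization Phi = N_h / A."""
    ex = phantom.shape[0] * phantom.spacing[0]
    ey = phantom.shape[1] * phantom.spacing[1]
    ez = phantom.shape[2] * phantom.spacing[2]
    m = beam.margin_cm
    if beam.geometry in ("AP", "PA"):
        return (ex + 2 * m) * (ez + 2 * m)
    if beam.geometry in ("LLAT", "RLAT"):
        return (ey + 2 * m) * (ez + 2 * m)
    if beam.geometry == "ROT":
        r = np.hypot(ex / 2, ey / 2) + m
        return 2 * r * (ez + 2 * m)
    r = np.sqrt((ex / 2) ** 2 + (ey / 2) ** 2 + (ez / 2) ** 2) + m
    return np.pi * r**2


def transport(phantom: g.LabeledVolume, materials: MaterialTable,
              beam: BeamConfig, score_map: bool = False,
              record_first_flight: int = 0) -> DoseResult:
    """Run the photon transport for one beam and score per-organ kerma."""
    n_labels = int(phantom.labels.max()) + 1
    mat_of_label = np.zeros(n_labels, dtype=np.uint8)
    for lab, (_, mid) in phantom.organ_map.items():
        if lab < n_labels:
            if mid not in materials.materials:
                raise KeyError(f"label {lab} bound to unknown material {mid}")
            mat_of_label[lab] = mid
    lung_mass = sum(
        g.mass_of(phantom, {lab}, materials)
        for lab in g.LUNG_LABELS if lab in phantom.organ_map
    )
    if lung_mass <= 0:
        raise ValueError("phantom has zero lung mass; LADF undefined")

    grid_log = np.log(materials.energy_grid)
    with np.errstate(divide="ignore"):
        log_mu = np.log(materials.mu_rho)
        log_muen = np.log(materials.mu_en_rho)
    f_photo = materials.photo / materials.mu_rho
    f_pair = materials.pair / materials.mu_rho

    extent = np.array([phantom.shape[a] * phantom.spacing[a] for a in range(3)])
    edep_batch = np.zeros((n_labels, N_BATCHES))
    edep_map = np.zeros(phantom.shape) if score_map else np.zeros((1, 1, 1))
    n_ff = int(record_first_flight)
    ff = np.full(max(n_ff, 1), np.nan)

    total = _run_kernel(
        phantom.labels, mat_of_label, materials.densities, grid_log,
        log_mu, log_muen, f_photo, f_pair, extent,
        np.asarray(phantom.spacing), _GEO_CODE[beam.geometry],
        float(beam.energy_mev), int(beam.histories), int(beam.seed) & 0x7FFFFFFF,
        float(beam.margin_cm), bool(score_map), edep_map, edep_batch, n_ff, ff,
    )

    label_mass = np.zeros(n_labels)
    vv = phantom.voxel_volume
    counts = np.bincount(phantom.labels.ravel(), minlength=n_labels)
    for lab in range(n_labels):
        if lab == 0:
            mid = 0
        elif lab in phantom.organ_map:
            mid = phantom.organ_map[lab][1]
        else:
            continue
        label_mass[lab] = counts[lab] * vv * materials.density_of(mid)

    return DoseResult(
        energy_mev=beam.energy_mev,
        geometry=beam.geometry,
        histories=beam.histories,
        beam_area_cm2=beam_area_cm2(beam, phantom),
        label_edep_mev=edep_batch.sum(axis=1),
        label_batch_mev=edep_batch,
        label_mass_g=label_mass,
        total_edep_mev=float(total),
        edep_map_mev=edep_map if score_map else None,
        first_flight_cm=ff[:n_ff] if n_ff else None,
    )


def dose_map(result: DoseResult, phantom: g.LabeledVolume,
             materials: MaterialTable, rebin: tuple[int, int, int] = (1, 1, 1)):
    """Percent-of-maximum dose map on the (optionally rebinned) voxel grid.

    Per-voxel dose is deposited energy over voxel mass; the mass-weighted
    sum over the map equals the total deposited energy.  The returned grid
    is normalized to its maximum in percent (all-zero maps stay zero).
    """
    if result.edep_map_mev is None:
        raise ValueError("transport was run without map recording")
    edep = result.edep_map_mev
    mat_of_label = np.zeros(int(phantom.labels.max()) + 1, dtype=int)
    for lab, (_, mid) in phantom.organ_map.items():
        mat_of_label[lab] = mid
    rho = materials.densities[mat_of_label[phantom.labels]]
    mass = rho * phantom.voxel_volume
    if rebin != (1, 1, 1):
        rx, ry, rz = rebin
        shape = edep.shape
        nx, ny, nz = shape[0] // rx, shape[1] // ry, shape[2] // rz
        edep = edep[:nx * rx, :ny * ry, :nz * rz].reshape(nx, rx, ny, ry, nz, rz).sum(axis=(1, 3, 5))
        mass = mass[:nx * rx, :ny * ry, :nz * rz].reshape(nx, rx, ny, ry, nz, rz).sum(axis=(1, 3, 5))
    with np.errstate(invalid="ignore", divide="ignore"):
        dose = np.where(mass > 0, edep / mass, 0.0)
    peak = dose.max()
    if peak <= 0:
        return np.zeros_like(dose)
    return 100.0 * dose / peak
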