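"""Pressure-shift free-energy decomposition.

The stability shift of a solute between a low-pressure state N and a
high-pressure state H is assembled from a thermodynamic cycle in which
solvation does not alter the solute structure:

    dG = dE_conf + ddmu - T dS

* ``dE_conf`` — change in mean solute conformational energy, consumed
  from per-frame energy tables (a minimal vacuum nonbonded evaluator is
  provided for self-contained synthetic fixtures);
* ``ddmu`` — change in solvation free energy, split into a polar part
  (two-dielectric finite-difference Poisson solve with a
  pressure/temperature-dependent water permittivity) and a nonpolar part
  (surface tension x area, with the van der Waals attraction term
  neglected);
* ``dS`` — solute entropy change: ideal-gas translational
  (Sackur-Tetrode) + classical rigid-rotor rotational + quasi-harmonic
  internal entropy from the mass-weighted coordinate covariance, with
  block averaging over contiguous trajectory segments.

Entropies are in kcal/mol/K, energies in kcal/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .constants import (
    AMU_KG,
    ANGSTROM_M,
    AVOGADRO,
    BOLTZMANN_J,
    COULOMB_KCAL,
    HBAR_J,
    KB_KCALMOL,
    PLANCK_J,
    VACUUM_PERMITTIVITY,
)
from .geometry import apply_transform, superpose
from .model_io import EnergyTerms, Structure, Trajectory

__all__ = [
    "EntropyComponents",
    "SolvationTerms",
    "FreeEnergyBreakdown",
    "ATOMIC_MASSES",
    "GAMMA_277K",
    "mean_conformational_energy",
    "delta_with_sd",
    "nonbonded_energy",
    "water_density",
    "water_dielectric",
    "polar_solvation",
    "nonpolar_solvation",
    "translational_entropy",
    "rotational_entropy",
    "principal_moments",
    "quasiharmonic_internal_entropy",
    "entropy_components",
    "block_entropy",
    "free_energy_shift",
    "free_energy_table",
]

# surface tension for the nonpolar solvation term at 277 K
GAMMA_277K = 0.1091  # kcal/mol/Å^2

ATOMIC_MASSES = {  # amu
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "MG": 24.305, "K": 39.098, "CL": 35.45, "NA": 22.990,
    "CA": 40.078, "FE": 55.845,
}


def masses_for(structure: Structure) -> np.ndarray:
    return np.array(
        [ATOMIC_MASSES[a.element.upper()] for a in structure.atoms], dtype=float
    )


# --------------------------------------------------------------------------
# conformational energy
# --------------------------------------------------------------------------


def mean_conformational_energy(
    energies: Sequence[EnergyTerms],
    window: slice | tuple[int, int] | None = None,
) -> tuple[tuple[float, float], tuple[float, float] | None]:
    """Window mean +- population SD of total (and electrostatic) energy."""
    if isinstance(window, tuple):
        window = slice(*window)
    rows = list(energies)[window] if window is not None else list(energies)
    if not rows:
        raise ValueError("empty window")
    tot = np.array([e.total for e in rows], dtype=float)
    out_tot = (float(tot.mean()), float(tot.std()))
    elecs = [e.electrostatic for e in rows]
    if any(e is None for e in elecs):
        return out_tot, None
    ele = np.array(elecs, dtype=float)
    return out_tot, (float(ele.mean()), float(ele.std()))


def delta_with_sd(
    high: tuple[float, float], low: tuple[float, float]
) -> tuple[float, float]:
    """high - low with SDs propagated in quadrature."""
    return high[0] - low[0], math.hypot(high[1], low[1])


def nonbonded_energy(
    coords: np.ndarray,
    charges: np.ndarray,
    lj_params: np.ndarray | None = None,
) -> float:
    """Vacuum Coulomb + 12-6 Lennard-Jones sum over unique pairs, kcal/mol.

    ``lj_params`` is an (N, 2) array of per-atom (epsilon kcal/mol,
    sigma Å), combined by Lorentz-Berthelot rules; ``None`` disables the
    LJ term. A single atom has zero energy.
    """
    coords = np.asarray(coords, dtype=float)
    charges = np.asarray(charges, dtype=float)
    n = coords.shape[0]
    if charges.shape[0] != n:
        raise ValueError("every atom needs a charge")
    if n < 2:
        return 0.0
    iu, ju = np.triu_indices(n, k=1)
    r = np.linalg.norm(coords[iu] - coords[ju], axis=1)
    energy = float(np.sum(COULOMB_KCAL * charges[iu] * charges[ju] / r))
    if lj_params is not None:
        lj = np.asarray(lj_params, dtype=float)
        if lj.shape != (n, 2):
            raise ValueError("lj_params must be (N, 2): epsilon, sigma per atom")
        eps = np.sqrt(lj[iu, 0] * lj[ju, 0])
        sig = 0.5 * (lj[iu, 1] + lj[ju, 1])
        sr6 = (sig / r) ** 6
        energy += float(np.sum(4.0 * eps * (sr6**2 - sr6)))
    return energy


# --------------------------------------------------------------------------
# water permittivity (Kirkwood g-factor continuum input)
# --------------------------------------------------------------------------

# ambient-pressure density vs temperature, g/cm^3 (piecewise-linear)
_RHO0_T = np.array([270.0, 273.15, 277.0, 283.0, 293.0, 298.15, 313.0,
                    333.0, 353.0, 373.0, 380.0])
_RHO0_V = np.array([0.9999, 0.99984, 0.99997, 0.99970, 0.99821, 0.99705,
                    0.99222, 0.98320, 0.97180, 0.95840, 0.95320])

# Tait equation of state constants (isothermal compression)
_TAIT_C = 0.3150
_TAIT_B = 299.6  # MPa

_WATER_MOLAR_MASS = 0.0180153  # kg/mol
_CAL_T, _CAL_P, _CAL_EPS = 298.15, 0.1, 78.4  # calibration point


def water_density(temperature: float, pressure: float) -> float:
    """Liquid-water density (g/cm^3) from a table + Tait compression.

    Valid for 270-380 K and 0 < p <= 200 MPa.
    """
    if not (270.0 <= temperature <= 380.0):
        raise ValueError(f"temperature {temperature} K outside 270-380 K")
    if not (0.0 < pressure <= 200.0):
        raise ValueError(f"pressure {pressure} MPa outside (0, 200] MPa")
    rho0 = float(np.interp(temperature, _RHO0_T, _RHO0_V))
    p0 = 0.1
    shrink = _TAIT_C * math.log10((_TAIT_B + pressure) / (_TAIT_B + p0))
    return rho0 / (1.0 - shrink)


def _kirkwood_eps(number_density: float, temperature: float, a_const: float) -> float:
    """Solve (eps-1)(2eps+1)/(9eps) = G for eps, G = A n / T."""
    g = a_const * number_density / temperature
    b = 1.0 + 9.0 * g
    return (b + math.sqrt(b * b + 8.0)) / 4.0


def _calibration_constant() -> float:
    # choose the dipole-correlation prefactor A = g mu^2 / (9 eps0 kB)
    # so the ambient point reproduces the tabulated permittivity 78.4
    n = (
        water_density(_CAL_T, _CAL_P) * 1.0e3 / _WATER_MOLAR_MASS * AVOGADRO
    )  # m^-3
    eps = _CAL_EPS
    g = (eps - 1.0) * (2.0 * eps + 1.0) / (9.0 * eps)
    return g * _CAL_T / n


_A_CONST = _calibration_constant()


def water_dielectric(temperature: float, pressure: float) -> float:
    """Relative permittivity of liquid water at (T, p).

    Kirkwood dipole-correlation (g-factor) estimate: the correlation
    strength is calibrated at ambient conditions (78.4 at 298.15 K,
    0.1 MPa) and carried to other state points through the water number
    density from a tabulated equation of state. Monotone increasing in
    pressure at fixed T, decreasing in T at fixed p.
    """
    if not (270.0 <= temperature <= 380.0):
        raise ValueError(f"temperature {temperature} K outside 270-380 K")
    rho = water_density(temperature, pressure)  # raises on bad pressure
    n = rho * 1.0e3 / _WATER_MOLAR_MASS * AVOGADRO
    return _kirkwood_eps(n, temperature, _A_CONST)


# --------------------------------------------------------------------------
# polar solvation: finite-difference two-dielectric Poisson solve
# --------------------------------------------------------------------------


class PoissonConvergenceError(RuntimeError):
    def __init__(self, iterations: int, residual: float):
        super().__init__(
            f"Poisson solver not converged after {iterations} iterations "
            f"(relative residual {residual:.2e})"
        )
        self.iterations = iterations


def _trilinear_weights(pos, origin, h, shape):
    """Node indices and weights spreading a point onto its 8 grid nodes."""
    f = (pos - origin) / h
    i0 = np.floor(f).astype(int)
    i0 = np.clip(i0, 0, np.array(shape) - 2)
    t = f - i0
    idx, w = [], []
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                idx.append((i0[0] + dx, i0[1] + dy, i0[2] + dz))
                w.append(
                    (t[0] if dx else 1 - t[0])
                    * (t[1] if dy else 1 - t[1])
                    * (t[2] if dz else 1 - t[2])
                )
    return idx, w


def _solve_fd_poisson(eps_x, eps_y, eps_z, source, boundary, omega,
                      tol=1.0e-6, max_iter=20000):
    """Red-black SOR for div(eps grad phi) = -source on a node grid.

    ``source`` already carries the 4*pi*q/h right-hand side at nodes;
    ``boundary`` fixes the outermost node layer (Dirichlet).
    """
    phi = boundary.copy()
    nx, ny, nz = phi.shape
    ii, jj, kk = np.meshgrid(
        np.arange(1, nx - 1), np.arange(1, ny - 1), np.arange(1, nz - 1),
        indexing="ij",
    )
    red = ((ii + jj + kk) % 2).astype(bool)
    e_e = eps_x[1:, 1:-1, 1:-1]
    e_w = eps_x[:-1, 1:-1, 1:-1]
    e_n = eps_y[1:-1, 1:, 1:-1]
    e_s = eps_y[1:-1, :-1, 1:-1]
    e_u = eps_z[1:-1, 1:-1, 1:]
    e_d = eps_z[1:-1, 1:-1, :-1]
    denom = e_e + e_w + e_n + e_s + e_u + e_d
    src = source[1:-1, 1:-1, 1:-1]
    src_norm = np.linalg.norm(src)
    if src_norm == 0.0:
        return phi
    residual = math.inf
    for it in range(1, max_iter + 1):
        for mask in (red, ~red):
            num = (
                e_e * phi[2:, 1:-1, 1:-1]
                + e_w * phi[:-2, 1:-1, 1:-1]
                + e_n * phi[1:-1, 2:, 1:-1]
                + e_s * phi[1:-1, :-2, 1:-1]
                + e_u * phi[1:-1, 1:-1, 2:]
                + e_d * phi[1:-1, 1:-1, :-2]
                + src
            )
            interior = phi[1:-1, 1:-1, 1:-1]
            interior[mask] = (1.0 - omega) * interior[mask] + omega * (
                num[mask] / denom[mask]
            )
        if it % 20 == 0 or it == max_iter:
            num = (
                e_e * phi[2:, 1:-1, 1:-1]
                + e_w * phi[:-2, 1:-1, 1:-1]
                + e_n * phi[1:-1, 2:, 1:-1]
                + e_s * phi[1:-1, :-2, 1:-1]
                + e_u * phi[1:-1, 1:-1, 2:]
                + e_d * phi[1:-1, 1:-1, :-2]
                + src
            )
            residual = np.linalg.norm(num - denom * phi[1:-1, 1:-1, 1:-1])
            residual /= src_norm
            if residual < tol:
                return phi
    raise PoissonConvergenceError(max_iter, residual)


def _grid_energy(coords, charges, origin, h, phi, shape):
    e = 0.0
    for pos, q in zip(coords, charges):
        if q == 0.0:
            continue
        idx, w = _trilinear_weights(pos, origin, h, shape)
        val = sum(wk * phi[i] for i, wk in zip(idx, w))
        e += 0.5 * q * val
    return e * COULOMB_KCAL


def polar_solvation(
    structure: Structure,
    charges: np.ndarray,
    radii: np.ndarray,
    eps_in: float = 2.0,
    eps_out: float = 80.0,
    grid_spacing: float = 0.4,
    margin: float = 8.0,
    tol: float = 1.0e-6,
) -> float:
    """Polar solvation free energy by two-dielectric Poisson solve, kcal/mol.

    The grid spans the solute plus ``margin`` Å each side. Atomic
    charges are spread trilinearly onto nodes; the dielectric is
    ``eps_in`` at grid faces whose midpoint falls inside any atom sphere
    (``radii``, Å) and ``eps_out`` outside. The reaction-field energy is
    E(eps map) - E(uniform eps_in) on the identical grid, which cancels
    the grid self-energy. Boundary potentials are Coulombic screened by
    the respective exterior dielectric.
    """
    coords = np.asarray(structure.coords, dtype=float)
    charges = np.asarray(charges, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if np.all(charges == 0.0):
        return 0.0
    h = float(grid_spacing)
    lo = coords.min(axis=0) - radii.max() - margin
    hi = coords.max(axis=0) + radii.max() + margin
    shape = tuple(int(np.ceil((hi[d] - lo[d]) / h)) + 1 for d in range(3))
    origin = lo
    axes = [origin[d] + h * np.arange(shape[d]) for d in range(3)]

    # charge spreading
    q_grid = np.zeros(shape)
    for pos, q in zip(coords, charges):
        if q == 0.0:
            continue
        idx, w = _trilinear_weights(pos, origin, h, shape)
        for i, wk in zip(idx, w):
            q_grid[i] += q * wk
    source = 4.0 * math.pi * q_grid / h

    # face dielectric maps (midpoint-in-sphere test)
    def face_eps(axis):
        sh = list(shape)
        sh[axis] -= 1
        pts_axes = []
        for d in range(3):
            ax = axes[d]
            pts_axes.append(ax[:-1] + h / 2 if d == axis else ax)
        gx, gy, gz = np.meshgrid(*pts_axes, indexing="ij")
        inside = np.zeros(tuple(sh), dtype=bool)
        for pos, r in zip(coords, radii):
            d2 = (gx - pos[0]) ** 2 + (gy - pos[1]) ** 2 + (gz - pos[2]) ** 2
            inside |= d2 <= r * r
        return np.where(inside, eps_in, eps_out)

    eps_maps = [face_eps(0), face_eps(1), face_eps(2)]

    # Dirichlet boundary: screened Coulomb from all charges
    def boundary(eps_screen):
        phi = np.zeros(shape)
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        bmask = np.zeros(shape, dtype=bool)
        bmask[0, :, :] = bmask[-1, :, :] = True
        bmask[:, 0, :] = bmask[:, -1, :] = True
        bmask[:, :, 0] = bmask[:, :, -1] = True
        bx, by, bz = gx[bmask], gy[bmask], gz[bmask]
        vals = np.zeros(bx.shape)
        for pos, q in zip(coords, charges):
            if q == 0.0:
                continue
            r = np.sqrt((bx - pos[0]) ** 2 + (by - pos[1]) ** 2 + (bz - pos[2]) ** 2)
            vals += q / (eps_screen * np.maximum(r, h))
        phi[bmask] = vals
        return phi

    n_mean = np.mean(shape)
    omega = 2.0 / (1.0 + math.sin(math.pi / n_mean))

    phi_solv = _solve_fd_poisson(*eps_maps, source, boundary(eps_out), omega, tol)
    uniform = [np.full_like(m, eps_in) for m in eps_maps]
    phi_vac = _solve_fd_poisson(*uniform, source, boundary(eps_in), omega, tol)

    e_solv = _grid_energy(coords, charges, origin, h, phi_solv, shape)
    e_vac = _grid_energy(coords, charges, origin, h, phi_vac, shape)
    return e_solv - e_vac


# --------------------------------------------------------------------------
# nonpolar solvation
# --------------------------------------------------------------------------


@dataclass
class SolvationTerms:
    """Polar + nonpolar solvation free energy, kcal/mol.

    The nonpolar part is gamma x A; the van der Waals attraction term is
    neglected (fixed 0), its contribution being far below the other
    terms.
    """

    polar: float
    nonpolar: float
    gamma: float
    area: float
    vdw_term: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.nonpolar - self.gamma * self.area) > 1.0e-9:
            raise ValueError("nonpolar must equal gamma * area")
        if self.vdw_term != 0.0:
            raise ValueError("vdw_term is neglected and must be 0")

    @property
    def total(self) -> float:
        return self.polar + self.nonpolar


def surface_tension(temperature: float) -> float:
    """Water surface tension gamma(T), kcal/mol/Å^2.

    Anchored at gamma(277 K) = 0.1091 with the tabulated linear
    temperature slope of the air-water interfacial tension
    (about -1.5e-4 kcal/mol/Å^2/K near ambient).
    """
    return GAMMA_277K - 1.5e-4 * (temperature - 277.0)


def nonpolar_solvation(
    area: float, temperature: float = 277.0, polar: float = 0.0
) -> SolvationTerms:
    """gamma(T) x A as a SolvationTerms fragment; area in Å^2."""
    if area < 0.0:
        raise ValueError("area must be non-negative")
    gamma = surface_tension(temperature)
    return SolvationTerms(
        polar=polar, nonpolar=gamma * area, gamma=gamma, area=area
    )


# --------------------------------------------------------------------------
# entropies
# --------------------------------------------------------------------------


@dataclass
class EntropyComponents:
    """Translational + rotational + internal solute entropy, kcal/mol/K."""

    s_trans: float
    s_rot: float
    s_int: float
    temperature: float
    mass: float | None = None  # amu
    volume: float | None = None  # L/mol
    moments: tuple[float, float, float] | None = None  # amu Å^2
    omegas: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def total(self) -> float:
        return self.s_trans + self.s_rot + self.s_int


def translational_entropy(mass: float, volume: float, temperature: float) -> float:
    """Ideal-gas (Sackur-Tetrode) translational entropy, kcal/mol/K.

    ``mass`` in amu, ``volume`` in L/mol (default standard state is the
    caller's choice; 1 L/mol corresponds to a 1 M standard state).
    """
    if mass <= 0 or volume <= 0 or temperature <= 0:
        raise ValueError("mass, volume and temperature must be positive")
    m_kg = mass * AMU_KG
    v_m3 = volume * 1.0e-3 / AVOGADRO  # per molecule
    lam = (2.0 * math.pi * m_kg * BOLTZMANN_J * temperature) / PLANCK_J**2
    return KB_KCALMOL * (1.5 * math.log(lam) + math.log(v_m3) + 2.5)


def rotational_entropy(
    i_x: float, i_y: float, i_z: float, temperature: float, sigma: float = 1.0
) -> float:
    """Classical rigid-rotor rotational entropy, kcal/mol/K.

    Principal moments in amu*Å^2; ``sigma`` is the rotational symmetry
    number (1 for an asymmetric protein).
    """
    if min(i_x, i_y, i_z) <= 0 or temperature <= 0:
        raise ValueError("moments and temperature must be positive")
    conv = AMU_KG * ANGSTROM_M**2
    prod = (i_x * conv) * (i_y * conv) * (i_z * conv)
    pref = (8.0 * math.pi**2 * BOLTZMANN_J * temperature) / PLANCK_J**2
    arg = math.sqrt(math.pi) / sigma * pref**1.5 * math.sqrt(prod)
    return KB_KCALMOL * (math.log(arg) + 1.5)


def principal_moments(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Principal moments of inertia (amu*Å^2), ascending."""
    coords = np.asarray(coords, dtype=float)
    masses = np.asarray(masses, dtype=float)
    com = (masses[:, None] * coords).sum(axis=0) / masses.sum()
    x = coords - com
    r2 = np.sum(x * x, axis=1)
    tensor = np.einsum("i,ij,ik->jk", masses, x, x)
    inertia = np.diag(np.sum(masses * r2) * np.ones(3)) - tensor
    return np.sort(np.linalg.eigvalsh(inertia))


def _qho_entropy(omegas: np.ndarray, temperature: float) -> float:
    """Quantum harmonic-oscillator entropy sum, kcal/mol/K."""
    x = HBAR_J * np.asarray(omegas) / (BOLTZMANN_J * temperature)
    with np.errstate(over="ignore"):
        term = x / np.expm1(x) - np.log1p(-np.exp(-x))
    return float(KB_KCALMOL * np.sum(term))


def quasiharmonic_internal_entropy(
    frames: np.ndarray,
    masses: np.ndarray,
    temperature: float,
    n_external_modes: int = 6,
    eigenvalue_floor: float = 1.0e-8,
    presuperposed: bool = False,
) -> tuple[float, np.ndarray]:
    """Internal-motion entropy from the mass-weighted covariance.

    Frames are best-fitted to their mean to remove external motion
    (skipped when ``presuperposed``), the covariance of mass-weighted
    coordinates sqrt(m) x is eigen-decomposed, each retained eigenvalue
    lambda_i (amu*Å^2) defines an effective mode frequency
    omega_i = sqrt(kB T / lambda_i), and the quantum harmonic-oscillator
    entropy (kinetic term included) is summed over modes. The
    ``n_external_modes`` smallest eigenvalues and any eigenvalue below
    ``eigenvalue_floor`` are discarded.

    Returns (S_int in kcal/mol/K, omegas ascending in rad/s).
    """
    frames = np.asarray(frames, dtype=float)
    n_frames, n_atoms, _ = frames.shape
    if n_frames < n_atoms:
        import warnings

        warnings.warn(
            f"{n_frames} frames < {n_atoms} atoms: covariance is rank-deficient;"
            " zero modes are dropped"
        )
    if not presuperposed:
        mean = frames.mean(axis=0)
        for _ in range(2):
            fitted = np.empty_like(frames)
            for k in range(n_frames):
                t, _ = superpose(frames[k], mean)
                fitted[k] = apply_transform(t, frames[k])
            mean = fitted.mean(axis=0)
            frames = fitted
    flat = frames.reshape(n_frames, 3 * n_atoms)
    w = np.sqrt(np.repeat(np.asarray(masses, dtype=float), 3))
    q = (flat - flat.mean(axis=0)) * w
    cov = (q.T @ q) / n_frames
    evals = np.linalg.eigvalsh(cov)  # ascending, amu Å^2
    evals = evals[max(0, n_external_modes):] if n_external_modes else evals
    evals = evals[evals > eigenvalue_floor]
    if evals.size == 0:
        return 0.0, np.array([])
    kbt_int = BOLTZMANN_J * temperature / (AMU_KG * ANGSTROM_M**2)  # amu Å^2 / s^2
    omegas = np.sort(np.sqrt(kbt_int / evals))
    return _qho_entropy(omegas, temperature), omegas


def entropy_components(
    frames: np.ndarray,
    masses: np.ndarray,
    temperature: float,
    volume: float = 1.0,
    sigma: float = 1.0,
    presuperposed: bool = False,
) -> EntropyComponents:
    """Full solute entropy S = S_trans + S_rot + S_int for one segment."""
    masses = np.asarray(masses, dtype=float)
    m_total = float(masses.sum())
    s_tr = translational_entropy(m_total, volume, temperature)
    mean = np.asarray(frames, dtype=float).mean(axis=0)
    mom = principal_moments(mean, masses)
    s_rot = rotational_entropy(*mom, temperature, sigma=sigma)
    s_int, omegas = quasiharmonic_internal_entropy(
        frames, masses, temperature, presuperposed=presuperposed
    )
    return EntropyComponents(
        s_trans=s_tr,
        s_rot=s_rot,
        s_int=s_int,
        temperature=temperature,
        mass=m_total,
        volume=volume,
        moments=tuple(mom),
        omegas=omegas,
    )


def block_entropy(
    trajectory: Trajectory,
    temperature: float,
    masses: np.ndarray | None = None,
    n_blocks: int = 5,
    volume: float = 1.0,
) -> tuple[float, float, list[EntropyComponents]]:
    """Mean +- SD of total solute entropy over contiguous equal blocks.

    The frame range is split into ``n_blocks`` contiguous blocks
    (trailing remainder dropped); each block yields an independent
    S = S_trans + S_rot + S_int estimate.
    """
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2")
    if masses is None:
        masses = masses_for(trajectory.topology)
    n = trajectory.n_frames
    block_len = n // n_blocks
    if block_len < 2:
        raise ValueError("too few frames for the requested block count")
    comps = []
    for b in range(n_blocks):
        seg = trajectory.frames[b * block_len:(b + 1) * block_len]
        comps.append(entropy_components(seg, masses, temperature, volume=volume))
    totals = np.array([c.total for c in comps])
    return float(totals.mean()), float(totals.std()), comps


# --------------------------------------------------------------------------
# cycle assembly
# --------------------------------------------------------------------------


@dataclass
class FreeEnergyBreakdown:
    """One row of the pressure-shift decomposition, kcal/mol.

    ``delta_g = delta_e_conf + delta_delta_mu - t_delta_s`` holds by
    construction; ``delta_delta_g`` is relative to a reference label.
    """

    label: str
    delta_e_conf: tuple[float, float]
    delta_delta_mu: tuple[float, float]
    t_delta_s: tuple[float, float]
    delta_g: tuple[float, float] = field(init=False)
    delta_delta_g: float | None = None

    def __post_init__(self) -> None:
        mean = self.delta_e_conf[0] + self.delta_delta_mu[0] - self.t_delta_s[0]
        sd = math.sqrt(
            self.delta_e_conf[1] ** 2
            + self.delta_delta_mu[1] ** 2
            + self.t_delta_s[1] ** 2
        )
        self.delta_g = (mean, sd)


def free_energy_shift(
    delta_e_conf: tuple[float, float],
    delta_delta_mu: tuple[float, float],
    t_delta_s: tuple[float, float],
    label: str = "",
) -> FreeEnergyBreakdown:
    """Assemble dG = dE_conf + ddmu - T dS with quadrature SDs."""
    for name, val in (
        ("delta_e_conf", delta_e_conf),
        ("delta_delta_mu", delta_delta_mu),
        ("t_delta_s", t_delta_s),
    ):
        if val is None:
            raise ValueError(f"missing component {name}")
    return FreeEnergyBreakdown(
        label=label,
        delta_e_conf=tuple(delta_e_conf),
        delta_delta_mu=tuple(delta_delta_mu),
        t_delta_s=tuple(t_delta_s),
    )


def free_energy_table(
    rows: Mapping[str, tuple],
    reference_label: str,
) -> list[FreeEnergyBreakdown]:
    """Breakdown per label with ddG relative to ``reference_label``.

    ``rows`` maps label -> (delta_e_conf, delta_delta_mu, t_delta_s),
    each a (mean, sd) pair. The reference label's ddG is 0 exactly.
    """
    if reference_label not in rows:
        raise KeyError(f"reference label {reference_label!r} not among rows")
    out = [
        free_energy_shift(*vals, label=label) for label, vals in rows.items()
    ]
    ref_g = next(b for b in out if b.label == reference_label).delta_g[0]
    for b in out:
        b.delta_delta_g = b.delta_g[0] - ref_g
    return out
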