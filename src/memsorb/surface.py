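"""Charged flat-surface membrane model and bead-surface energies.

The membrane is an infinite, laterally uniform plane at z = 0 carrying a
signed surface charge density (negative for biological membranes), immersed
in a 1:1 electrolyte.  A bead at height z above the plane feels

* screened electrostatics from the linearised Gouy-Chapman plane potential,
  ``u_ele = q e sigma_s / (eps0 epsr kappa) * exp(-kappa z)`` (per mole),
  with kappa the inverse Debye length set by the ionic strength, and
* a 9-3 integrated Lennard-Jones wall,
  ``u_vdw = eps_w [ (2/15)(sigma_w/z)^9 - (sigma_w/z)^3 ]``,
  with Lorentz-Berthelot combination of the bead and wall parameters.

Both terms vanish as z -> infinity and the total is strictly additive over
beads, so the whole-molecule energy depends only on bead heights — the
surface is invariant under lateral translation and rotation about its
normal.  The parameterisation is fully exposed (per-residue charges,
sigma, epsilon via the parameter table; wall and electrolyte constants via
:class:`SurfaceParams`), so published per-residue parameter sets can be
dropped in; alternative functional forms would replace the two kernel
functions here and in the sampler's inlined copy.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._constants import (AVOGADRO, BOLTZMANN, ELEMENTARY_CHARGE,
                         VACUUM_PERMITTIVITY)
from .structio import CGBead, CGProtein

__all__ = ["SurfaceParams", "EnergyBreakdown", "debye_length",
           "bead_surface_energy", "pose_energy", "OVERLAP_ENERGY"]

#: Energy reported for an invalid pose (a bead at or below the plane).  The
#: sampler treats it as "never accept"; it is a signal, not an exception.
OVERLAP_ENERGY = np.inf


def debye_length(ionic_strength: float, temperature: float = 310.0,
                 epsilon_r: float = 78.5) -> float:
    """Debye screening length in nm for a 1:1 electrolyte.

    kappa^-1 = sqrt(eps0 epsr kB T / (2 NA e^2 I)), with the ionic strength
    I in mol/L (converted to mol/m^3 internally).
    """
    if ionic_strength <= 0:
        raise ValueError("ionic strength must be positive")
    if temperature <= 0 or epsilon_r <= 0:
        raise ValueError("temperature and permittivity must be positive")
    lam = np.sqrt(
        VACUUM_PERMITTIVITY * epsilon_r * BOLTZMANN * temperature
        / (2.0 * AVOGADRO * ELEMENTARY_CHARGE**2 * ionic_strength * 1000.0))
    return float(lam * 1e9)


@dataclass(frozen=True)
class EnergyBreakdown:
    """Additive decomposition of the adsorption energy (kJ/mol)."""

    u_vdw: float
    u_ele: float

    @property
    def u_tot(self) -> float:
        return self.u_vdw + self.u_ele

    def __add__(self, other: "EnergyBreakdown") -> "EnergyBreakdown":
        return EnergyBreakdown(self.u_vdw + other.u_vdw,
                               self.u_ele + other.u_ele)


@dataclass(frozen=True)
class SurfaceParams:
    """Flat charged-membrane parameters.

    scd: surface charge density, C/m^2 (signed; negative mimics a
    membrane); ionic_strength in mol/L sets the Debye length;
    temperature (K) and epsilon_r enter the screening only — replica
    tempering never changes them.  wall_epsilon (kJ/mol) and wall_sigma
    (nm) parameterise the 9-3 wall and combine with per-bead values by
    Lorentz-Berthelot rules.
    """

    scd: float = -0.127
    ionic_strength: float = 0.18
    temperature: float = 310.0
    epsilon_r: float = 78.5
    wall_epsilon: float = 0.5
    wall_sigma: float = 0.5

    def __post_init__(self):
        if self.ionic_strength <= 0:
            raise ValueError("ionic strength must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.epsilon_r <= 0:
            raise ValueError("relative permittivity must be positive")

    @property
    def debye_length_nm(self) -> float:
        return debye_length(self.ionic_strength, self.temperature,
                            self.epsilon_r)

    @property
    def kappa_per_nm(self) -> float:
        return 1.0 / self.debye_length_nm

    def electrostatic_prefactor(self) -> float:
        """q=+1 contact energy e sigma_s / (eps0 epsr kappa), kJ/mol."""
        kappa_per_m = self.kappa_per_nm * 1e9
        phi0 = self.scd / (VACUUM_PERMITTIVITY * self.epsilon_r * kappa_per_m)
        return ELEMENTARY_CHARGE * phi0 * AVOGADRO / 1000.0


def _ele_energy(q: np.ndarray, z_nm: np.ndarray, sp: SurfaceParams) -> np.ndarray:
    return q * sp.electrostatic_prefactor() * np.exp(-sp.kappa_per_nm * z_nm)


def _vdw_energy(eps: np.ndarray, sig: np.ndarray, z_nm: np.ndarray,
                sp: SurfaceParams) -> np.ndarray:
    eps_c = np.sqrt(eps * sp.wall_epsilon)
    sig_c = 0.5 * (sig + sp.wall_sigma)
    x3 = (sig_c / z_nm) ** 3
    return eps_c * ((2.0 / 15.0) * x3**3 - x3)


def bead_surface_energy(bead: CGBead, z: float,
                        sp: SurfaceParams) -> EnergyBreakdown:
    """Energy of a single bead at height z (nm) above the plane."""
    if z <= 0:
        raise ValueError("bead height must be positive "
                         "(protein may not penetrate the surface plane)")
    z_arr = np.asarray([z], dtype=float)
    u_ele = _ele_energy(np.asarray([bead.charge]), z_arr, sp)[0]
    u_vdw = _vdw_energy(np.asarray([bead.vdw_epsilon]),
                        np.asarray([bead.vdw_sigma]), z_arr, sp)[0]
    return EnergyBreakdown(float(u_vdw), float(u_ele))


def heights_energy(charges: np.ndarray, eps: np.ndarray, sig: np.ndarray,
                   z_nm: np.ndarray, sp: SurfaceParams
                   ) -> tuple[float, float]:
    """(u_vdw, u_ele) summed over beads at the given heights.

    Returns (inf, inf) if any bead is at or below the plane — the overlap
    signal used by the sampler.  This is the vectorised kernel behind
    :func:`pose_energy` and the Monte Carlo loop.
    """
    if np.min(z_nm) <= 0:
        return OVERLAP_ENERGY, OVERLAP_ENERGY
    u_ele = float(_ele_energy(charges, z_nm, sp).sum())
    u_vdw = float(_vdw_energy(eps, sig, z_nm, sp).sum())
    return u_vdw, u_ele


def pose_energy(cg: CGProtein, pose, sp: SurfaceParams) -> EnergyBreakdown:
    """Adsorption energy of a rigid protein in a given pose.

    ``pose`` is a :class:`memsorb.ptmc.Pose`.  Strictly additive over beads;
    any bead at z <= 0 yields the overlap signal (infinite energies), which
    the Metropolis step never accepts.
    """
    z = pose.bead_heights(cg)
    u_vdw, u_ele = heights_energy(cg.charges, cg.epsilon, cg.sigma, z, sp)
    return EnergyBreakdown(u_vdw, u_ele)
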