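"""Parallel tempering Monte Carlo of a rigid protein over a charged surface.

A ladder of canonical Metropolis replicas at increasing temperatures samples
rigid-body poses (COM position + orientation) of a coarse-grained protein
above the membrane plane.  Every cycle each replica attempts one random
translation and one random rotation about the centre of mass; neighbouring
rungs attempt configuration swaps at a fixed cycle interval (adjacent pairs,
alternating even/odd sweeps, which satisfies detailed balance).  Tempering
scales only the Metropolis factor: the physical screening temperature of the
surface model never changes.

Step sizes are adapted multiplicatively toward a target acceptance ratio of
0.5 during equilibration and frozen afterwards so that production samples
come from a fixed transition kernel.  The analysis stream is the coldest
(physical, 310 K by default) rung.

Lateral (x, y) coordinates live in a periodic box; the COM height is
confined to (0, box_edge] with a reflecting upper bound.  A pose placing any
bead at or below the plane is an overlap: infinite energy, never accepted.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from ._constants import GAS_CONSTANT
from .structio import CGProtein, Descriptors, dipoles
from .surface import SurfaceParams, OVERLAP_ENERGY

__all__ = ["Pose", "PTMCConfig", "ReplicaSamples", "PTMCResult",
           "propose_move", "metropolis_accept", "adapt_steps",
           "swap_accept_probability", "attempt_swap", "orientation_angle",
           "run_ptmc"]

_STEP_MIN = 1e-4
_ROT_MAX = np.pi


@dataclass(frozen=True)
class Pose:
    """Rigid-body pose: COM position (nm) and orientation quaternion.

    The quaternion is scalar-last (scipy convention) and kept normalised.
    """

    com: np.ndarray  # (3,)
    quat: np.ndarray  # (4,), scalar last, |q| = 1

    def __post_init__(self):
        object.__setattr__(self, "com", np.asarray(self.com, dtype=float))
        q = np.asarray(self.quat, dtype=float)
        norm = np.linalg.norm(q)
        if norm == 0:
            raise ValueError("zero quaternion")
        object.__setattr__(self, "quat", q / norm)

    @classmethod
    def identity(cls, com=(0.0, 0.0, 0.0)) -> "Pose":
        return cls(np.asarray(com, dtype=float),
                   np.array([0.0, 0.0, 0.0, 1.0]))

    def rotation_matrix(self) -> np.ndarray:
        return Rotation.from_quat(self.quat).as_matrix()

    def apply(self, cg: CGProtein) -> np.ndarray:
        """World-frame bead positions (nm) of the rigid molecule."""
        return self.com + cg.body_coords @ self.rotation_matrix().T

    def bead_heights(self, cg: CGProtein) -> np.ndarray:
        return self.com[2] + cg.body_coords @ self.rotation_matrix()[2]


@dataclass(frozen=True)
class PTMCConfig:
    """Sampler configuration; defaults follow the full-scale protocol."""

    temperatures: tuple[float, ...] = (310.0, 500.0, 800.0, 1500.0, 2500.0)
    cycles_total: int = 15_000_000
    cycles_equil: int = 5_000_000
    swap_interval: int = 500
    box_edge: float = 30.0  # nm
    init_height: float = 10.0  # nm
    init_xy: tuple[float, float] = (0.0, 0.0)
    target_acceptance: float = 0.5
    adapt_interval: int = 1000
    record_stride: int = 100
    step_translation: float = 1.0  # nm, initial
    step_rotation: float = 0.5  # rad, initial
    seed: int = 0

    def __post_init__(self):
        t = tuple(float(x) for x in self.temperatures)
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("temperature ladder must be strictly increasing")
        if not 0 < self.cycles_equil < self.cycles_total:
            raise ValueError("need 0 < cycles_equil < cycles_total")
        for name in ("swap_interval", "adapt_interval", "record_stride"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class ReplicaSamples:
    """Production sample stream of one temperature rung."""

    temperature: float
    cycle: np.ndarray  # (S,)
    z_com: np.ndarray  # (S,), nm
    cos_theta: np.ndarray  # (S,), electric dipole vs surface normal
    cos_theta_h: np.ndarray  # (S,), hydrophobic dipole
    u_vdw: np.ndarray  # (S,), kJ/mol
    u_ele: np.ndarray
    com: np.ndarray  # (S, 3)
    quat: np.ndarray  # (S, 4)

    @property
    def u_tot(self) -> np.ndarray:
        return self.u_vdw + self.u_ele

    @property
    def n_samples(self) -> int:
        return len(self.cycle)

    def pose(self, i: int) -> Pose:
        return Pose(self.com[i].copy(), self.quat[i].copy())


@dataclass
class PTMCResult:
    """Per-rung production streams plus swap and adaptation bookkeeping."""

    replicas: list[ReplicaSamples]
    config: PTMCConfig
    seed: int
    swap_attempts: np.ndarray  # (n_rungs - 1,)
    swap_accepts: np.ndarray
    final_step_translation: np.ndarray  # (n_rungs,)
    final_step_rotation: np.ndarray
    descriptors: Descriptors | None = None
    production_acceptance: np.ndarray | None = None  # (n_rungs, 2):
    #   measured (translation, rotation) acceptance of the frozen kernel

    @property
    def target_index(self) -> int:
        """Index of the coldest (physical) rung — the analysis stream."""
        return int(np.argmin(self.config.temperatures))

    @property
    def target(self) -> ReplicaSamples:
        return self.replicas[self.target_index]


# ---------------------------------------------------------------------------
# elementary moves

def _rotvec_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix for a unit axis; hot-loop primitive."""
    from math import cos, sin
    c, s = cos(angle), sin(angle)
    ux, uy, uz = float(axis[0]), float(axis[1]), float(axis[2])
    t = 1.0 - c
    return np.array([
        [c + t * ux * ux, t * ux * uy - s * uz, t * ux * uz + s * uy],
        [t * ux * uy + s * uz, c + t * uy * uy, t * uy * uz - s * ux],
        [t * ux * uz - s * uy, t * uy * uz + s * ux, c + t * uz * uz]])


def _random_axis(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:  # pragma: no cover - essentially impossible
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def propose_move(pose: Pose, step_translation: float, step_rotation: float,
                 rng: np.random.Generator) -> Pose:
    """One trial rigid-body move about the COM.

    Each COM component is displaced uniformly within +/- step_translation;
    the orientation is composed with a rotation about a uniformly random
    axis by an angle uniform in [0, step_rotation].
    """
    if step_translation < 0 or step_rotation < 0:
        raise ValueError("step sizes must be non-negative")
    disp = rng.uniform(-step_translation, step_translation, size=3)
    axis = _random_axis(rng)
    angle = rng.uniform(0.0, step_rotation)
    rot = Rotation.from_rotvec(axis * angle) * Rotation.from_quat(pose.quat)
    return Pose(pose.com + disp, rot.as_quat())


def metropolis_accept(delta_u: float, temperature: float,
                      rng: np.random.Generator) -> bool:
    """Canonical Metropolis criterion with molar energies (kJ/mol)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if np.isinf(delta_u):
        return delta_u < 0
    if delta_u <= 0:
        return True
    return rng.random() < np.exp(-delta_u / (GAS_CONSTANT * temperature))


def adapt_steps(recent_acceptance_rate: float,
                current_steps: tuple[float, float],
                target: float = 0.5,
                box_edge: float = 30.0) -> tuple[float, float]:
    """Multiplicative step-size update toward the target acceptance ratio.

    Grows both steps by 1.1 when the measured rate exceeds the target,
    shrinks by 0.9 when below; translation clamped to
    [1e-4, box_edge / 2] nm, rotation to [1e-4, pi] rad.
    """
    if not 0.0 <= recent_acceptance_rate <= 1.0:
        raise ValueError("acceptance rate must be in [0, 1]")
    trans, rot = current_steps
    if recent_acceptance_rate > target:
        factor = 1.1
    elif recent_acceptance_rate < target:
        factor = 0.9
    else:
        factor = 1.0
    trans = float(np.clip(trans * factor, _STEP_MIN, box_edge / 2.0))
    rot = float(np.clip(rot * factor, _STEP_MIN, _ROT_MAX))
    return trans, rot


def swap_accept_probability(beta_i: float, beta_j: float,
                            u_i: float, u_j: float) -> float:
    """min(1, exp[(beta_i - beta_j)(U_i - U_j)]) for a replica swap."""
    if np.isinf(u_i) or np.isinf(u_j):
        return 0.0
    arg = (beta_i - beta_j) * (u_i - u_j)
    return float(min(1.0, np.exp(min(arg, 0.0))) if arg < 0 else 1.0)


def attempt_swap(state_i, state_j, t_i: float, t_j: float,
                 rng: np.random.Generator):
    """Attempt a configuration exchange between two neighbouring rungs.

    ``state_i``/``state_j`` are (Pose, u_tot) pairs.  Returns
    (accepted, state_i, state_j); on success the configurations exchange
    while the temperatures stay fixed to their rungs.
    """
    beta_i = 1.0 / (GAS_CONSTANT * t_i)
    beta_j = 1.0 / (GAS_CONSTANT * t_j)
    p = swap_accept_probability(beta_i, beta_j, state_i[1], state_j[1])
    if rng.random() < p:
        return True, state_j, state_i
    return False, state_i, state_j


def orientation_angle(pose: Pose, descriptors: Descriptors
                      ) -> tuple[float, float]:
    """cos(theta) of the rotated electric and hydrophobic dipoles.

    theta is the angle between the outward surface normal z-hat and the
    dipole in the world frame.  A (numerically) zero dipole yields NaN — a
    flag, not an error.
    """
    rmat = pose.rotation_matrix()
    out = []
    for mu in (descriptors.electric_dipole, descriptors.hydrophobic_dipole):
        norm = np.linalg.norm(mu)
        out.append(float(rmat[2] @ (mu / norm)) if norm > 1e-12 else np.nan)
    return out[0], out[1]


# ---------------------------------------------------------------------------
# the sampler

def run_ptmc(cg: CGProtein, sp: SurfaceParams,
             config: PTMCConfig | None = None) -> PTMCResult:
    """Run parallel tempering MC; deterministic given ``config.seed``.

    One cycle = one translation attempt plus one rotation attempt per
    replica.  Swap sweeps run every ``swap_interval`` cycles over adjacent
    pairs, alternating even/odd.  Production samples (after
    ``cycles_equil``) are recorded every ``record_stride`` cycles on every
    rung.
    """
    config = config or PTMCConfig()
    temps = np.asarray(config.temperatures, dtype=float)
    n_rep = len(temps)
    if n_rep < 2:
        warnings.warn("temperature ladder has < 2 rungs: degenerate "
                      "single-replica MC", stacklevel=2)
    betas = 1.0 / (GAS_CONSTANT * temps)

    # RNG: one child stream per replica plus one for swaps, all derived
    # from the master seed so replica-count changes leave streams intact.
    children = np.random.SeedSequence(config.seed).spawn(n_rep + 1)
    rngs = [np.random.Generator(np.random.PCG64(s)) for s in children[:n_rep]]
    swap_rng = np.random.Generator(np.random.PCG64(children[n_rep]))

    body = cg.body_coords
    desc = dipoles(cg)
    mu_e, mu_h = desc.electric_dipole, desc.hydrophobic_dipole
    mu_e_hat = mu_e / np.linalg.norm(mu_e) if np.linalg.norm(mu_e) > 1e-12 else None
    mu_h_hat = mu_h / np.linalg.norm(mu_h) if np.linalg.norm(mu_h) > 1e-12 else None

    charges, eps, sig = cg.charges, cg.epsilon, cg.sigma
    a_ele = charges * sp.electrostatic_prefactor()
    kappa = sp.kappa_per_nm
    eps_c = np.sqrt(eps * sp.wall_epsilon)
    sig_c = 0.5 * (sig + sp.wall_sigma)
    box = config.box_edge
    half = box / 2.0

    def energy(z: np.ndarray) -> tuple[float, float]:
        if z.min() <= 0.0:
            return OVERLAP_ENERGY, OVERLAP_ENERGY
        x3 = (sig_c / z) ** 3
        u_vdw = float(np.sum(eps_c * ((2.0 / 15.0) * x3 * x3 * x3 - x3)))
        u_ele = float(np.sum(a_ele * np.exp(-kappa * z)))
        return u_vdw, u_ele

    # per-replica state
    com = np.zeros((n_rep, 3))
    com[:, 0], com[:, 1] = config.init_xy
    com[:, 2] = config.init_height
    rmats = np.empty((n_rep, 3, 3))
    z_cache = [None] * n_rep
    u_vdw_cur = np.empty(n_rep)
    u_ele_cur = np.empty(n_rep)
    for k in range(n_rep):
        q = rngs[k].normal(size=4)
        rmats[k] = Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
        z_cache[k] = com[k, 2] + body @ rmats[k][2]
        u_vdw_cur[k], u_ele_cur[k] = energy(z_cache[k])

    steps_t = np.full(n_rep, config.step_translation)
    steps_r = np.full(n_rep, config.step_rotation)
    # per-move-type acceptance counters (translation, rotation)
    acc = np.zeros((n_rep, 2), dtype=int)
    att = np.zeros((n_rep, 2), dtype=int)

    swap_attempts = np.zeros(max(n_rep - 1, 0), dtype=int)
    swap_accepts = np.zeros(max(n_rep - 1, 0), dtype=int)
    swap_parity = 0

    rec: list[list] = [[] for _ in range(n_rep)]  # per-replica sample rows
    rec_rmat: list[list] = [[] for _ in range(n_rep)]

    exp = np.exp
    isfinite = np.isfinite

    # Randoms are drawn in per-replica blocks (one block layout per cycle:
    # 3 uniform for translation, 3 normal for the axis, 1 uniform for the
    # angle, 2 uniform for the two Metropolis tests).  Draw order is fixed,
    # so streams stay deterministic for a given seed.
    _BLOCK = 2048
    buf_u = [np.empty((0, 6))] * n_rep
    buf_n = [np.empty((0, 3))] * n_rep
    buf_pos = [0] * n_rep

    for cycle in range(1, config.cycles_total + 1):
        for k in range(n_rep):
            if buf_pos[k] >= len(buf_u[k]):
                buf_u[k] = rngs[k].random((_BLOCK, 6))
                buf_n[k] = rngs[k].normal(size=(_BLOCK, 3))
                buf_pos[k] = 0
            row_u = buf_u[k][buf_pos[k]]
            row_n = buf_n[k][buf_pos[k]]
            buf_pos[k] += 1

            beta = betas[k]
            u_cur = u_vdw_cur[k] + u_ele_cur[k]
            st = steps_t[k]

            # translation attempt
            new_z_com = com[k, 2] + (2.0 * row_u[2] - 1.0) * st
            if new_z_com > box:  # reflecting upper bound
                new_z_com = 2.0 * box - new_z_com
            z_new = z_cache[k] + (new_z_com - com[k, 2])
            u_vdw_n, u_ele_n = energy(z_new)
            du = (u_vdw_n + u_ele_n) - u_cur
            att[k, 0] += 1
            if du <= 0 or (isfinite(du) and row_u[4] < exp(-du * beta)):
                x = com[k, 0] + (2.0 * row_u[0] - 1.0) * st
                y = com[k, 1] + (2.0 * row_u[1] - 1.0) * st
                # periodic lateral wrap
                com[k, 0] = (x + half) % box - half
                com[k, 1] = (y + half) % box - half
                com[k, 2] = new_z_com
                z_cache[k] = z_new
                u_vdw_cur[k], u_ele_cur[k] = u_vdw_n, u_ele_n
                u_cur = u_vdw_n + u_ele_n
                acc[k, 0] += 1

            # rotation attempt
            nrm = (row_n[0] * row_n[0] + row_n[1] * row_n[1]
                   + row_n[2] * row_n[2]) ** 0.5
            if nrm < 1e-12:  # pragma: no cover
                nrm = 1.0
            axis = row_n / nrm
            angle = row_u[3] * steps_r[k]
            rmat_new = _rotvec_matrix(axis, angle) @ rmats[k]
            z_new = com[k, 2] + body @ rmat_new[2]
            u_vdw_n, u_ele_n = energy(z_new)
            du = (u_vdw_n + u_ele_n) - u_cur
            att[k, 1] += 1
            if du <= 0 or (isfinite(du) and row_u[5] < exp(-du * beta)):
                rmats[k] = rmat_new
                z_cache[k] = z_new
                u_vdw_cur[k], u_ele_cur[k] = u_vdw_n, u_ele_n
                acc[k, 1] += 1

        # step adaptation, frozen after equilibration
        if cycle % config.adapt_interval == 0 and cycle <= config.cycles_equil:
            for k in range(n_rep):
                rate_t = acc[k, 0] / att[k, 0] if att[k, 0] else 0.0
                rate_r = acc[k, 1] / att[k, 1] if att[k, 1] else 0.0
                steps_t[k] = adapt_steps(rate_t, (steps_t[k], steps_r[k]),
                                         config.target_acceptance, box)[0]
                steps_r[k] = adapt_steps(rate_r, (steps_t[k], steps_r[k]),
                                         config.target_acceptance, box)[1]
                acc[k] = 0
                att[k] = 0

        # swap sweep
        if n_rep > 1 and cycle % config.swap_interval == 0:
            for i in range(swap_parity, n_rep - 1, 2):
                swap_attempts[i] += 1
                arg = (betas[i] - betas[i + 1]) * (
                    (u_vdw_cur[i] + u_ele_cur[i])
                    - (u_vdw_cur[i + 1] + u_ele_cur[i + 1]))
                if arg >= 0 or swap_rng.random() < exp(arg):
                    for obj in (com, rmats, u_vdw_cur, u_ele_cur):
                        obj[[i, i + 1]] = obj[[i + 1, i]]
                    z_cache[i], z_cache[i + 1] = z_cache[i + 1], z_cache[i]
                    swap_accepts[i] += 1
            swap_parity ^= 1

        # production recording
        if cycle > config.cycles_equil and cycle % config.record_stride == 0:
            for k in range(n_rep):
                ct = (rmats[k][2] @ mu_e_hat) if mu_e_hat is not None else np.nan
                cth = (rmats[k][2] @ mu_h_hat) if mu_h_hat is not None else np.nan
                rec[k].append((cycle, com[k, 2], ct, cth,
                               u_vdw_cur[k], u_ele_cur[k],
                               com[k, 0], com[k, 1]))
                rec_rmat[k].append(rmats[k].copy())

    replicas = []
    for k in range(n_rep):
        rows = np.asarray(rec[k], dtype=float).reshape(-1, 8)
        quats = (Rotation.from_matrix(np.asarray(rec_rmat[k])).as_quat()
                 if rec_rmat[k] else np.empty((0, 4)))
        com_s = np.column_stack([rows[:, 6], rows[:, 7], rows[:, 1]]) \
            if len(rows) else np.empty((0, 3))
        replicas.append(ReplicaSamples(
            temperature=float(temps[k]), cycle=rows[:, 0].astype(int),
            z_com=rows[:, 1], cos_theta=rows[:, 2], cos_theta_h=rows[:, 3],
            u_vdw=rows[:, 4], u_ele=rows[:, 5], com=com_s, quat=quats))

    # acc/att stop being reset once adaptation freezes, so their final
    # ratio is the production acceptance rate of the frozen kernel
    prod_acc = np.divide(acc, att, out=np.zeros((n_rep, 2)), where=att > 0)
    return PTMCResult(replicas=replicas, config=config, seed=config.seed,
                      swap_attempts=swap_attempts, swap_accepts=swap_accepts,
                      final_step_translation=steps_t.copy(),
                      final_step_rotation=steps_r.copy(),
                      descriptors=desc, production_acceptance=prod_acc)
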