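"""Seeded generators for every input class the pipeline consumes.

Two families:

* curved "banana" bead proteins (arcs) with tunable end-charge patterns,
  emulating BAR-domain dimers — a positively charged membrane-binding
  patch at one or both tips and scattered acidic beads along the body
  giving a small negative net charge;
* planted all-atom (Ca-only) trajectories with known per-residue Gaussian
  fluctuations, planted orthonormal collective modes, optional slow
  two-state dynamics, and an optional contact pair toggling in and out of
  salt-bridge range with known Bernoulli occupancy.

Every generator is a pure function of its spec (seed included) and returns
its own ground truth, so downstream tests never re-derive it.  Fixture
trajectories are written as multi-MODEL PDB, with coordinates quantized to
the format's 3-decimal Angstrom precision.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._constants import ANGSTROM_PER_NM
from .parameters import default_param_table
from .structio import (AtomicStructure, CGProtein, Trajectory,
                       write_trajectory)

__all__ = ["ArcSpec", "PlantedTrajectorySpec", "make_arc_protein",
           "make_planted_trajectory", "write_fixture_set",
           "ASYMMETRIC_ARC", "SYMMETRIC_ARC"]

_CHARGE_RESIDUE = {1: "LYS", -1: "GLU", 0: "GLY"}


@dataclass(frozen=True)
class ArcSpec:
    """Circular-arc bead protein with a configurable charge pattern.

    ``first_end_charges``/``last_end_charges`` assign charges to the first
    and last beads; ``body_charge_every`` places ``body_charge`` on body
    beads whose distance from the nearer terminus is a multiple of that
    stride — a mirror-symmetric placement, so symmetric end patterns give
    a mirror-symmetric molecule.  All other beads are neutral.
    """

    n_beads: int = 50
    radius_nm: float = 6.0
    angle_rad: float = 1.5
    first_end_charges: tuple[int, ...] = ()
    last_end_charges: tuple[int, ...] = ()
    body_charge: int = 0
    body_charge_every: int = 0
    seed: int = 0

    def charge_vector(self) -> np.ndarray:
        q = np.zeros(self.n_beads)
        k1 = len(self.first_end_charges)
        k2 = len(self.last_end_charges)
        q[:k1] = self.first_end_charges
        if k2:
            q[-k2:] = self.last_end_charges
        if self.body_charge_every:
            lo = max(k1, 1)
            hi = self.n_beads - max(k2, 1)
            for i in range(lo, hi):
                if min(i, self.n_beads - 1 - i) % self.body_charge_every == 0:
                    q[i] = self.body_charge
        return q


#: Default study molecules: one positively charged tip (+6e), a weakly
#: negative opposite tip and scattered acidic body beads (net -3e) for the
#: charge-asymmetric arc; +3e at both tips (net -1e) for the symmetric one.
ASYMMETRIC_ARC = ArcSpec(first_end_charges=(1,) * 6,
                         last_end_charges=(-1,) * 2,
                         body_charge=-1, body_charge_every=5)
SYMMETRIC_ARC = ArcSpec(first_end_charges=(1,) * 3,
                        last_end_charges=(1,) * 3,
                        body_charge=-1, body_charge_every=5)


def make_arc_protein(spec: ArcSpec) -> CGProtein:
    """Beads spaced uniformly on a planar circular arc (deterministic)."""
    if spec.n_beads < 5:
        raise ValueError("need at least 5 beads")
    if spec.angle_rad <= 0:
        raise ValueError("arc angle must be positive")
    phi = np.linspace(-spec.angle_rad / 2.0, spec.angle_rad / 2.0,
                      spec.n_beads)
    pos = np.column_stack([spec.radius_nm * np.sin(phi),
                           spec.radius_nm * (1.0 - np.cos(phi)),
                           np.zeros_like(phi)])
    q = spec.charge_vector()
    table = default_param_table()
    names = [_CHARGE_RESIDUE[int(round(c))] for c in q]
    h = [table[n]["hydrophobicity"] for n in names]
    sig = [table[n]["sigma"] for n in names]
    eps = [table[n]["epsilon"] for n in names]
    return CGProtein(pos, q, h, sig, eps, names,
                     res_ids=list(range(1, spec.n_beads + 1)),
                     chain_ids=["A"] * spec.n_beads,
                     source_id=f"arc-n{spec.n_beads}-seed{spec.seed}")


@dataclass(frozen=True)
class PlantedTrajectorySpec:
    """Planted-statistics trajectory over a Ca-only topology.

    ``sigma`` is the isotropic per-axis Gaussian displacement (Angstrom);
    ``mode_amplitudes`` are standard deviations along planted orthonormal
    collective modes; ``two_state_offset``/``switch_rate`` add a slow
    Markov jump process; ``contact_p`` toggles the terminal residue pair
    inside salt-bridge range with that Bernoulli probability per frame.
    """

    n_frames: int = 2000
    n_residues: int = 30
    sigma: float = 0.5  # Angstrom, per axis
    mode_amplitudes: tuple[float, ...] = ()
    two_state_offset: float = 0.0  # Angstrom, magnitude of the jump vector
    switch_rate: float = 0.02  # per-frame flip probability
    contact_p: float | None = None
    contact_bound: float = 3.8  # Angstrom, inside the 4 A salt-bridge cutoff
    contact_unbound: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


@dataclass
class PlantedGroundTruth:
    """Everything the generator planted, for downstream assertions."""

    mean: np.ndarray  # (n, 3) A
    sigma: float
    modes: np.ndarray  # (k, 3n) orthonormal, rigid-motion free
    mode_amplitudes: np.ndarray  # (k,)
    mode_coefficients: np.ndarray  # (F, k)
    state_sequence: np.ndarray | None  # (F,) in {0, 1}
    state_offset_vector: np.ndarray | None  # (3n,)
    contact_pair: tuple[int, int] | None  # atom indices
    contact_events: np.ndarray | None  # (F,) bool
    seed: int


def _mean_chain(n: int) -> np.ndarray:
    i = np.arange(n)
    return np.column_stack([3.8 * i, 2.0 * np.sin(0.3 * i),
                            2.0 * np.cos(0.57 * i)])


def _rigid_free_modes(mean: np.ndarray, k: int,
                      rng: np.random.Generator) -> np.ndarray:
    """k random orthonormal 3n-vectors orthogonal to rigid-body motions."""
    n = len(mean)
    rigid = []
    for ax in range(3):
        t = np.zeros((n, 3))
        t[:, ax] = 1.0
        rigid.append(t.ravel())
    centered = mean - mean.mean(axis=0)
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = 1.0
        rigid.append(np.cross(centered, e).ravel())
    basis = np.array(rigid).T  # (3n, 6)
    q_rigid, _ = np.linalg.qr(basis)
    modes = []
    while len(modes) < k:
        v = rng.normal(size=3 * n)
        v -= q_rigid @ (q_rigid.T @ v)
        for m in modes:
            v -= m * (m @ v)
        norm = np.linalg.norm(v)
        if norm > 1e-8:
            modes.append(v / norm)
    return np.array(modes)


def make_planted_trajectory(spec: PlantedTrajectorySpec
                            ) -> tuple[Trajectory, PlantedGroundTruth]:
    """Generate a trajectory with fully known statistical structure.

    The topology is Ca-only except for an optional contact pair: the first
    residue carries a GLU OE1 oxygen and the last a LYS NZ nitrogen, which
    the generator toggles between ``contact_bound`` and ``contact_unbound``
    separation with Bernoulli(``contact_p``) per frame.
    """
    rng = np.random.default_rng(spec.seed)
    n, f = spec.n_residues, spec.n_frames
    mean = _mean_chain(n)
    k = len(spec.mode_amplitudes)
    modes = (_rigid_free_modes(mean, k, rng) if k
             else np.empty((0, 3 * n)))
    amps = np.asarray(spec.mode_amplitudes, dtype=float)
    coeff = rng.normal(size=(f, k)) * amps if k else np.empty((f, 0))

    frames = np.repeat(mean[None, :, :], f, axis=0)
    if k:
        frames += (coeff @ modes).reshape(f, n, 3)

    state = offset_vec = None
    if spec.two_state_offset > 0:
        offset_vec = _rigid_free_modes(mean, k + 1, np.random.default_rng(
            spec.seed + 1))[-1] * spec.two_state_offset
        flips = rng.random(f) < spec.switch_rate
        state = np.bitwise_xor.accumulate(flips).astype(int)
        frames += state[:, None, None] * offset_vec.reshape(1, n, 3)

    if spec.sigma > 0:
        frames += rng.normal(scale=spec.sigma, size=(f, n, 3))

    contact_pair = events = None
    names = ["CA"] * n
    elements = ["C"] * n
    res_names = ["ALA"] * n
    if spec.contact_p is not None:
        i, j = 0, n - 1
        contact_pair = (i, j)
        names[i], elements[i], res_names[i] = "OE1", "O", "GLU"
        names[j], elements[j], res_names[j] = "NZ", "N", "LYS"
        events = rng.random(f) < spec.contact_p
        direction = np.array([1.0, 0.0, 0.0])
        dist = np.where(events, spec.contact_bound, spec.contact_unbound)
        frames[:, j, :] = frames[:, i, :] + dist[:, None] * direction

    top = AtomicStructure(
        serial=np.arange(1, n + 1), name=names, element=elements,
        res_name=res_names, res_id=np.arange(1, n + 1),
        chain_id=["A"] * n, coords=mean, source_id=f"planted-seed{spec.seed}")
    traj = Trajectory(top, frames)
    gt = PlantedGroundTruth(mean=mean, sigma=spec.sigma, modes=modes,
                            mode_amplitudes=amps, mode_coefficients=coeff,
                            state_sequence=state,
                            state_offset_vector=offset_vec,
                            contact_pair=contact_pair,
                            contact_events=events, seed=spec.seed)
    return traj, gt


def write_fixture_set(out_dir: str | Path, seed: int = 42) -> dict:
    """Write the canonical test fixtures and a ground-truth manifest.

    Re-running with the same seed produces byte-identical files.  Returns
    the manifest (also written as ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "files": {}}

    for name, spec in (("arc_asymmetric", ASYMMETRIC_ARC),
                       ("arc_symmetric", SYMMETRIC_ARC)):
        spec = ArcSpec(**{**spec.__dict__, "seed": seed})
        cg = make_arc_protein(spec)
        path = out / f"{name}.json"
        path.write_text(cg.to_json())
        manifest["files"][path.name] = {
            "kind": "cg_protein", "seed": seed,
            "net_charge": float(cg.charges.sum()),
            "n_beads": cg.n_beads,
        }

    traj_spec = PlantedTrajectorySpec(n_frames=50, n_residues=20,
                                      sigma=0.3, contact_p=0.4, seed=seed)
    traj, gt = make_planted_trajectory(traj_spec)
    path = out / "planted_trajectory.pdb"
    write_trajectory(traj, path)
    manifest["files"][path.name] = {
        "kind": "trajectory", "seed": seed,
        "n_frames": traj.n_frames, "n_residues": traj_spec.n_residues,
        "sigma_A": traj_spec.sigma,
        "contact_p": traj_spec.contact_p,
        "contact_event_count": int(gt.contact_events.sum()),
    }

    (out / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1))
    return manifest
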