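"""Structure and trajectory I/O plus the coarse-grained united-residue model.

Atomic structures are read from PDB text (fixed-column ATOM/HETATM records,
multi-MODEL files as the portable trajectory dialect) through biotite and
held in thin array-backed containers.  Coarse-graining reduces every residue
to a single interaction site at its alpha-carbon carrying a formal charge,
a hydrophobicity value and Lennard-Jones wall parameters; whole-molecule
descriptors (net charge, electric and hydrophobic dipoles about the centre
of mass) summarise the charge anisotropy that drives adsorption orientation.
"""
from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import biotite.structure as bst
import biotite.structure.io.pdb as bpdb

from ._constants import ANGSTROM_PER_NM
from .parameters import default_param_table

__all__ = [
    "AtomRecord", "AtomicStructure", "Trajectory", "CGBead", "CGProtein",
    "Descriptors", "StructureParseError", "read_structure", "write_structure",
    "read_trajectory", "write_trajectory", "coarse_grain", "net_charge",
    "dipoles",
]

WATER_NAMES = frozenset({"HOH", "WAT", "TIP3", "SOL", "DOD"})


class StructureParseError(ValueError):
    """Raised when PDB content cannot be parsed."""


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    chain_id: str
    position: np.ndarray  # (3,), Angstrom
    ins_code: str = ""


class AtomicStructure:
    """Ordered collection of atoms with per-atom annotation arrays.

    Coordinates are in Angstrom.  ``(chain_id, residue_id, ins_code, name)``
    is unique within a model.
    """

    def __init__(self, serial, name, element, res_name, res_id, chain_id,
                 coords, ins_code=None, source_id=""):
        n = len(name)
        self.serial = np.asarray(serial, dtype=int)
        self.name = np.asarray(name, dtype=object)
        self.element = np.asarray(element, dtype=object)
        self.res_name = np.asarray(res_name, dtype=object)
        self.res_id = np.asarray(res_id, dtype=int)
        self.chain_id = np.asarray(chain_id, dtype=object)
        self.ins_code = (np.asarray(ins_code, dtype=object)
                         if ins_code is not None
                         else np.full(n, "", dtype=object))
        self.coords = np.asarray(coords, dtype=float).reshape(n, 3)
        self.source_id = source_id
        if n == 0:
            raise StructureParseError("structure contains no atoms")
        if not np.all(np.isfinite(self.coords)):
            raise StructureParseError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.name)

    def __len__(self) -> int:
        return self.n_atoms

    def atom(self, i: int) -> AtomRecord:
        return AtomRecord(
            serial=int(self.serial[i]), name=str(self.name[i]),
            element=str(self.element[i]), residue_name=str(self.res_name[i]),
            residue_id=int(self.res_id[i]), chain_id=str(self.chain_id[i]),
            position=self.coords[i].copy(), ins_code=str(self.ins_code[i]),
        )

    def __iter__(self) -> Iterator[AtomRecord]:
        return (self.atom(i) for i in range(self.n_atoms))

    def residue_keys(self) -> list[tuple[str, int, str]]:
        """Unique (chain, residue_id, ins_code) keys in order of appearance."""
        seen: dict[tuple[str, int, str], None] = {}
        for c, r, ic in zip(self.chain_id, self.res_id, self.ins_code):
            seen.setdefault((str(c), int(r), str(ic)))
        return list(seen)

    def select(self, chain=None, res_ids=None, atom_names=None,
               elements=None) -> np.ndarray:
        """Boolean mask combining simple per-field criteria (AND)."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if chain is not None:
            chains = {chain} if isinstance(chain, str) else set(chain)
            mask &= np.isin(self.chain_id.astype(str), list(chains))
        if res_ids is not None:
            mask &= np.isin(self.res_id, np.asarray(list(res_ids)))
        if atom_names is not None:
            names = {atom_names} if isinstance(atom_names, str) else set(atom_names)
            mask &= np.isin(self.name.astype(str), list(names))
        if elements is not None:
            els = {elements} if isinstance(elements, str) else set(elements)
            mask &= np.isin(self.element.astype(str), list(els))
        return mask

    @classmethod
    def from_biotite(cls, arr: bst.AtomArray, source_id: str = "") -> "AtomicStructure":
        serial = (arr.get_annotation("atom_id")
                  if "atom_id" in arr.get_annotation_categories()
                  else np.arange(1, arr.array_length() + 1))
        ins = (arr.get_annotation("ins_code")
               if "ins_code" in arr.get_annotation_categories()
               else None)
        return cls(serial, arr.atom_name, arr.element, arr.res_name,
                   arr.res_id, arr.chain_id, arr.coord, ins, source_id)

    def to_biotite(self, coords: np.ndarray | None = None) -> bst.AtomArray:
        arr = bst.AtomArray(self.n_atoms)
        arr.coord = np.asarray(self.coords if coords is None else coords,
                               dtype=np.float32)
        arr.atom_name = self.name.astype(str)
        arr.element = self.element.astype(str)
        arr.res_name = self.res_name.astype(str)
        arr.res_id = self.res_id
        arr.chain_id = self.chain_id.astype(str)
        arr.set_annotation("ins_code", self.ins_code.astype(str))
        return arr


@dataclass
class Trajectory:
    """Ordered coordinate frames over a fixed topology (Angstrom)."""

    topology: AtomicStructure
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    frame_stride_ps: float | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} does not match "
                f"topology ({self.topology.n_atoms} atoms)")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


@dataclass(frozen=True)
class CGBead:
    residue_name: str
    residue_id: int
    chain_id: str
    position: np.ndarray  # (3,), nm
    charge: float  # elementary charges
    hydrophobicity: float
    vdw_epsilon: float  # kJ/mol
    vdw_sigma: float  # nm


class CGProtein:
    """Rigid united-residue bead model: one bead per residue at the Ca.

    Positions are in nm.  The molecule is rigid: only whole-body poses are
    ever applied, so inter-bead distances are invariant.  Equal bead masses
    are assumed, making the centre of mass the coordinate mean.
    """

    def __init__(self, positions_nm, charges, hydrophobicity, sigma, epsilon,
                 res_names, res_ids, chain_ids, source_id=""):
        self.positions = np.asarray(positions_nm, dtype=float).reshape(-1, 3)
        n = len(self.positions)
        self.charges = np.asarray(charges, dtype=float).reshape(n)
        self.hydrophobicity = np.asarray(hydrophobicity, dtype=float).reshape(n)
        self.sigma = np.asarray(sigma, dtype=float).reshape(n)
        self.epsilon = np.asarray(epsilon, dtype=float).reshape(n)
        self.res_names = list(res_names)
        self.res_ids = [int(r) for r in res_ids]
        self.chain_ids = [str(c) for c in chain_ids]
        self.source_id = source_id
        if np.any(self.sigma <= 0):
            raise ValueError("vdw sigma must be positive")
        if np.any(self.epsilon < 0):
            raise ValueError("vdw epsilon must be non-negative")

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def center_of_mass(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    @property
    def body_coords(self) -> np.ndarray:
        """Bead positions relative to the centre of mass (nm)."""
        return self.positions - self.center_of_mass

    @property
    def beads(self) -> list[CGBead]:
        return [CGBead(self.res_names[i], self.res_ids[i], self.chain_ids[i],
                       self.positions[i].copy(), float(self.charges[i]),
                       float(self.hydrophobicity[i]), float(self.epsilon[i]),
                       float(self.sigma[i]))
                for i in range(self.n_beads)]

    def to_json(self) -> str:
        payload = {
            "source_id": self.source_id,
            "positions_nm": self.positions.tolist(),
            "charges": self.charges.tolist(),
            "hydrophobicity": self.hydrophobicity.tolist(),
            "sigma": self.sigma.tolist(),
            "epsilon": self.epsilon.tolist(),
            "res_names": self.res_names,
            "res_ids": self.res_ids,
            "chain_ids": self.chain_ids,
        }
        return json.dumps(payload, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "CGProtein":
        d = json.loads(text)
        return cls(d["positions_nm"], d["charges"], d["hydrophobicity"],
                   d["sigma"], d["epsilon"], d["res_names"], d["res_ids"],
                   d["chain_ids"], d.get("source_id", ""))


@dataclass(frozen=True)
class Descriptors:
    """Whole-molecule charge/hydrophobicity descriptors about the COM."""

    net_charge: float  # elementary charges
    electric_dipole: np.ndarray  # (3,), e*nm
    hydrophobic_dipole: np.ndarray  # (3,), scale*nm


# ---------------------------------------------------------------------------
# reading / writing

def _as_pdb_file(source: str | Path) -> bpdb.PDBFile:
    if isinstance(source, Path) or (isinstance(source, str)
                                    and "\n" not in source
                                    and Path(source).exists()):
        text = Path(source).read_text()
    else:
        text = str(source)
    try:
        return bpdb.PDBFile.read(io.StringIO(text))
    except Exception as exc:  # biotite raises various parse errors
        raise StructureParseError(f"cannot parse PDB content: {exc}") from exc


def _get_model(pdb_file: bpdb.PDBFile, model_index: int,
               include_hetero: bool, include_water: bool):
    n_models = pdb_file.get_model_count()
    if model_index < 0 or model_index >= n_models:
        raise StructureParseError(
            f"model_index {model_index} out of range (file has {n_models})")
    try:
        arr = pdb_file.get_structure(model=model_index + 1,
                                     altloc="occupancy",
                                     extra_fields=["atom_id"])
    except Exception as exc:
        raise StructureParseError(f"malformed PDB record: {exc}") from exc
    mask = np.ones(arr.array_length(), dtype=bool)
    if not include_water:
        mask &= ~np.isin(arr.res_name, list(WATER_NAMES))
    if not include_hetero:
        mask &= ~arr.hetero
    arr = arr[mask]
    if arr.array_length() == 0:
        raise StructureParseError("selection left no atoms")
    return arr


def read_structure(source: str | Path, model_index: int = 0, *,
                   include_hetero: bool = False, include_water: bool = False,
                   source_id: str = "") -> AtomicStructure:
    """Read one MODEL of a PDB file (default the first).

    ``source`` may be PDB text or a path.  Alternate locations resolve to
    the highest-occupancy (ties: first) conformer; waters and hetero
    ligands are excluded unless the flags say otherwise.
    """
    pdb_file = _as_pdb_file(source)
    arr = _get_model(pdb_file, model_index, include_hetero, include_water)
    if not source_id and isinstance(source, (str, Path)) and "\n" not in str(source):
        source_id = Path(source).stem
    return AtomicStructure.from_biotite(arr, source_id=source_id)


def read_trajectory(source: str | Path,
                    topology: AtomicStructure | None = None, *,
                    frame_stride_ps: float | None = None,
                    include_hetero: bool = False) -> Trajectory:
    """Read a trajectory: multi-MODEL PDB, or DCD/XTC via the mdtraj adapter.

    For binary formats a ``topology`` is mandatory.  All frames must have the
    same atom count; a mismatch raises naming the offending frame.
    """
    path = Path(source) if "\n" not in str(source) else None
    if path is not None and path.suffix.lower() in {".dcd", ".xtc"}:
        return _read_binary_trajectory(path, topology, frame_stride_ps)
    pdb_file = _as_pdb_file(source)
    n_models = pdb_file.get_model_count()
    models = [_get_model(pdb_file, i, include_hetero, False)
              for i in range(n_models)]
    n0 = models[0].array_length()
    for i, m in enumerate(models):
        if m.array_length() != n0:
            raise StructureParseError(
                f"frame {i} has {m.array_length()} atoms, expected {n0}")
    top = topology or AtomicStructure.from_biotite(models[0])
    if top.n_atoms != n0:
        raise ValueError(
            f"frame 0 has {n0} atoms, topology has {top.n_atoms}")
    frames = np.stack([m.coord for m in models]).astype(float)
    return Trajectory(top, frames, frame_stride_ps)


def _read_binary_trajectory(path: Path, topology: AtomicStructure | None,
                            frame_stride_ps: float | None) -> Trajectory:
    if topology is None:
        raise ValueError("binary trajectories require an explicit topology")
    import mdtraj  # optional adapter

    # mdtraj wants a topology file; round-trip through a PDB string
    import tempfile
    with tempfile.NamedTemporaryFile("w", suffix=".pdb", delete=False) as fh:
        fh.write(write_structure(topology))
        top_path = fh.name
    traj = mdtraj.load(str(path), top=top_path)
    frames = np.asarray(traj.xyz, dtype=float) * ANGSTROM_PER_NM
    if frames.shape[1] != topology.n_atoms:
        raise ValueError(
            f"frame 0 has {frames.shape[1]} atoms, topology has "
            f"{topology.n_atoms}")
    return Trajectory(topology, frames, frame_stride_ps)


def write_structure(structure: AtomicStructure,
                    path: str | Path | None = None) -> str:
    """Write a structure as PDB text; optionally also to ``path``."""
    pdb_file = bpdb.PDBFile()
    pdb_file.set_structure(structure.to_biotite())
    buf = io.StringIO()
    pdb_file.write(buf)
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


def write_trajectory(traj: Trajectory,
                     path: str | Path | None = None) -> str:
    """Write a trajectory as multi-MODEL PDB text."""
    n = traj.topology.n_atoms
    stack = bst.AtomArrayStack(traj.n_frames, n)
    template = traj.topology.to_biotite()
    for cat in template.get_annotation_categories():
        stack.set_annotation(cat, template.get_annotation(cat))
    stack.coord = traj.frames.astype(np.float32)
    pdb_file = bpdb.PDBFile()
    pdb_file.set_structure(stack)
    buf = io.StringIO()
    pdb_file.write(buf)
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# coarse-graining and descriptors

def coarse_grain(structure: AtomicStructure,
                 params: dict[str, dict[str, float]] | None = None
                 ) -> CGProtein:
    """Reduce each residue to one bead at its alpha-carbon.

    Coordinates convert Angstrom -> nm.  Charges, hydrophobicity and LJ
    parameters come from ``params`` (default table if omitted); unknown
    residue types raise unless the table has a ``"*"`` fallback entry.
    Residues without a CA atom raise, listing them.
    """
    table = params if params is not None else default_param_table()
    is_ca = structure.select(atom_names="CA")
    ca_index: dict[tuple[str, int, str], int] = {}
    for i in np.nonzero(is_ca)[0]:
        key = (str(structure.chain_id[i]), int(structure.res_id[i]),
               str(structure.ins_code[i]))
        ca_index.setdefault(key, int(i))

    keys = structure.residue_keys()
    missing = [k for k in keys if k not in ca_index]
    if missing:
        raise ValueError(
            "residues without a CA atom: "
            + ", ".join(f"{c}:{r}{ic}" for c, r, ic in missing))

    pos, q, h, sig, eps, names, rids, chains = [], [], [], [], [], [], [], []
    for key in keys:
        i = ca_index[key]
        res = str(structure.res_name[i])
        entry = table.get(res) or table.get("*")
        if entry is None:
            raise KeyError(
                f"no parameters for residue type {res!r} and no '*' fallback")
        pos.append(structure.coords[i] / ANGSTROM_PER_NM)
        q.append(entry["charge"])
        h.append(entry["hydrophobicity"])
        sig.append(entry["sigma"])
        eps.append(entry["epsilon"])
        names.append(res)
        rids.append(key[1])
        chains.append(key[0])
    return CGProtein(pos, q, h, sig, eps, names, rids, chains,
                     source_id=structure.source_id)


def net_charge(cg: CGProtein) -> int:
    """Sum of bead charges, in elementary charges."""
    return int(round(float(cg.charges.sum())))


def dipoles(cg: CGProtein,
            hydrophobicity_scale: dict[str, float] | None = None
            ) -> Descriptors:
    """Electric and hydrophobic dipoles about the centre of mass.

    mu_e = sum_i q_i (r_i - r_com)  [e*nm];  mu_h likewise with the
    hydrophobicity values (optionally overridden by ``hydrophobicity_scale``
    mapping residue names to values).  For a neutral molecule mu_e is
    translation invariant; otherwise it depends on the COM origin, which is
    the documented convention.
    """
    rel = cg.body_coords
    h = cg.hydrophobicity
    if hydrophobicity_scale is not None:
        h = np.array([hydrophobicity_scale[r] for r in cg.res_names])
    mu_e = (cg.charges[:, None] * rel).sum(axis=0)
    mu_h = (h[:, None] * rel).sum(axis=0)
    return Descriptors(float(cg.charges.sum()), mu_e, mu_h)
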