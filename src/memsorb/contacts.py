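"""Interface statistics on all-atom trajectories.

Definitions used throughout:

* salt bridge — an acidic oxygen (ASP OD1/OD2, GLU OE1/OE2, optionally the
  C-terminal OXT) and a basic nitrogen (LYS NZ, ARG NE/NH1/NH2, optionally
  HIS ND1/NE2) closer than 4 A;
* hydrogen bond — polarised O/N/S heavy atoms closer than 3.5 A whose
  D-H...A arrangement deviates from linearity by less than 30 deg (the
  H-D-A convention is selectable);
* occupancy — the percentage of analysed frames in which a residue pair has
  at least one qualifying atom-pair event (multiple atom pairs in one frame
  count once per residue pair).

Neighbour searches use a KD-tree; the brute-force all-pairs formulation
serves as the oracle in the test suite.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._constants import COULOMB_KJ_A
from .structio import AtomicStructure, Trajectory

__all__ = ["InteractionEvent", "OccupancyRecord", "detect_salt_bridges",
           "detect_hbonds", "occupancy_table", "occupancy_frame",
           "contact_numbers", "pair_interaction_energy"]

ACIDIC_OXYGENS = {("ASP", "OD1"), ("ASP", "OD2"),
                  ("GLU", "OE1"), ("GLU", "OE2")}
BASIC_NITROGENS = {("LYS", "NZ"),
                   ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2")}
HIS_NITROGENS = {("HIS", "ND1"), ("HIS", "NE2")}
POLAR_ELEMENTS = ("O", "N", "S")

AtomKey = tuple[str, int, str, str]  # chain, residue_id, residue_name, atom


@dataclass(frozen=True)
class InteractionEvent:
    kind: str  # "salt_bridge" | "h_bond"
    atom_a: AtomKey
    atom_b: AtomKey
    frame: int = 0

    @property
    def residue_pair(self):
        ra = self.atom_a[:3]
        rb = self.atom_b[:3]
        return tuple(sorted((ra, rb)))


@dataclass(frozen=True)
class OccupancyRecord:
    kind: str
    chain_a: str
    residue_id_a: int
    residue_name_a: str
    chain_b: str
    residue_id_b: int
    residue_name_b: str
    occupancy: float  # percent of analysed frames


def _atom_key(top: AtomicStructure, i: int) -> AtomKey:
    return (str(top.chain_id[i]), int(top.res_id[i]),
            str(top.res_name[i]), str(top.name[i]))


def _residue_token(top: AtomicStructure, i: int):
    return (str(top.chain_id[i]), int(top.res_id[i]))


def _pairs_within(coords_a, coords_b, cutoff) -> list[tuple[int, int]]:
    """Index pairs (into a and b) with distance strictly under cutoff."""
    if len(coords_a) == 0 or len(coords_b) == 0:
        return []
    tree = cKDTree(coords_b)
    out = []
    for ia, neigh in enumerate(tree.query_ball_point(coords_a, cutoff)):
        for ib in neigh:
            if np.linalg.norm(coords_a[ia] - coords_b[ib]) < cutoff:
                out.append((ia, ib))
    return out


def detect_salt_bridges(coords: np.ndarray, topology: AtomicStructure,
                        cutoff: float = 4.0, *,
                        include_oxt: bool = False,
                        include_his: bool = False,
                        frame: int = 0) -> list[InteractionEvent]:
    """Salt-bridge events in one frame (coordinates in Angstrom)."""
    coords = np.asarray(coords, dtype=float)
    acid = set(ACIDIC_OXYGENS)
    base = set(BASIC_NITROGENS)
    if include_his:
        base |= HIS_NITROGENS
    pairs_rn = [(str(r), str(n)) for r, n in
                zip(topology.res_name, topology.name)]
    ai = [i for i, rn in enumerate(pairs_rn)
          if rn in acid or (include_oxt and rn[1] == "OXT")]
    bi = [i for i, rn in enumerate(pairs_rn) if rn in base]
    events = []
    for ia, ib in _pairs_within(coords[ai], coords[bi], cutoff):
        i, j = ai[ia], bi[ib]
        if _residue_token(topology, i) == _residue_token(topology, j):
            continue
        events.append(InteractionEvent("salt_bridge", _atom_key(topology, i),
                                       _atom_key(topology, j), frame))
    return events


def _hydrogen_map(coords: np.ndarray, topology: AtomicStructure,
                  heavy_idx: np.ndarray) -> dict[int, list[int]]:
    """heavy atom index -> hydrogens covalently attached (distance < 1.25 A,
    same residue)."""
    is_h = topology.select(elements="H")
    h_idx = np.nonzero(is_h)[0]
    mapping: dict[int, list[int]] = {}
    if len(h_idx) == 0 or len(heavy_idx) == 0:
        return mapping
    tree = cKDTree(coords[heavy_idx])
    dist, nearest = tree.query(coords[h_idx], k=1,
                               distance_upper_bound=1.25)
    for hi, (d, nh) in zip(h_idx, zip(dist, nearest)):
        if not np.isfinite(d):
            continue
        heavy = int(heavy_idx[nh])
        if _residue_token(topology, heavy) == _residue_token(topology, hi):
            mapping.setdefault(heavy, []).append(int(hi))
    return mapping


def detect_hbonds(coords: np.ndarray, topology: AtomicStructure,
                  d_cutoff: float = 3.5, angle_cutoff: float = 30.0, *,
                  fallback_no_hydrogen: bool = False,
                  angle_convention: str = "dha",
                  frame: int = 0) -> list[InteractionEvent]:
    """Hydrogen-bond events in one frame.

    ``angle_convention='dha'`` (default) accepts a pair when the D-H...A
    angle deviates from linearity by less than ``angle_cutoff`` degrees;
    ``'hda'`` instead bounds the H-D-A angle.  Without hydrogens in the
    topology the geometric test needs ``fallback_no_hydrogen=True`` to fall
    back to the distance criterion alone.
    """
    coords = np.asarray(coords, dtype=float)
    polar = np.nonzero(topology.select(elements=POLAR_ELEMENTS))[0]
    if len(polar) == 0:
        return []
    h_map = _hydrogen_map(coords, topology, polar)
    has_h = topology.select(elements="H").any()
    if not has_h and not fallback_no_hydrogen:
        raise ValueError("topology has no hydrogens; set "
                         "fallback_no_hydrogen=True for a distance-only "
                         "criterion")
    events = []
    cp = coords[polar]
    for ia, ib in _pairs_within(cp, cp, d_cutoff):
        i, j = int(polar[ia]), int(polar[ib])
        if i >= j:
            continue
        if _residue_token(topology, i) == _residue_token(topology, j):
            continue
        ok = False
        if not has_h:
            ok = True
        else:
            for donor, acceptor in ((i, j), (j, i)):
                for h in h_map.get(donor, ()):  # noqa: B007
                    ok = _angle_ok(coords[donor], coords[h],
                                   coords[acceptor], angle_cutoff,
                                   angle_convention)
                    if ok:
                        break
                if ok:
                    break
        if ok:
            events.append(InteractionEvent("h_bond", _atom_key(topology, i),
                                           _atom_key(topology, j), frame))
    return events


def _angle_ok(d: np.ndarray, h: np.ndarray, a: np.ndarray,
              angle_cutoff: float, convention: str) -> bool:
    if convention == "dha":
        v1, v2 = d - h, a - h
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        deviation = 180.0 - np.degrees(np.arccos(np.clip(cosang, -1, 1)))
        return deviation < angle_cutoff
    if convention == "hda":
        v1, v2 = h - d, a - d
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        return np.degrees(np.arccos(np.clip(cosang, -1, 1))) < angle_cutoff
    raise ValueError(f"unknown angle convention {convention!r}")


def occupancy_table(traj: Trajectory,
                    window: tuple[int, int] | None = None,
                    min_occupancy: float = 10.0, *,
                    sb_cutoff: float = 4.0, hb_cutoff: float = 3.5,
                    hb_angle: float = 30.0,
                    fallback_no_hydrogen: bool = True,
                    include_oxt: bool = False,
                    include_his: bool = False) -> list[OccupancyRecord]:
    """Residue-pair occupancies over a frame window.

    ``window`` is a half-open (start, stop) frame range, defaulting to the
    whole trajectory — callers declare the equilibrated portion themselves.
    Multiple atom-pair events count once per residue pair per frame;
    symmetric pairs are merged.  Rows under ``min_occupancy`` percent are
    dropped (a presentation filter: pass 0 to keep everything).
    """
    start, stop = window if window is not None else (0, traj.n_frames)
    if stop <= start:
        raise ValueError("empty frame window")
    top = traj.topology
    counts: dict[tuple, int] = {}
    names: dict[tuple, tuple] = {}
    n_frames = 0
    for f in range(start, stop):
        n_frames += 1
        coords = traj.frames[f]
        events = detect_salt_bridges(coords, top, sb_cutoff, frame=f,
                                     include_oxt=include_oxt,
                                     include_his=include_his)
        events += detect_hbonds(coords, top, hb_cutoff, hb_angle, frame=f,
                                fallback_no_hydrogen=fallback_no_hydrogen)
        seen = set()
        for ev in events:
            key = (ev.kind, ev.residue_pair)
            if key in seen:
                continue
            seen.add(key)
            counts[key] = counts.get(key, 0) + 1
            names[key] = ev.residue_pair
    records = []
    for key, c in counts.items():
        kind = key[0]
        ra, rb = names[key]
        occ = 100.0 * c / n_frames
        if occ < min_occupancy:
            continue
        records.append(OccupancyRecord(kind, ra[0], ra[1], ra[2],
                                       rb[0], rb[1], rb[2], occ))
    records.sort(key=lambda r: (-r.occupancy, r.chain_a, r.residue_id_a))
    return records


def occupancy_frame(records: Sequence[OccupancyRecord]) -> pd.DataFrame:
    """Records as a table with the conventional columns."""
    return pd.DataFrame([{
        "Kind": r.kind,
        "Subunit A": r.chain_a, "Residue 1": f"{r.residue_name_a}{r.residue_id_a}",
        "Subunit B": r.chain_b, "Residue 2": f"{r.residue_name_b}{r.residue_id_b}",
        "Occupancy (%)": round(r.occupancy, 2),
    } for r in records])


def contact_numbers(traj: Trajectory, group_a: np.ndarray,
                    group_b: np.ndarray, cutoff: float = 4.0,
                    window: tuple[int, int] | None = None) -> pd.DataFrame:
    """Average number of group-B residues contacting each group-A residue.

    A contact is any heavy-atom pair under ``cutoff`` Angstrom.  Groups are
    boolean atom masks and must not overlap.
    """
    group_a = np.asarray(group_a, dtype=bool)
    group_b = np.asarray(group_b, dtype=bool)
    if (group_a & group_b).any():
        raise ValueError("groups overlap")
    top = traj.topology
    heavy = ~top.select(elements="H")
    ia = np.nonzero(group_a & heavy)[0]
    ib = np.nonzero(group_b & heavy)[0]
    res_a = [_residue_token(top, i) for i in ia]
    res_b = [_residue_token(top, i) for i in ib]
    order_a = list(dict.fromkeys(res_a))
    start, stop = window if window is not None else (0, traj.n_frames)
    if stop <= start:
        raise ValueError("empty frame window")
    totals = {r: 0.0 for r in order_a}
    for f in range(start, stop):
        coords = traj.frames[f]
        partners: dict[tuple, set] = {r: set() for r in order_a}
        for pa, pb in _pairs_within(coords[ia], coords[ib], cutoff):
            partners[res_a[pa]].add(res_b[pb])
        for r in order_a:
            totals[r] += len(partners[r])
    n_frames = stop - start
    return pd.DataFrame({
        "chain": [r[0] for r in order_a],
        "residue_id": [r[1] for r in order_a],
        "mean_contacts": [totals[r] / n_frames for r in order_a],
    })


def pair_interaction_energy(traj: Trajectory, group_a: np.ndarray,
                            group_b: np.ndarray,
                            ff_params: dict[tuple[str, str], dict],
                            *, dielectric: float = 1.0,
                            cutoff: float = 10.0,
                            window: tuple[int, int] | None = None
                            ) -> tuple[float, float]:
    """(electrostatic, van der Waals) inter-group energies in kJ/mol.

    Coulomb ``k q_i q_j / (eps_r r)`` plus Lennard-Jones
    ``4 eps [(sigma/r)^12 - (sigma/r)^6]`` with Lorentz-Berthelot
    combination, summed over inter-group atom pairs within ``cutoff``
    Angstrom and averaged over the frame window.  ``ff_params`` maps
    ``(residue_name, atom_name)`` to ``{charge, sigma, epsilon}`` (sigma in
    Angstrom, epsilon in kJ/mol); missing entries raise, listing them.
    """
    group_a = np.asarray(group_a, dtype=bool)
    group_b = np.asarray(group_b, dtype=bool)
    if (group_a & group_b).any():
        raise ValueError("groups overlap")
    top = traj.topology
    ia = np.nonzero(group_a)[0]
    ib = np.nonzero(group_b)[0]

    def params_for(idx):
        missing, q, sig, eps = [], [], [], []
        for i in idx:
            key = (str(top.res_name[i]), str(top.name[i]))
            entry = ff_params.get(key)
            if entry is None:
                missing.append(f"{key[0]}:{key[1]}")
            else:
                q.append(entry["charge"])
                sig.append(entry["sigma"])
                eps.append(entry["epsilon"])
        if missing:
            raise KeyError("missing force-field parameters for atoms: "
                           + ", ".join(sorted(set(missing))))
        return np.array(q), np.array(sig), np.array(eps)

    qa, siga, epsa = params_for(ia)
    qb, sigb, epsb = params_for(ib)
    start, stop = window if window is not None else (0, traj.n_frames)
    if stop <= start:
        raise ValueError("empty frame window")
    e_sum = v_sum = 0.0
    for f in range(start, stop):
        coords = traj.frames[f]
        for pa, pb in _pairs_within(coords[ia], coords[ib], cutoff):
            r = float(np.linalg.norm(coords[ia[pa]] - coords[ib[pb]]))
            e_sum += COULOMB_KJ_A * qa[pa] * qb[pb] / (dielectric * r)
            sig = 0.5 * (siga[pa] + sigb[pb])
            eps = np.sqrt(epsa[pa] * epsb[pb])
            sr6 = (sig / r) ** 6
            v_sum += 4.0 * eps * (sr6 * sr6 - sr6)
    n_frames = stop - start
    return e_sum / n_frames, v_sum / n_frames
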