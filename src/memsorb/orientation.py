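"""Orientation-level analysis of PTMC sample streams.

Turns the physical-rung sample stream into the adsorption-level results:
the minimum-energy pose, its orientation class (one-end-on, two-end-on,
lying-on-side, arch-on, desorbed), per-residue contact statistics, and
pseudo free-energy surfaces over 2D projections such as
(cos theta_electric, cos theta_hydrophobic).

"Ends" of an elongated molecule are the first/last fraction of beads
ordered along its principal long axis; "mid" is the central third.  A bead
is in contact when its centre is below the contact cutoff height (default
0.7 nm, about bead-wall VDW contact).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from ._constants import GAS_CONSTANT
from .structio import CGProtein
from .surface import SurfaceParams, EnergyBreakdown, heights_energy
from .ptmc import Pose, PTMCResult, ReplicaSamples

__all__ = ["OrientationClass", "ContactReport", "PseudoFES",
           "minimum_energy_pose", "polish_pose", "classify_orientation",
           "contact_residues", "density_map", "principal_axis"]

DEFAULT_CONTACT_CUTOFF_NM = 0.7


@dataclass(frozen=True)
class OrientationClass:
    label: str  # one-end-on | two-end-on | lying-on-side | arch-on | desorbed
    end_contacts: tuple[bool, bool]
    mid_contact: bool
    contact_fraction: float


@dataclass
class ContactReport:
    """Per-residue membrane-contact statistics over production frames."""

    frame: pd.DataFrame  # chain, residue_id, residue_name, min_height_nm,
    #                      contact_fraction — sorted by fraction descending
    cutoff_nm: float
    key_threshold: float = 0.5

    @property
    def key_residues(self) -> list[str]:
        """Residues in contact in more than ``key_threshold`` of frames,
        formatted one-letter-style as e.g. ``K56`` (author numbering)."""
        sel = self.frame[self.frame.contact_fraction > self.key_threshold]
        return [f"{_ONE_LETTER.get(rn, 'X')}{rid}"
                for rn, rid in zip(sel.residue_name, sel.residue_id)]


_ONE_LETTER = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def minimum_energy_pose(result: PTMCResult,
                        rung: int | None = None
                        ) -> tuple[Pose, EnergyBreakdown]:
    """Lowest-U_tot production sample at the physical rung.

    Ties break to the earliest cycle (argmin's first occurrence over the
    cycle-ordered stream).
    """
    rep = result.replicas[result.target_index if rung is None else rung]
    if rep.n_samples == 0:
        raise ValueError("no production samples at the requested rung")
    i = int(np.argmin(rep.u_tot))
    return rep.pose(i), EnergyBreakdown(float(rep.u_vdw[i]),
                                        float(rep.u_ele[i]))


def polish_pose(pose: Pose, cg: CGProtein, sp: SurfaceParams,
                maxiter: int = 400) -> tuple[Pose, EnergyBreakdown]:
    """Greedy local refinement of a pose (Nelder-Mead over height and
    orientation); lateral position is irrelevant to the energy."""
    body = cg.body_coords
    r0 = Rotation.from_quat(pose.quat)

    def u_of(x):
        rmat = (Rotation.from_rotvec(x[1:4]) * r0).as_matrix()
        z = x[0] + body @ rmat[2]
        u_vdw, u_ele = heights_energy(cg.charges, cg.epsilon, cg.sigma, z, sp)
        u = u_vdw + u_ele
        return u if np.isfinite(u) else 1e9

    x0 = np.array([pose.com[2], 0.0, 0.0, 0.0])
    res = minimize(u_of, x0, method="Nelder-Mead",
                   options={"maxiter": maxiter, "xatol": 1e-5,
                            "fatol": 1e-8})
    z_com, rv = float(res.x[0]), res.x[1:4]
    rot = Rotation.from_rotvec(rv) * r0
    new = Pose(np.array([pose.com[0], pose.com[1], z_com]), rot.as_quat())
    z = new.bead_heights(cg)
    u_vdw, u_ele = heights_energy(cg.charges, cg.epsilon, cg.sigma, z, sp)
    return new, EnergyBreakdown(u_vdw, u_ele)


def principal_axis(cg: CGProtein) -> np.ndarray:
    """Unit vector of the molecule's principal long axis (body frame).

    Raises for near-spherical molecules where the axis is ill-defined.
    """
    body = cg.body_coords
    cov = body.T @ body / len(body)
    w, v = np.linalg.eigh(cov)
    if w[-1] < 4.0 * w[-2] or w[-1] <= 0:
        raise ValueError(
            "degenerate principal axis (molecule near-spherical); define "
            "the ends explicitly via the `axis` argument")
    return v[:, -1]


def _end_mid_indices(cg: CGProtein, end_fraction: float,
                     axis: np.ndarray | None):
    ax = principal_axis(cg) if axis is None else np.asarray(axis, float)
    t = cg.body_coords @ ax
    order = np.argsort(t, kind="stable")
    n = len(order)
    k = max(1, int(round(end_fraction * n)))
    third = n // 3
    return order[:k], order[-k:], order[third:n - third]


def classify_orientation(pose: Pose, cg: CGProtein,
                         contact_cutoff: float = DEFAULT_CONTACT_CUTOFF_NM,
                         end_fraction: float = 0.2,
                         axis: np.ndarray | None = None) -> OrientationClass:
    """Classify an adsorbed pose by its end/mid contact pattern.

    Cascade (first match wins): no bead in contact -> desorbed; mid in
    contact and at least half the beads in contact -> lying-on-side; both
    ends -> two-end-on; exactly one end and mid clear -> one-end-on;
    remaining mid-involving patterns -> arch-on.  Invariant under rotation
    about the surface normal and lateral translation.
    """
    end1, end2, mid = _end_mid_indices(cg, end_fraction, axis)
    z = pose.bead_heights(cg)
    contact = z < contact_cutoff
    frac = float(contact.mean())
    e1, e2 = bool(contact[end1].any()), bool(contact[end2].any())
    m = bool(contact[mid].any())
    if not contact.any():
        label = "desorbed"
    elif m and frac >= 0.5:
        label = "lying-on-side"
    elif e1 and e2:
        label = "two-end-on"
    elif (e1 != e2) and not m:
        label = "one-end-on"
    else:
        label = "arch-on"
    return OrientationClass(label, (e1, e2), m, frac)


def contact_residues(result: PTMCResult, cg: CGProtein,
                     contact_cutoff: float = DEFAULT_CONTACT_CUTOFF_NM,
                     key_threshold: float = 0.5) -> ContactReport:
    """Per-residue contact fractions over the physical rung's production
    frames: fraction of frames with the bead centre below the cutoff."""
    rep = result.target
    if rep.n_samples == 0:
        raise ValueError("no production samples")
    body = cg.body_coords
    rmats = Rotation.from_quat(rep.quat).as_matrix()  # (S, 3, 3)
    heights = rep.com[:, 2][:, None] + rmats[:, 2, :] @ body.T  # (S, n)
    frac = (heights < contact_cutoff).mean(axis=0)
    min_h = heights.min(axis=0)
    df = pd.DataFrame({
        "chain": cg.chain_ids, "residue_id": cg.res_ids,
        "residue_name": cg.res_names, "min_height_nm": min_h,
        "contact_fraction": frac,
    }).sort_values(["contact_fraction", "residue_id"],
                   ascending=[False, True], kind="stable",
                   ignore_index=True)
    return ContactReport(df, contact_cutoff, key_threshold)


@dataclass
class PseudoFES:
    """Normalised 2D sampling density and pseudo free-energy surface."""

    counts: np.ndarray
    density: np.ndarray
    free_energy: np.ma.MaskedArray  # kJ/mol, min-shifted; empty bins masked
    x_edges: np.ndarray
    y_edges: np.ndarray
    temperature: float


def plot_density(fes: "PseudoFES", path, xlabel="cos θ (electric)",
                 ylabel="cos θ (hydrophobic)", title=None):
    """Contour plot of a pseudo free-energy surface to a PNG/PDF file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xc = 0.5 * (fes.x_edges[:-1] + fes.x_edges[1:])
    yc = 0.5 * (fes.y_edges[:-1] + fes.y_edges[1:])
    fig, ax = plt.subplots(figsize=(4.5, 3.8))
    im = ax.contourf(xc, yc, fes.free_energy.T, levels=20, cmap="viridis")
    fig.colorbar(im, ax=ax, label="F (kJ/mol)")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def density_map(samples: np.ndarray, bins: int | tuple[int, int] = 50,
                temperature: float = 310.0,
                range_: tuple | None = None) -> PseudoFES:
    """Histogram 2D samples and derive F = -kB T ln(density).

    F is reported per mole (kJ/mol), shifted so its minimum is zero; empty
    bins are masked rather than infinite.
    """
    samples = np.asarray(samples, dtype=float).reshape(-1, 2)
    if samples.shape[0] < 1:
        raise ValueError("need at least one sample")
    if isinstance(bins, int) and bins < 1 or not np.all(np.asarray(bins) >= 1):
        raise ValueError("bins must be >= 1")
    counts, xe, ye = np.histogram2d(samples[:, 0], samples[:, 1], bins=bins,
                                    range=range_)
    area = np.outer(np.diff(xe), np.diff(ye))
    density = counts / counts.sum() / area
    masked = np.ma.masked_where(counts == 0, density)
    f = -GAS_CONSTANT * temperature * np.ma.log(masked)
    f = f - f.min()
    return PseudoFES(counts, density, f, xe, ye, temperature)
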