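"""Per-residue and collective fluctuation statistics.

Implements least-squares (Kabsch) superposition, per-frame RMSD, RMSF and
crystallographic B-factors (isotropic relation B = 8 pi^2 <dr^2> / 3), PCA
of aligned coordinates with mode-limited cross-correlation matrices, and
time-lagged independent component analysis (TICA) for slow collective
modes.

TICA solves the symmetrized generalized eigenproblem
``C_tau v = lambda C_0 v`` of the time-lagged covariance against the
instantaneous covariance (with shrinkage regularization of C_0) and orders
components by autocorrelation eigenvalue.  Input may span several
trajectory segments; lagged pairs are never formed across a segment
boundary, so independent trajectories (or the two protomers of a dimer)
can be concatenated safely.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .structio import Trajectory

__all__ = ["FluctuationProfile", "ModeDecomposition", "superpose",
           "align_frames", "rmsd_series", "rmsf_profile", "pca_modes",
           "correlation_matrix", "tica_modes"]

B_FACTOR_PREFACTOR = 8.0 * np.pi**2 / 3.0


@dataclass
class FluctuationProfile:
    """Per-atom RMSF (Angstrom) and derived isotropic B-factor (A^2)."""

    rmsf: np.ndarray
    chain: list[str]
    residue_id: list[int]
    residue_name: list[str]
    n_frames: int
    align_description: str = ""

    @property
    def b_factor(self) -> np.ndarray:
        return B_FACTOR_PREFACTOR * self.rmsf**2


@dataclass
class ModeDecomposition:
    """Collective-mode decomposition of aligned coordinate fluctuations.

    ``modes`` has one row per mode over the flattened (3N) selected
    coordinates.  PCA eigenvalues are variances (A^2), descending; TICA
    eigenvalues are autocorrelations at the chosen lag, descending.
    """

    method: str  # "PCA" | "TICA"
    eigenvalues: np.ndarray  # (k,)
    modes: np.ndarray  # (k, d)
    projections: np.ndarray  # (F, k)
    mean: np.ndarray  # (d,)
    lag: int | None = None
    segment_lengths: tuple[int, ...] | None = None

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)


# ---------------------------------------------------------------------------
# superposition

def _check_selection(coords: np.ndarray):
    if len(coords) < 3:
        raise ValueError("need at least 3 atoms for superposition")
    c = coords - coords.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise ValueError("selection is collinear or degenerate")


def superpose(mobile: np.ndarray, reference: np.ndarray,
              selection: np.ndarray | None = None
              ) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns (rotation, translation, rmsd) such that
    ``mobile @ rotation.T + translation`` minimises the RMSD over the
    selected atoms.  The rotation is proper (det = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    sel = (np.ones(len(mobile), dtype=bool) if selection is None
           else np.asarray(selection, dtype=bool))
    m, r = mobile[sel], reference[sel]
    _check_selection(m)
    mc, rc = m.mean(axis=0), r.mean(axis=0)
    h = (m - mc).T @ (r - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = rc - rot @ mc
    moved = m @ rot.T + trans
    rmsd = float(np.sqrt(((moved - r) ** 2).sum(axis=1).mean()))
    return rot, trans, rmsd


def _batch_superpose(frames: np.ndarray, reference: np.ndarray,
                     sel: np.ndarray) -> np.ndarray:
    """Superpose every frame onto the reference (all atoms transformed)."""
    m = frames[:, sel, :]
    r = reference[sel]
    mc = m.mean(axis=1, keepdims=True)
    rc = r.mean(axis=0)
    h = np.einsum("fni,nj->fij", m - mc, r - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(np.einsum("fij,fjk->fik",
                                        np.transpose(vt, (0, 2, 1)),
                                        np.transpose(u, (0, 2, 1)))))
    flip = np.ones((len(frames), 3))
    flip[:, 2] = d
    rot = np.einsum("fji,fj,fjk->fik",
                    vt, flip, np.transpose(u, (0, 2, 1)))
    # x' = R (x - mc) + rc
    return np.einsum("fij,fnj->fni", rot, frames - mc) + rc


def align_frames(traj: Trajectory, align_selection: np.ndarray | None = None,
                 reference: np.ndarray | None = None,
                 iterations: int = 3) -> np.ndarray:
    """Frames superposed onto the (iteratively refined) mean structure.

    With an explicit ``reference`` a single pass aligns to it; otherwise
    the reference is the trajectory mean, recomputed after each pass.
    """
    sel = (np.ones(traj.n_atoms, dtype=bool) if align_selection is None
           else np.asarray(align_selection, dtype=bool))
    _check_selection(traj.frames[0][sel])
    if reference is not None:
        return _batch_superpose(traj.frames, np.asarray(reference, float),
                                sel)
    aligned = traj.frames
    ref = aligned[0]
    for _ in range(iterations):
        aligned = _batch_superpose(traj.frames, ref, sel)
        ref = aligned.mean(axis=0)
    return aligned


def rmsd_series(traj: Trajectory, reference: np.ndarray,
                align_selection: np.ndarray | None = None,
                measure_selection: np.ndarray | None = None,
                align: bool = True) -> np.ndarray:
    """Per-frame RMSD to a reference after alignment.

    Each frame is superposed onto the reference on ``align_selection``
    (all atoms by default), then the RMSD is taken over
    ``measure_selection``.  ``align=False`` computes the raw RMSD in the
    frames' own coordinates.
    """
    reference = np.asarray(reference, dtype=float)
    if reference.shape != traj.frames[0].shape:
        raise ValueError("reference shape does not match trajectory frames")
    msel = (np.ones(traj.n_atoms, dtype=bool) if measure_selection is None
            else np.asarray(measure_selection, dtype=bool))
    if msel.sum() == 0:
        raise ValueError("empty measure selection")
    aligned = (align_frames(traj, align_selection, reference=reference)
               if align else traj.frames)
    diff = aligned[:, msel, :] - reference[msel]
    return np.sqrt((diff**2).sum(axis=2).mean(axis=1))


def rmsf_profile(traj: Trajectory,
                 align_selection: np.ndarray | None = None,
                 measure_selection: np.ndarray | None = None,
                 window: tuple[int, int] | None = None
                 ) -> FluctuationProfile:
    """Per-atom RMSF about the window-mean structure after superposition.

    RMSF_i = sqrt(<|r_i - <r_i>|^2>) in Angstrom; the B-factor follows the
    isotropic relation.  The window declares the equilibrated portion and
    defaults to all frames.
    """
    start, stop = window if window is not None else (0, traj.n_frames)
    if stop - start < 2:
        raise ValueError("need at least two frames for an RMSF")
    sub = Trajectory(traj.topology, traj.frames[start:stop],
                     traj.frame_stride_ps)
    msel = (np.ones(traj.n_atoms, dtype=bool) if measure_selection is None
            else np.asarray(measure_selection, dtype=bool))
    aligned = align_frames(sub, align_selection)
    mean = aligned.mean(axis=0)
    rmsf = np.sqrt(((aligned - mean) ** 2).sum(axis=2).mean(axis=0))[msel]
    idx = np.nonzero(msel)[0]
    top = traj.topology
    return FluctuationProfile(
        rmsf=rmsf,
        chain=[str(top.chain_id[i]) for i in idx],
        residue_id=[int(top.res_id[i]) for i in idx],
        residue_name=[str(top.res_name[i]) for i in idx],
        n_frames=stop - start,
    )


# ---------------------------------------------------------------------------
# collective modes

def _fix_sign(modes: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|.| component positive."""
    out = modes.copy()
    for k in range(len(out)):
        i = int(np.argmax(np.abs(out[k])))
        if out[k, i] < 0:
            out[k] = -out[k]
    return out


def pca_modes(traj: Trajectory,
              selection: np.ndarray | None = None,
              align_selection: np.ndarray | None = None,
              n_modes: int | None = None,
              align: bool = True) -> ModeDecomposition:
    """PCA of the aligned selected coordinates.

    Eigenvalues are variances along the modes, descending, and sum to the
    total variance of the aligned selection.  Projections of the training
    frames have zero mean by construction.  ``align=False`` skips the
    superposition for frames that are already in a common frame.
    """
    sel = (np.ones(traj.n_atoms, dtype=bool) if selection is None
           else np.asarray(selection, dtype=bool))
    aligned = align_frames(traj, align_selection) if align else traj.frames
    x = aligned[:, sel, :].reshape(traj.n_frames, -1)
    if n_modes is not None and traj.n_frames <= n_modes:
        raise ValueError("fewer frames than requested modes")
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    eig = s**2 / len(x)
    modes = _fix_sign(vt)
    proj = xc @ modes.T
    if n_modes is not None:
        eig, modes, proj = eig[:n_modes], modes[:n_modes], proj[:, :n_modes]
    return ModeDecomposition("PCA", eig, modes, proj, mean)


def correlation_matrix(decomp: ModeDecomposition,
                       n_modes: int | None = None) -> np.ndarray:
    """Residue-residue normalized cross-correlation from leading modes.

    C_ij = <dr_i . dr_j> / sqrt(<dr_i^2><dr_j^2>) with the covariance
    reconstructed from the first ``n_modes`` modes (all by default); with
    all modes this equals the direct correlation of the raw fluctuations.
    """
    k = decomp.n_modes if n_modes is None else int(n_modes)
    if k > decomp.n_modes:
        raise ValueError("n_modes exceeds available modes")
    d = decomp.modes.shape[1]
    if d % 3:
        raise ValueError("modes are not 3D-coordinate shaped")
    m = decomp.modes[:k].reshape(k, d // 3, 3)
    m = m * np.sqrt(decomp.eigenvalues[:k])[:, None, None]
    cov = np.einsum("kia,kja->ij", m, m)
    diag = np.sqrt(np.clip(np.diag(cov), 1e-300, None))
    return cov / np.outer(diag, diag)


def _as_segments(data, selection, align_selection) -> list[np.ndarray]:
    if isinstance(data, Trajectory):
        sel = (np.ones(data.n_atoms, dtype=bool) if selection is None
               else np.asarray(selection, dtype=bool))
        aligned = align_frames(data, align_selection)
        return [aligned[:, sel, :].reshape(data.n_frames, -1)]
    if isinstance(data, np.ndarray):
        return [np.asarray(data, dtype=float)]
    return [np.asarray(seg, dtype=float) for seg in data]


def tica_modes(data, lag: int, *,
               selection: np.ndarray | None = None,
               align_selection: np.ndarray | None = None,
               regularization: float = 1e-5,
               n_modes: int | None = None) -> ModeDecomposition:
    """TICA of feature time series (or of aligned Ca coordinates).

    ``data`` may be a Trajectory, a (F, d) feature array, or a list of
    segment arrays; lagged pairs are only formed within segments.  Solves
    the symmetrized generalized eigenproblem C_tau v = lambda C_0 v with
    shrinkage ``C_0 += regularization * tr(C_0)/d * I``; components are
    ordered by autocorrelation eigenvalue, which for the reversible
    estimate is real and at most ~1.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    segments = _as_segments(data, selection, align_selection)
    if all(len(s) <= lag for s in segments):
        raise ValueError("no segment longer than the lag")
    d = segments[0].shape[1]
    total = np.concatenate(segments, axis=0)
    mean = total.mean(axis=0)

    c0 = np.zeros((d, d))
    ct = np.zeros((d, d))
    n_pairs = 0
    for seg in segments:
        if len(seg) <= lag:
            continue
        a = seg[:-lag] - mean
        b = seg[lag:] - mean
        c0 += a.T @ a + b.T @ b
        ct += a.T @ b + b.T @ a
        n_pairs += 2 * len(a)
    c0 /= n_pairs
    ct /= n_pairs
    if regularization:
        c0 = c0 + regularization * np.trace(c0) / d * np.eye(d)
    try:
        eig, vec = scipy.linalg.eigh(ct, c0)
    except scipy.linalg.LinAlgError as exc:
        raise ValueError("singular instantaneous covariance; increase the "
                         "regularization") from exc
    order = np.argsort(eig)[::-1]
    eig, vec = eig[order], vec[:, order]
    modes = _fix_sign(vec.T)
    proj = (total - mean) @ modes.T
    if n_modes is not None:
        eig, modes, proj = eig[:n_modes], modes[:n_modes], proj[:, :n_modes]
    return ModeDecomposition("TICA", eig, modes, proj, mean, lag=lag,
                             segment_lengths=tuple(len(s) for s in segments))
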