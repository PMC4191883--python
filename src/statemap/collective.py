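"""Collective motions: anisotropic network model (ANM) and essential
dynamics PCA of conformer ensembles.

The ANM builds the 3N x 3N Hessian of a uniform-spring Cα elastic
network (pairwise interaction cutoff 15 Å by default); its low-frequency
nonzero modes approximate functional collective motions.  Essential
dynamics diagonalises the coordinate covariance of a superposed
trajectory; mode variance fractions quantify how much of the overall
dynamics each mode carries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import eigh
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from statemap.structio import Trajectory
from statemap.geometry import kabsch_rmsd

ZERO_MODE_TOL = 1e-8   # relative to the largest eigenvalue


class DisconnectedNetworkError(ValueError):
    def __init__(self, n_components: int, labels: np.ndarray):
        self.n_components = n_components
        self.labels = labels
        sizes = np.bincount(labels)
        super().__init__(
            f"elastic network is disconnected at this cutoff: "
            f"{n_components} components of sizes {sizes.tolist()}")


@dataclass
class ModeSet:
    """Eigen-modes of an ANM Hessian or a trajectory covariance."""

    kind: str                         # "anm" | "pca"
    eigenvalues: np.ndarray           # modes as returned (see kind)
    eigenvectors: np.ndarray          # (3N, n_modes), columns orthonormal
    variance_fractions: np.ndarray | None = None   # pca only
    all_eigenvalues: np.ndarray | None = None      # full spectrum
    mean_coords: np.ndarray | None = None          # pca fitting reference
    params: dict = field(default_factory=dict)

    @property
    def n_modes(self) -> int:
        return self.eigenvectors.shape[1]


def anm_hessian(coords: np.ndarray, cutoff: float = 15.0,
                force_constant: float = 1.0) -> np.ndarray:
    """Dense 3N x 3N ANM Hessian for a Cα coordinate set.

    Off-diagonal 3x3 block for a contact (i, j):
    ``-k * outer(d, d) / |d|^2`` with d = r_j - r_i; diagonal blocks make
    rows sum to zero (translational invariance).
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    hess = np.zeros((3 * n, 3 * n))
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    for i, j in pairs:
        d = coords[j] - coords[i]
        block = -force_constant * np.outer(d, d) / (d @ d)
        hess[3*i:3*i+3, 3*j:3*j+3] = block
        hess[3*j:3*j+3, 3*i:3*i+3] = block
        hess[3*i:3*i+3, 3*i:3*i+3] -= block
        hess[3*j:3*j+3, 3*j:3*j+3] -= block
    return hess


def _check_connected(coords: np.ndarray, cutoff: float) -> None:
    n = coords.shape[0]
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0 and n > 1:
        raise DisconnectedNetworkError(n, np.arange(n))
    data = np.ones(len(pairs))
    adj = csr_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        raise DisconnectedNetworkError(n_comp, labels)


def anm_modes(coords: np.ndarray, cutoff: float = 15.0,
              n_modes: int = 20, force_constant: float = 1.0) -> ModeSet:
    """Lowest nonzero ANM modes (ascending eigenvalue).

    Exactly 6 near-zero eigenvalues (rigid-body null space) are expected
    for a connected network and skipped.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 3:
        raise ValueError("ANM needs at least 3 Cα atoms")
    _check_connected(coords, cutoff)
    hess = anm_hessian(coords, cutoff, force_constant)
    evals, evecs = eigh(hess)
    tol = ZERO_MODE_TOL * evals[-1]
    n_zero = int(np.sum(evals < tol))
    if n_zero != 6:
        raise RuntimeError(
            f"expected 6 rigid-body zero modes, found {n_zero}")
    n_modes = min(n_modes, len(evals) - 6)
    sel = slice(6, 6 + n_modes)
    return ModeSet(kind="anm", eigenvalues=evals[sel].copy(),
                   eigenvectors=evecs[:, sel].copy(),
                   all_eigenvalues=evals,
                   params={"cutoff": cutoff,
                           "force_constant": force_constant})


def superpose_frames(frames: np.ndarray, n_iter: int = 2) -> np.ndarray:
    """Superpose frames onto their evolving mean (iterated)."""
    frames = np.asarray(frames, dtype=float).copy()
    ref = frames.mean(axis=0)
    for _ in range(n_iter):
        for i in range(frames.shape[0]):
            _, rot, trans = kabsch_rmsd(ref, frames[i])
            frames[i] = frames[i] @ rot.T + trans
        ref = frames.mean(axis=0)
    return frames


def pca_modes(traj: Trajectory, subset: np.ndarray | None = None,
              n_modes: int | None = None) -> ModeSet:
    """Essential-dynamics PCA of a trajectory.

    Frames are superposed onto their mean (two refinement passes), the
    3N x 3N coordinate covariance is diagonalised, and the variance
    fraction of mode i is eigenvalue_i / sum(eigenvalues).
    """
    if traj.n_frames < 2:
        raise ValueError("PCA needs at least 2 frames")
    frames = np.stack(traj.frames)
    if subset is not None:
        frames = frames[:, np.asarray(subset, dtype=int), :]
    frames = superpose_frames(frames)
    n_f, n_at, _ = frames.shape
    flat = frames.reshape(n_f, 3 * n_at)
    mean = flat.mean(axis=0)
    dev = flat - mean
    cov = dev.T @ dev / (n_f - 1)
    evals, evecs = eigh(cov)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    evals = np.clip(evals, 0.0, None)
    total = evals.sum()
    fractions = evals / total if total > 0 else np.zeros_like(evals)
    if n_modes is not None:
        evals_out, evecs_out = evals[:n_modes], evecs[:, :n_modes]
        frac_out = fractions[:n_modes]
    else:
        evals_out, evecs_out, frac_out = evals, evecs, fractions
    return ModeSet(kind="pca", eigenvalues=evals_out.copy(),
                   eigenvectors=evecs_out.copy(),
                   variance_fractions=frac_out.copy(),
                   all_eigenvalues=evals,
                   mean_coords=mean.reshape(n_at, 3),
                   params={"n_frames": n_f})


def project_onto_mode(traj: Trajectory, modes: ModeSet, mode_index: int = 0,
                      subset: np.ndarray | None = None) -> np.ndarray:
    """Per-frame projection of the displacement-from-mean onto one mode."""
    if modes.mean_coords is None:
        raise ValueError("projection needs a PCA ModeSet with a stored mean")
    frames = np.stack(traj.frames)
    if subset is not None:
        frames = frames[:, np.asarray(subset, dtype=int), :]
    if frames.shape[1] != modes.mean_coords.shape[0]:
        raise ValueError(
            f"mode dimension mismatch: trajectory has {frames.shape[1]} "
            f"atoms, mode expects {modes.mean_coords.shape[0]}")
    vec = modes.eigenvectors[:, mode_index]
    out = np.empty(frames.shape[0])
    for i in range(frames.shape[0]):
        _, rot, trans = kabsch_rmsd(modes.mean_coords, frames[i])
        fitted = frames[i] @ rot.T + trans
        out[i] = (fitted - modes.mean_coords).ravel() @ vec
    return out


def write_nmd(path: str | Path, modes: ModeSet, coords: np.ndarray,
              title: str = "statemap modes") -> None:
    """Write modes in NMD text format (viewable with Normal Mode Wizard)."""
    coords = np.asarray(coords, dtype=float)
    with open(path, "w") as fh:
        fh.write(f"title {title}\n")
        fh.write("names " + " ".join(["CA"] * coords.shape[0]) + "\n")
        fh.write("coordinates " +
                 " ".join(f"{v:.3f}" for v in coords.ravel()) + "\n")
        for i in range(modes.n_modes):
            scale = (1.0 / np.sqrt(modes.eigenvalues[i])
                     if modes.eigenvalues[i] > 0 else 1.0)
            vec = modes.eigenvectors[:, i]
            fh.write(f"mode {i + 1} {scale:.6g} " +
                     " ".join(f"{v:.6f}" for v in vec) + "\n")
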